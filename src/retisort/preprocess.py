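"""Stimulation-artifact blanking.

Stimulation pulses leak into every channel as transients far larger
than any spike. Before detection those samples are reset to exactly
zero, by two complementary rules:

* deterministic: the full pulse window of every stimulus event
  (cathodic phase T plus anodic phase 2T, plus a guard) is blanked;
* adaptive: any sample where at least a fraction ``frac`` of channels
  simultaneously exceed ``k_art`` robust noise sigmas is blanked (with
  a +/- guard dilation), catching artifacts that are not in the event
  table, e.g. at the end of a recording.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import Recording

__all__ = ["ArtifactMask", "robust_noise_sigma", "blank_artifacts"]


@dataclass
class ArtifactMask:
    """Per-channel boolean mask of blanked samples plus interval list."""

    blanked: np.ndarray  # bool, channels x samples
    intervals: list[tuple[int, int, int]]  # (channel, start, end) half-open

    @property
    def n_blanked(self) -> int:
        return int(self.blanked.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.intervals, columns=["channel", "start_sample", "end_sample"]
        )


def robust_noise_sigma(signal: np.ndarray) -> float:
    """MAD-based noise standard deviation, insensitive to sparse spikes.

    sigma = median(|x - median(x)|) / 0.6745. An all-constant signal
    yields 0, which is valid.
    """
    signal = np.asarray(signal, dtype=np.float64)
    if signal.size < 16:
        raise ValueError("need at least 16 samples for a noise estimate")
    return float(np.median(np.abs(signal - np.median(signal))) / 0.6745)


def _mask_intervals(mask_row: np.ndarray, channel: int) -> list[tuple[int, int, int]]:
    padded = np.concatenate([[False], mask_row, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return [(channel, int(s), int(e)) for s, e in zip(starts, ends)]


def blank_artifacts(
    rec: Recording,
    k_art: float = 10.0,
    frac: float = 0.5,
    guard: float = 0.002,
) -> tuple[Recording, ArtifactMask]:
    """Zero out stimulation artifacts; returns the blanked copy and its mask.

    Parameters
    ----------
    k_art : threshold, in robust noise sigmas, for the cross-channel
        coincidence detector.
    frac : fraction of channels that must exceed the threshold
        simultaneously for the adaptive rule to fire.
    guard : dilation (s) applied around both the stimulus window and any
        adaptively detected artifact sample.

    Idempotent: blanking an already-blanked recording changes nothing.
    """
    samples = rec.samples.copy()
    n_ch, n = samples.shape
    guard_n = int(round(guard * rec.rate))
    mask = np.zeros_like(samples, dtype=bool)

    # deterministic blanking of each stimulus pulse window [onset, onset+3T+guard]
    for ev in rec.stimuli:
        width_n = int(round(3 * ev.cathode_width * rec.rate)) + guard_n
        lo = max(ev.onset, 0)
        hi = min(ev.onset + width_n + 1, n)
        mask[:, lo:hi] = True

    # adaptive cross-channel coincidence rule; the noise estimate excludes
    # stimulus windows and exact zeros so a second pass sees the same statistics
    if n_ch > 0 and n >= 16:
        sigmas = np.zeros(n_ch)
        for i in range(n_ch):
            clean = samples[i, ~mask[i]]
            clean = clean[clean != 0.0]
            sigmas[i] = robust_noise_sigma(clean) if clean.size >= 16 else 0.0
        votable = sigmas > 0
        if votable.any():
            exceed = np.abs(samples[votable]) > (k_art * sigmas[votable])[:, None]
            coincident = exceed.sum(axis=0) >= frac * votable.sum()
            if coincident.any():
                idx = np.flatnonzero(coincident)
                for i in idx:
                    lo = max(i - guard_n, 0)
                    hi = min(i + guard_n + 1, n)
                    mask[:, lo:hi] = True

    samples[mask] = 0.0
    intervals: list[tuple[int, int, int]] = []
    for i, ch in enumerate(rec.geometry.channel_ids):
        intervals.extend(_mask_intervals(mask[i], ch))
    blanked = Recording(
        samples=samples, rate=rec.rate, geometry=rec.geometry, stimuli=list(rec.stimuli)
    )
    return blanked, ArtifactMask(blanked=mask, intervals=intervals)
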