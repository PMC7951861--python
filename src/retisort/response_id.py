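"""Evoked-response identification from per-unit rasters.

A sorted unit's spike train is re-referenced to each stimulus onset to
form a raster (one row per trial) and a post-stimulus time histogram.
A trial counts as a response when the firing rate in the 300 ms after
the stimulus is more than 3 times the rate in the 100 ms before it
(with the window lengths fixed, this is the count inequality
n_post > 9 * n_pre); a unit is classified responsive when at least
half of the stimulation trials pass (10 of the 20 repeats in the
standard protocol). All inequalities are strict.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np

__all__ = [
    "RasterSet",
    "ResponseVerdict",
    "PRE_WINDOW",
    "POST_WINDOW",
    "build_raster",
    "psth",
    "trial_passes",
    "classify_unit",
]

# response-criterion windows (s): pre [-0.1, 0), post (0, 0.3]
PRE_WINDOW = 0.1
POST_WINDOW = 0.3


@dataclass
class RasterSet:
    """Per-trial stimulus-relative spike times (s) for one unit."""

    unit: tuple[int, int]  # (channel, cluster)
    trials: list[np.ndarray]  # sorted times within [-pre, post]
    amplitudes: list[float]  # stimulus amplitude per trial (V)
    pre: float = 0.1
    post: float = 0.9

    @property
    def n_trials(self) -> int:
        return len(self.trials)


@dataclass
class ResponseVerdict:
    unit: tuple[int, int]
    passes: list[bool]
    n_pass: int
    n_trials: int
    responsive: bool
    pre_rates: list[float] = field(default_factory=list)  # Hz per trial
    post_rates: list[float] = field(default_factory=list)


def build_raster(
    spike_times: np.ndarray,
    stimuli,
    rate: float | None = None,
    pre: float = 0.1,
    post: float = 0.9,
    unit: tuple[int, int] = (0, 0),
) -> RasterSet:
    """Re-reference a unit's spike times to each stimulus onset.

    ``spike_times`` may be sample indices (pass ``rate``) or seconds.
    Spikes outside [-pre, post] of an onset are excluded from that
    trial's row.
    """
    t = np.asarray(spike_times, dtype=np.float64)
    if rate is not None:
        t = t / rate
    t = np.sort(t)
    trials, amps = [], []
    for ev in stimuli:
        onset_s = ev.onset / rate if rate is not None else float(ev.onset)
        rel = t - onset_s
        trials.append(rel[(rel >= -pre) & (rel <= post)])
        amps.append(ev.amplitude)
    return RasterSet(unit=unit, trials=trials, amplitudes=amps, pre=pre, post=post)


def psth(r: RasterSet, bin: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of raster spike times over [-pre, post], summed across trials."""
    if bin <= 0:
        raise ValueError("bin width must be positive")
    edges = np.arange(-r.pre, r.post + bin / 2, bin)
    if edges[-1] < r.post:
        edges = np.append(edges, r.post)
    all_times = np.concatenate(r.trials) if r.trials else np.empty(0)
    counts, edges = np.histogram(all_times, bins=edges)
    return edges, counts


def trial_passes(n_pre: int, n_post: int, mode: str = "rate") -> bool:
    """Single-trial response criterion: post-stimulus firing more than
    3 times the pre-stimulus firing.

    In ``rate`` mode the firing frequencies are compared
    (n_post / 0.3 s > 3 * n_pre / 0.1 s, i.e. n_post > 9 * n_pre);
    ``count`` mode compares raw counts (n_post > 3 * n_pre). Strict
    inequality, so one post-stimulus spike against a silent baseline
    passes.
    """
    if mode == "rate":
        return n_post / POST_WINDOW > 3.0 * (n_pre / PRE_WINDOW)
    if mode == "count":
        return n_post > 3 * n_pre
    raise ValueError(f"unknown mode {mode!r}")


def classify_unit(
    r: RasterSet, min_pass: int | None = None, mode: str = "rate"
) -> ResponseVerdict:
    """Responsive iff at least ``min_pass`` trials satisfy the criterion.

    ``min_pass`` defaults to 10 for the standard 20-trial protocol and
    to ceil(n_trials / 2) otherwise.
    """
    if r.n_trials == 0:
        raise ValueError("cannot classify a unit with zero trials")
    if min_pass is None:
        min_pass = 10 if r.n_trials == 20 else ceil(r.n_trials / 2)
    passes, pre_rates, post_rates = [], [], []
    for trial in r.trials:
        n_pre = int(np.sum((trial >= -PRE_WINDOW) & (trial < 0)))
        n_post = int(np.sum((trial > 0) & (trial <= POST_WINDOW)))
        passes.append(trial_passes(n_pre, n_post, mode=mode))
        pre_rates.append(n_pre / PRE_WINDOW)
        post_rates.append(n_post / POST_WINDOW)
    n_pass = int(sum(passes))
    return ResponseVerdict(
        unit=r.unit, passes=passes, n_pass=n_pass, n_trials=r.n_trials,
        responsive=n_pass >= min_pass, pre_rates=pre_rates, post_rates=post_rates,
    )
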