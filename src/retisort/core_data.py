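"""Core containers for multi-electrode-array recordings.

A :class:`Recording` bundles the per-channel voltage traces (µV), the
sampling rate, the electrode grid geometry and the stimulus event table.
Recordings round-trip through a documented HDF5 layout (or, for tiny
hand-written fixtures, a directory of CSV files) and can be epoched
around stimulus onsets.

Conventions: sample indices are 0-based; time is in seconds; each
stimulus onset defines t = 0 for its trial; the pre-stimulus window is
half-open [-pre, 0) and the post-stimulus window is (0, post].
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "ElectrodeGeometry",
    "StimulusEvent",
    "Recording",
    "Epoch",
    "FormatError",
    "IntegrityError",
    "EpochError",
    "load_recording",
    "save_recording",
    "epoch_recording",
]


class FormatError(ValueError):
    """A container file is missing a required dataset or column."""


class IntegrityError(ValueError):
    """A Recording invariant is violated."""


class EpochError(ValueError):
    """One or more stimuli sit too close to the recording edge to epoch."""


@dataclass(frozen=True)
class ElectrodeGeometry:
    """Electrode grid: channel id -> (row, col) index and (x, y) position in µm.

    ``pitch`` is the inter-electrode spacing in µm (100 µm for the
    120-electrode array this tool targets).
    """

    rows: dict[int, int]
    cols: dict[int, int]
    xy_um: dict[int, tuple[float, float]]
    pitch: float = 100.0

    def __post_init__(self) -> None:
        if set(self.rows) != set(self.cols) or set(self.rows) != set(self.xy_um):
            raise IntegrityError("geometry maps must cover the same channel ids")
        for ch in self.rows:
            x, y = self.xy_um[ch]
            if not (
                np.isclose(x, self.cols[ch] * self.pitch)
                and np.isclose(y, self.rows[ch] * self.pitch)
            ):
                raise IntegrityError(
                    f"channel {ch}: position {self.xy_um[ch]} inconsistent with "
                    f"grid index ({self.rows[ch]}, {self.cols[ch]}) at pitch {self.pitch}"
                )

    @property
    def channel_ids(self) -> list[int]:
        return sorted(self.rows)

    @classmethod
    def grid(cls, n_rows: int, n_cols: int, pitch: float = 100.0) -> "ElectrodeGeometry":
        """Dense n_rows x n_cols grid with channel ids in row-major order."""
        rows, cols, xy = {}, {}, {}
        ch = 0
        for r in range(n_rows):
            for c in range(n_cols):
                rows[ch] = r
                cols[ch] = c
                xy[ch] = (c * pitch, r * pitch)
                ch += 1
        return cls(rows=rows, cols=cols, xy_um=xy, pitch=pitch)


@dataclass(frozen=True)
class StimulusEvent:
    """One biphasic, cathode-first stimulation pulse.

    The cathodic phase has amplitude ``amplitude`` (V) and width
    ``cathode_width`` (s); the charge-balancing anodic phase (amplitude/2,
    width 2*cathode_width) is implied, never stored.
    """

    onset: int
    electrode: int
    amplitude: float
    cathode_width: float = 0.025
    trial: int = 0

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise IntegrityError("stimulus amplitude must be positive")
        if self.cathode_width <= 0:
            raise IntegrityError("cathode width must be positive")


@dataclass
class Recording:
    """Multi-channel extracellular recording.

    ``samples`` is a (n_channels, n_samples) float array in µV, one row
    per channel in ``geometry.channel_ids`` order; ``rate`` is the
    sampling frequency in Hz.
    """

    samples: np.ndarray
    rate: float
    geometry: ElectrodeGeometry
    stimuli: list[StimulusEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise IntegrityError("samples must be a 2-D (channels x samples) array")
        if self.samples.shape[0] != len(self.geometry.channel_ids):
            raise IntegrityError(
                f"samples has {self.samples.shape[0]} rows but geometry defines "
                f"{len(self.geometry.channel_ids)} channels"
            )
        if self.rate <= 0:
            raise IntegrityError("sampling rate must be positive")
        for ev in self.stimuli:
            if not (0 <= ev.onset < self.n_samples):
                raise IntegrityError(
                    f"stimulus onset {ev.onset} outside [0, {self.n_samples})"
                )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def channel_index(self, channel_id: int) -> int:
        return self.geometry.channel_ids.index(channel_id)

    def channel(self, channel_id: int) -> np.ndarray:
        return self.samples[self.channel_index(channel_id)]


@dataclass
class Epoch:
    """One (channel, stimulus) window of the recording, t = 0 at onset."""

    channel: int
    trial: int
    amplitude: float
    pre: float
    post: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        if self.pre < 0.1 or self.post < 0.3:
            raise IntegrityError(
                "epoch window must cover the response windows (pre >= 0.1 s, post >= 0.3 s)"
            )


# ---------------------------------------------------------------------------
# Container I/O
# ---------------------------------------------------------------------------

_STIM_COLUMNS = ["onset_sample", "electrode", "amplitude_v", "cathode_width_s", "trial"]


def _stimuli_frame(stimuli: list[StimulusEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "onset_sample": np.array([s.onset for s in stimuli], dtype=np.int64),
            "electrode": np.array([s.electrode for s in stimuli], dtype=np.int32),
            "amplitude_v": np.array([s.amplitude for s in stimuli], dtype=np.float64),
            "cathode_width_s": np.array(
                [s.cathode_width for s in stimuli], dtype=np.float64
            ),
            "trial": np.array([s.trial for s in stimuli], dtype=np.int32),
        }
    )


def _stimuli_from_frame(df: pd.DataFrame) -> list[StimulusEvent]:
    missing = [c for c in _STIM_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"stimulus table lacks columns: {missing}")
    return [
        StimulusEvent(
            onset=int(r.onset_sample),
            electrode=int(r.electrode),
            amplitude=float(r.amplitude_v),
            cathode_width=float(r.cathode_width_s),
            trial=int(r.trial),
        )
        for r in df.itertuples()
    ]


def save_recording(rec: Recording, path: str | os.PathLike) -> None:
    """Write a Recording to the HDF5 container layout.

    Layout: /recording/samples (float32, channels x samples, µV),
    /recording/rate, /geometry/{channel_ids,rows,cols,xy_um,pitch},
    /stimuli/<column> arrays. Refuses to write non-finite samples.
    """
    if not np.all(np.isfinite(rec.samples)):
        raise IntegrityError("samples contain NaN or infinity; refusing to write")
    ids = rec.geometry.channel_ids
    with h5py.File(path, "w") as f:
        g = f.create_group("recording")
        g.create_dataset("samples", data=rec.samples.astype(np.float32))
        g.create_dataset("rate", data=float(rec.rate))
        geo = f.create_group("geometry")
        geo.create_dataset("channel_ids", data=np.array(ids, dtype=np.int32))
        geo.create_dataset(
            "rows", data=np.array([rec.geometry.rows[c] for c in ids], dtype=np.int32)
        )
        geo.create_dataset(
            "cols", data=np.array([rec.geometry.cols[c] for c in ids], dtype=np.int32)
        )
        geo.create_dataset(
            "xy_um", data=np.array([rec.geometry.xy_um[c] for c in ids], dtype=np.float64)
        )
        geo.create_dataset("pitch", data=float(rec.geometry.pitch))
        st = f.create_group("stimuli")
        frame = _stimuli_frame(rec.stimuli)
        for col in _STIM_COLUMNS:
            st.create_dataset(col, data=frame[col].to_numpy())


def _load_hdf5(path: str | os.PathLike) -> Recording:
    with h5py.File(path, "r") as f:
        for req in ["recording/samples", "recording/rate", "geometry", "stimuli"]:
            if req not in f:
                raise FormatError(f"missing dataset or group: /{req}")
        samples = np.asarray(f["recording/samples"], dtype=np.float64)
        rate = float(f["recording/rate"][()])
        geo = f["geometry"]
        for req in ["channel_ids", "rows", "cols", "xy_um", "pitch"]:
            if req not in geo:
                raise FormatError(f"missing dataset: /geometry/{req}")
        ids = [int(c) for c in geo["channel_ids"][()]]
        rows = {c: int(r) for c, r in zip(ids, geo["rows"][()])}
        cols = {c: int(v) for c, v in zip(ids, geo["cols"][()])}
        xy = {c: (float(p[0]), float(p[1])) for c, p in zip(ids, geo["xy_um"][()])}
        geometry = ElectrodeGeometry(
            rows=rows, cols=cols, xy_um=xy, pitch=float(geo["pitch"][()])
        )
        st = f["stimuli"]
        for col in _STIM_COLUMNS:
            if col not in st:
                raise FormatError(f"missing dataset: /stimuli/{col}")
        frame = pd.DataFrame({col: np.asarray(st[col]) for col in _STIM_COLUMNS})
    return Recording(samples=samples, rate=rate, geometry=geometry,
                     stimuli=_stimuli_from_frame(frame))


def _load_csv_dir(path: str | os.PathLike) -> Recording:
    """Fixture dialect: geometry.csv + stimuli.csv + channel_<id>.csv files."""
    path = os.fspath(path)
    geo_path = os.path.join(path, "geometry.csv")
    stim_path = os.path.join(path, "stimuli.csv")
    rate_path = os.path.join(path, "rate.csv")
    for p in (geo_path, stim_path, rate_path):
        if not os.path.exists(p):
            raise FormatError(f"missing fixture file: {p}")
    geo_df = pd.read_csv(geo_path)
    for col in ["channel_id", "row", "col"]:
        if col not in geo_df.columns:
            raise FormatError(f"geometry.csv lacks column: {col}")
    pitch = float(geo_df["pitch"].iloc[0]) if "pitch" in geo_df.columns else 100.0
    rows = dict(zip(geo_df["channel_id"].astype(int), geo_df["row"].astype(int)))
    cols = dict(zip(geo_df["channel_id"].astype(int), geo_df["col"].astype(int)))
    xy = {c: (cols[c] * pitch, rows[c] * pitch) for c in rows}
    geometry = ElectrodeGeometry(rows=rows, cols=cols, xy_um=xy, pitch=pitch)
    rate = float(pd.read_csv(rate_path)["rate_hz"].iloc[0])
    traces = []
    n = None
    for ch in geometry.channel_ids:
        ch_path = os.path.join(path, f"channel_{ch}.csv")
        if not os.path.exists(ch_path):
            raise FormatError(f"missing fixture file: {ch_path}")
        df = pd.read_csv(ch_path)
        v = df["microvolts"].to_numpy(dtype=np.float64)
        if n is not None and len(v) != n:
            raise IntegrityError("fixture channels have inconsistent lengths")
        n = len(v)
        traces.append(v)
    stimuli = _stimuli_from_frame(pd.read_csv(stim_path))
    return Recording(samples=np.vstack(traces), rate=rate, geometry=geometry,
                     stimuli=stimuli)


def load_recording(path: str | os.PathLike) -> Recording:
    """Read a Recording from the HDF5 container or the CSV fixture directory."""
    if os.path.isdir(path):
        return _load_csv_dir(path)
    return _load_hdf5(path)


def save_recording_csv(rec: Recording, path: str | os.PathLike) -> None:
    """Write the CSV fixture dialect (one file per channel); for tiny fixtures."""
    path = os.fspath(path)
    os.makedirs(path, exist_ok=True)
    ids = rec.geometry.channel_ids
    pd.DataFrame(
        {
            "channel_id": ids,
            "row": [rec.geometry.rows[c] for c in ids],
            "col": [rec.geometry.cols[c] for c in ids],
            "pitch": rec.geometry.pitch,
        }
    ).to_csv(os.path.join(path, "geometry.csv"), index=False)
    pd.DataFrame({"rate_hz": [rec.rate]}).to_csv(
        os.path.join(path, "rate.csv"), index=False
    )
    _stimuli_frame(rec.stimuli).to_csv(os.path.join(path, "stimuli.csv"), index=False)
    for i, ch in enumerate(ids):
        pd.DataFrame(
            {"sample_index": np.arange(rec.n_samples), "microvolts": rec.samples[i]}
        ).to_csv(os.path.join(path, f"channel_{ch}.csv"), index=False)


# ---------------------------------------------------------------------------
# Epoching
# ---------------------------------------------------------------------------


def epoch_recording(rec: Recording, pre: float = 0.1, post: float = 0.9) -> list[Epoch]:
    """Cut one Epoch per (channel, stimulus), t = 0 aligned to the onset sample.

    Each epoch spans ``(pre + post) * rate + 1`` samples. Raises
    :class:`EpochError` listing every stimulus that sits closer than
    ``pre`` to the start or ``post`` to the end of the recording.
    """
    n_pre = int(round(pre * rec.rate))
    n_post = int(round(post * rec.rate))
    bad = [
        ev
        for ev in rec.stimuli
        if ev.onset - n_pre < 0 or ev.onset + n_post >= rec.n_samples
    ]
    if bad:
        raise EpochError(
            "stimuli too close to the recording edge: "
            + ", ".join(f"(trial {ev.trial}, onset {ev.onset})" for ev in bad)
        )
    epochs = []
    for i, ch in enumerate(rec.geometry.channel_ids):
        for ev in rec.stimuli:
            epochs.append(
                Epoch(
                    channel=ch,
                    trial=ev.trial,
                    amplitude=ev.amplitude,
                    pre=pre,
                    post=post,
                    samples=rec.samples[i, ev.onset - n_pre : ev.onset + n_post + 1].copy(),
                )
            )
    return epochs
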