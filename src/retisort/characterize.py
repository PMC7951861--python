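"""Spatial and voltage characterization of evoked responses.

Recording electrodes are grouped into concentric square layers around
the stimulation electrode: layer 1 holds the 8 immediately adjacent
electrodes (Euclidean distance between pitch and pitch*sqrt(2), i.e.
100-141.4 µm at 100 µm spacing), layer 2 the next square ring, and so
on — the Chebyshev distance on the grid indices. Responsiveness
percentages per layer describe the spatial reach of a stimulus.

The voltage-response curve (mean evoked spikes per pulse in the 300 ms
response window, per cathodic amplitude) is fitted with a Boltzmann
sigmoid y(V) = L + (U - L) / (1 + exp(-(V - V0)/s)); the threshold
voltage is where the fit crosses 0.5 spikes/pulse, and the saturation
voltage is the smallest tested amplitude reaching 95% of the fitted
upper plateau.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .core_data import ElectrodeGeometry
from .response_id import POST_WINDOW, RasterSet, ResponseVerdict

__all__ = [
    "LayerStats",
    "VoltageResponseCurve",
    "FitError",
    "ThresholdUndefinedError",
    "layer_index",
    "layer_percentages",
    "spikes_per_pulse",
    "boltzmann",
    "fit_voltage_curve",
]


class FitError(RuntimeError):
    """Sigmoid fit failed to converge or the requested level is out of range."""


class ThresholdUndefinedError(FitError):
    """0.5 spikes/pulse lies outside the fitted plateaus; no threshold voltage.

    The otherwise-valid fit is attached as ``.curve`` (threshold_v None).
    """

    def __init__(self, message: str, curve: "VoltageResponseCurve"):
        super().__init__(message)
        self.curve = curve


@dataclass
class LayerStats:
    layer: int
    n_units: int
    n_responsive: int

    @property
    def percentage(self) -> float:
        return 100.0 * self.n_responsive / self.n_units if self.n_units else 0.0


@dataclass
class VoltageResponseCurve:
    amplitudes: np.ndarray  # tested cathodic amplitudes (V), ascending
    mean_spikes: np.ndarray  # mean spikes per pulse at each amplitude
    lower: float  # fitted lower plateau L
    upper: float  # fitted upper plateau U
    midpoint: float  # V0 (V)
    slope: float  # s (V)
    threshold_v: float | None  # amplitude where the fit crosses 0.5
    saturation_v: float | None  # smallest tested amplitude with fit >= L + 0.95 (U-L)
    residual: float  # sum of squared fit residuals

    def predict(self, v: np.ndarray) -> np.ndarray:
        return boltzmann(np.asarray(v, dtype=float),
                         self.lower, self.upper, self.midpoint, self.slope)


def layer_index(
    stim: int, rec: int, geom: ElectrodeGeometry, metric: str = "chebyshev"
) -> int:
    """Distance layer of the recording electrode around the stimulation one.

    0 is the stimulation electrode itself. The default Chebyshev ring
    matches the square-grid convention (ring 1 = the 8 adjacent
    electrodes; ring k's Euclidean distances lie in
    [k * pitch, k * pitch * sqrt(2)]). ``metric="euclidean"`` bins by
    rounded Euclidean distance in units of the pitch instead.
    """
    for ch in (stim, rec):
        if ch not in geom.rows:
            raise KeyError(f"channel {ch} not in geometry")
    dr = geom.rows[stim] - geom.rows[rec]
    dc = geom.cols[stim] - geom.cols[rec]
    if metric == "chebyshev":
        return max(abs(dr), abs(dc))
    if metric == "euclidean":
        return int(round(float(np.hypot(dr, dc))))
    raise ValueError(f"unknown metric {metric!r}")


def layer_percentages(
    verdicts: list[ResponseVerdict],
    unit_channel: dict[tuple[int, int], int],
    stim: int,
    geom: ElectrodeGeometry,
    metric: str = "chebyshev",
) -> list[LayerStats]:
    """Responsive-unit percentage per layer (layers with no units omitted)."""
    counts: dict[int, list[int]] = {}
    for v in verdicts:
        ch = unit_channel[v.unit]
        k = layer_index(stim, ch, geom, metric=metric)
        if k == 0:
            continue  # the stimulation electrode records no clean units
        n_units, n_resp = counts.setdefault(k, [0, 0])
        counts[k][0] = n_units + 1
        counts[k][1] = n_resp + int(v.responsive)
    return [
        LayerStats(layer=k, n_units=c[0], n_responsive=c[1])
        for k, c in sorted(counts.items())
    ]


def spikes_per_pulse(
    rasters: list[RasterSet], responsive_units: set[tuple[int, int]] | None = None
) -> list[tuple[float, float]]:
    """Mean evoked spike count in (0, 300 ms] per stimulus amplitude.

    Averages over (unit, trial) pairs of responsive units; pass
    ``responsive_units`` to restrict, or None to use every raster given.
    """
    per_amp: dict[float, list[int]] = {}
    for r in rasters:
        if responsive_units is not None and r.unit not in responsive_units:
            continue
        for trial, amp in zip(r.trials, r.amplitudes):
            n = int(np.sum((trial > 0) & (trial <= POST_WINDOW)))
            per_amp.setdefault(float(amp), []).append(n)
    return [(amp, float(np.mean(ns))) for amp, ns in sorted(per_amp.items())]


def boltzmann(v, lower, upper, midpoint, slope):
    return lower + (upper - lower) / (1.0 + np.exp(-(v - midpoint) / slope))


def fit_voltage_curve(points: list[tuple[float, float]]) -> VoltageResponseCurve:
    """Least-squares Boltzmann fit of the voltage-response curve.

    Initialized from the data (L = min, U = max, V0 = mid-range,
    s = range/10). The threshold voltage solves y(V) = 0.5
    analytically from the fitted parameters and is None (with the rest
    of the fit intact) when 0.5 lies outside the fitted plateaus.
    """
    if len(points) < 4:
        raise ValueError("need at least 4 amplitude points to fit")
    pts = sorted(points)
    v = np.array([p[0] for p in pts], dtype=float)
    y = np.array([p[1] for p in pts], dtype=float)
    vrange = v.max() - v.min()
    p0 = [y.min(), y.max(), (v.max() + v.min()) / 2, max(vrange / 10, 1e-6)]
    try:
        popt, _ = curve_fit(boltzmann, v, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"sigmoid fit did not converge: {exc}") from exc
    lower, upper, midpoint, slope = (float(p) for p in popt)
    resid = float(((boltzmann(v, *popt) - y) ** 2).sum())

    def invert(level: float) -> float | None:
        lo, hi = min(lower, upper), max(lower, upper)
        if not (lo < level < hi):
            return None
        return float(midpoint - slope * np.log((upper - lower) / (level - lower) - 1.0))

    threshold_v = invert(0.5)
    sat_level = lower + 0.95 * (upper - lower)
    fitted = boltzmann(v, *popt)
    above = np.flatnonzero(fitted >= sat_level)
    saturation_v = float(v[above[0]]) if above.size else None
    curve = VoltageResponseCurve(
        amplitudes=v, mean_spikes=y, lower=lower, upper=upper,
        midpoint=midpoint, slope=slope, threshold_v=threshold_v,
        saturation_v=saturation_v, residual=resid,
    )
    if threshold_v is None:
        raise ThresholdUndefinedError(
            "0.5 spikes/pulse lies outside the fitted range "
            f"[{min(lower, upper):.3g}, {max(lower, upper):.3g}]",
            curve,
        )
    return curve
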