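"""End-to-end orchestration: preprocess → detect → sort → respond → characterize.

A single declarative :class:`PipelineConfig` (YAML round-trippable,
unknown keys rejected) carries every stage's parameters, with the
protocol's values as defaults: 0.1 s / 0.3 s response windows, the
3x firing-rate criterion, 10-of-20 passing trials, 25 ms cathodic
pulse width, 0.15-1.65 V amplitude grid.

All result tables are written as CSV/JSON together with a run manifest
(config hash, seed, library versions); identical (input, config, seed)
triples produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
import yaml

from . import characterize as ch
from . import core_data, preprocess, response_id, spike_detect, spike_sort, synth

log = logging.getLogger("retisort")

__all__ = [
    "PreprocessConfig",
    "ResponseConfig",
    "PipelineConfig",
    "StageError",
    "run_pipeline",
]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PreprocessConfig:
    k_art: float = 10.0
    frac: float = 0.5
    guard: float = 0.002


@dataclass
class ResponseConfig:
    pre: float = 0.1
    post: float = 0.9
    mode: str = "rate"  # 'rate': n_post > 9*n_pre; 'count': n_post > 3*n_pre
    min_pass: int | None = None  # None -> 10 of 20 (or ceil(n/2))
    psth_bin: float = 0.01


@dataclass
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    detection: spike_detect.DetectionConfig = field(
        default_factory=spike_detect.DetectionConfig
    )
    sorting: spike_sort.SortingConfig = field(default_factory=spike_sort.SortingConfig)
    response: ResponseConfig = field(default_factory=ResponseConfig)
    synth: synth.SynthConfig = field(default_factory=synth.SynthConfig)
    n_threshold_grid: int = 25
    max_opt_trials: int = 20  # trials used for threshold optimization
    seed: int = 0

    # -- YAML round-trip ----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(_listify(self.to_dict()), f, sort_keys=True)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return _build_dataclass(cls, data, path="config")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        return cls.from_dict(data)


def _listify(obj):
    """YAML-friendly copy: tuples -> lists, numpy scalars -> python."""
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_listify(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _build_dataclass(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping, got {type(data).__name__}")
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"{path}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        f = known[name]
        if dataclasses.is_dataclass(f.type) or (
            isinstance(f.type, str) and "Config" in f.type
        ):
            sub_cls = _resolve_field_class(cls, name)
            kwargs[name] = _build_dataclass(sub_cls, value, f"{path}.{name}")
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


def _resolve_field_class(cls, name: str):
    for f in fields(cls):
        if f.name == name:
            default = f.default_factory() if f.default_factory is not dataclasses.MISSING else None
            if default is not None:
                return type(default)
    raise ValueError(f"cannot resolve nested config class for {name!r}")


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def _trial_segments(
    signal: np.ndarray, rec: core_data.Recording, pre: float, post: float, limit: int
) -> list[np.ndarray]:
    n_pre = int(round(pre * rec.rate))
    n_post = int(round(post * rec.rate))
    segs = []
    for ev in rec.stimuli[:limit]:
        lo, hi = ev.onset - n_pre, ev.onset + n_post + 1
        if lo >= 0 and hi <= rec.n_samples:
            segs.append(signal[lo:hi])
    return segs


def _detect_all(
    rec: core_data.Recording, cfg: PipelineConfig
) -> tuple[dict[int, spike_detect.DetectionResult], dict[int, float]]:
    results: dict[int, spike_detect.DetectionResult] = {}
    thresholds: dict[int, float] = {}
    det_cfg = dataclasses.replace(cfg.detection, rate=rec.rate)
    for i, chan in enumerate(rec.geometry.channel_ids):
        signal = rec.samples[i]
        if not signal.any():
            results[chan] = spike_detect.detect_channel(
                signal, dataclasses.replace(det_cfg, threshold=1.0)
            )
            thresholds[chan] = float("nan")
            continue
        trace = spike_detect.energy_trace(signal, det_cfg)
        if det_cfg.threshold is not None:
            theta = det_cfg.threshold
        else:
            grid = spike_detect.default_threshold_grid(trace, cfg.n_threshold_grid)
            trials = _trial_segments(
                signal, rec, cfg.response.pre, cfg.response.post, cfg.max_opt_trials
            )
            if trials:
                theta, _, _ = spike_detect.optimize_threshold(trials, grid, det_cfg)
            else:  # no stimuli: fall back to the noise-quantile end of the grid
                theta = float(grid[0])
        results[chan] = spike_detect._detect_on_energy(signal, trace, det_cfg, theta)
        thresholds[chan] = theta
        log.debug("channel %d: threshold %.3g, %d spikes", chan, theta,
                  results[chan].n_spikes)
    return results, thresholds


def run_pipeline(
    rec: core_data.Recording | str | os.PathLike,
    config: PipelineConfig | str | os.PathLike | None = None,
    out_dir: str | os.PathLike | None = None,
    seed: int | None = None,
) -> dict:
    """Run the full analysis and (optionally) write the result bundle.

    Returns a dict with the blanked recording, per-channel detections,
    unit labels, rasters, verdicts, layer statistics and the
    voltage-response curve. Stage failures raise :class:`StageError`;
    when writing, partially written outputs are removed.
    """
    if config is None:
        config = PipelineConfig()
    elif not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
        config.sorting = dataclasses.replace(config.sorting, seed=seed)
    if not isinstance(rec, core_data.Recording):
        rec = core_data.load_recording(rec)

    bundle: dict = {"config": config}
    try:
        blanked, mask = preprocess.blank_artifacts(
            rec, k_art=config.preprocess.k_art, frac=config.preprocess.frac,
            guard=config.preprocess.guard,
        )
        bundle["recording"] = blanked
        bundle["mask"] = mask
    except Exception as exc:
        raise StageError("preprocess", exc) from exc

    try:
        detections, thresholds = _detect_all(blanked, config)
        bundle["detections"] = detections
        bundle["thresholds"] = thresholds
    except Exception as exc:
        raise StageError("detect", exc) from exc

    try:
        unit_labels: dict[int, spike_sort.UnitLabels] = {}
        for chan, det in detections.items():
            unit_labels[chan] = spike_sort.sort_channel(det, config.sorting, channel=chan)
        bundle["units"] = unit_labels
    except Exception as exc:
        raise StageError("sort", exc) from exc

    try:
        # classification follows the protocol's repeated-trial blocks: each
        # amplitude's stimuli form one block, and a unit is responsive if it
        # passes the trial criterion in at least min_pass trials of any block
        amp_groups: dict[float, list] = {}
        for ev in blanked.stimuli:
            amp_groups.setdefault(float(ev.amplitude), []).append(ev)
        rasters: dict[tuple[int, int], response_id.RasterSet] = {}
        verdicts: dict[tuple[int, int], response_id.ResponseVerdict] = {}
        for chan, ul in unit_labels.items():
            for u in range(ul.n_units):
                spikes = ul.spike_indices[ul.labels == u]
                rasters[(chan, u)] = response_id.build_raster(
                    spikes, blanked.stimuli, rate=blanked.rate,
                    pre=config.response.pre, post=config.response.post,
                    unit=(chan, u),
                )
                best: response_id.ResponseVerdict | None = None
                for amp in sorted(amp_groups):
                    r = response_id.build_raster(
                        spikes, amp_groups[amp], rate=blanked.rate,
                        pre=config.response.pre, post=config.response.post,
                        unit=(chan, u),
                    )
                    v = response_id.classify_unit(
                        r, min_pass=config.response.min_pass,
                        mode=config.response.mode,
                    )
                    if best is None or (v.responsive, v.n_pass) > (
                        best.responsive, best.n_pass
                    ):
                        best = v
                if best is not None:
                    verdicts[(chan, u)] = best
        bundle["rasters"] = rasters
        bundle["verdicts"] = verdicts
    except Exception as exc:
        raise StageError("respond", exc) from exc

    try:
        stim_ids = [ev.electrode for ev in blanked.stimuli]
        layers: list[ch.LayerStats] = []
        curve = None
        if stim_ids:
            stim = max(set(stim_ids), key=stim_ids.count)
            unit_channel = {k: k[0] for k in verdicts}
            layers = ch.layer_percentages(
                list(verdicts.values()), unit_channel, stim, blanked.geometry
            )
            responsive = {k for k, v in verdicts.items() if v.responsive}
            points = ch.spikes_per_pulse(
                [rasters[k] for k in verdicts], responsive_units=responsive
            )
            bundle["spikes_per_pulse"] = points
            if len(points) >= 4:
                try:
                    curve = ch.fit_voltage_curve(points)
                except ch.ThresholdUndefinedError as exc:
                    curve = exc.curve
                except ch.FitError as exc:
                    log.warning("voltage-curve fit failed: %s", exc)
        bundle["layers"] = layers
        bundle["voltage_curve"] = curve
    except Exception as exc:
        raise StageError("characterize", exc) from exc

    if out_dir is not None:
        try:
            write_bundle(bundle, out_dir)
        except Exception as exc:
            raise StageError("write", exc) from exc
    return bundle


# ---------------------------------------------------------------------------
# Output tables
# ---------------------------------------------------------------------------


def _config_hash(config: PipelineConfig) -> str:
    canon = json.dumps(_listify(config.to_dict()), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


def write_bundle(bundle: dict, out_dir: str | os.PathLike) -> list[str]:
    """Write every result table; on failure, remove what was written."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    written: list[str] = []

    def path(name: str) -> str:
        p = os.path.join(out_dir, name)
        written.append(p)
        return p

    try:
        config: PipelineConfig = bundle["config"]
        rec: core_data.Recording = bundle["recording"]
        config.to_yaml(path("config.yaml"))
        bundle["mask"].to_frame().to_csv(path("artifact_mask.csv"), index=False)

        rows = []
        wf_rows = []
        for chan, det in bundle["detections"].items():
            for k, idx in enumerate(det.indices):
                rows.append((chan, int(idx), idx / rec.rate))
                wf_rows.append([chan, int(idx)] + list(det.waveforms[k]))
        pd.DataFrame(rows, columns=["channel", "spike_sample", "spike_time_s"]).to_csv(
            path("spikes.csv"), index=False
        )
        L = config.detection.waveform_len
        pd.DataFrame(
            wf_rows, columns=["channel", "spike_sample"] + [f"s{i}" for i in range(L)]
        ).to_csv(path("waveforms.csv"), index=False)
        pd.DataFrame(
            [
                (chan, det.threshold, det.snr, det.n_spikes)
                for chan, det in bundle["detections"].items()
            ],
            columns=["channel", "threshold", "snr", "n_spikes"],
        ).to_csv(path("detection_summary.csv"), index=False)

        unit_rows = []
        sil = {}
        for chan, ul in bundle["units"].items():
            for idx, lab in zip(ul.spike_indices, ul.labels):
                unit_rows.append((chan, int(lab), int(idx), idx / rec.rate))
            if ul.report is not None:
                sil[str(chan)] = {
                    "chosen_k": ul.report.chosen_k,
                    "mean_sc_by_k": {str(k): v for k, v in ul.report.by_k.items()},
                }
        pd.DataFrame(
            unit_rows, columns=["channel", "unit", "spike_sample", "spike_time_s"]
        ).to_csv(path("units.csv"), index=False)
        with open(path("silhouette.json"), "w") as f:
            json.dump(sil, f, indent=1, sort_keys=True)

        raster_rows = [
            (k[0], k[1], ti, float(t))
            for k, r in bundle["rasters"].items()
            for ti, trial in enumerate(r.trials)
            for t in trial
        ]
        pd.DataFrame(
            raster_rows, columns=["channel", "unit", "trial", "t_rel_s"]
        ).to_csv(path("rasters.csv"), index=False)

        psth_rows = []
        for k, r in bundle["rasters"].items():
            edges, counts = response_id.psth(r, bin=config.response.psth_bin)
            for e, c in zip(edges[:-1], counts):
                psth_rows.append((k[0], k[1], float(e), int(c)))
        pd.DataFrame(
            psth_rows, columns=["channel", "unit", "bin_left_s", "count"]
        ).to_csv(path("psth.csv"), index=False)

        pd.DataFrame(
            [
                (k[0], k[1], v.n_pass, v.n_trials, v.responsive)
                for k, v in bundle["verdicts"].items()
            ],
            columns=["channel", "unit", "n_pass", "n_trials", "responsive"],
        ).to_csv(path("verdicts.csv"), index=False)

        pd.DataFrame(
            [
                (s.layer, s.n_units, s.n_responsive, s.percentage)
                for s in bundle["layers"]
            ],
            columns=["layer", "n_units", "n_responsive", "percentage"],
        ).to_csv(path("layers.csv"), index=False)

        if bundle.get("spikes_per_pulse"):
            pd.DataFrame(
                bundle["spikes_per_pulse"], columns=["amplitude_v", "mean_spikes"]
            ).to_csv(path("voltage_curve.csv"), index=False)
        curve = bundle.get("voltage_curve")
        if curve is not None:
            with open(path("voltage_fit.json"), "w") as f:
                json.dump(
                    {
                        "lower": curve.lower,
                        "upper": curve.upper,
                        "midpoint_v": curve.midpoint,
                        "slope_v": curve.slope,
                        "threshold_v": curve.threshold_v,
                        "saturation_v": curve.saturation_v,
                        "residual": curve.residual,
                    },
                    f, indent=1, sort_keys=True,
                )

        import scipy  # local import: version strings for the manifest

        manifest = {
            "config_sha256": _config_hash(config),
            "seed": config.seed,
            "n_channels": rec.n_channels,
            "n_stimuli": len(rec.stimuli),
            "versions": {"numpy": np.__version__, "scipy": scipy.__version__,
                         "pandas": pd.__version__},
        }
        with open(path("manifest.json"), "w") as f:
            json.dump(manifest, f, indent=1, sort_keys=True)
    except Exception:
        for p in written:
            if os.path.exists(p):
                os.remove(p)
        raise
    return written
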