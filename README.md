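# retisort

Spike detection, spike sorting and electrically-evoked response
identification for retinal multi-electrode-array (MEA) recordings.

Retinal prostheses restore vision by electrically stimulating retinal
ganglion cells (RGCs), and tuning the stimulus requires knowing which
recorded neurons actually respond, at which electrode distances, and
at which voltages. `retisort` automates that analysis for grid-MEA
stimulation experiments (charge-balanced biphasic voltage pulses,
cathode first, repeated trials over an amplitude ladder):

1. **Artifact blanking** — stimulation transients, far larger than any
   spike, are reset to zero (per-stimulus pulse windows plus a
   cross-channel coincidence detector).
2. **Spike detection** — a stationary (undecimated, à trous) wavelet
   transform feeds the Teager energy operator
   ψ(x(n)) = x(n)² − x(n−1)·x(n+1) per sub-band; the smoothed,
   combined energy is thresholded, with the threshold chosen to match
   a manual-marking reference rule (amplitude > 2× baseline
   bandwidth) and an SNR curve reported alongside.
3. **Spike sorting** — 3-level wavelet-packet features ({sd, Q1} per
   terminal node) are clustered with K-means; the cluster count
   maximizes the mean silhouette coefficient
   s(i) = (b(i) − a(i)) / max{a(i), b(i)}.
4. **Response identification** — per 20-trial stimulus block, a unit
   is responsive when the firing rate in the 300 ms after the pulse
   exceeds 3× the 100 ms pre-pulse rate in at least 10 trials.
5. **Characterization** — responsive-unit percentages per Chebyshev
   electrode ring around the stimulation site, and a Boltzmann sigmoid
   fit of spikes-per-pulse vs cathodic amplitude yielding the
   threshold voltage (fit = 0.5 spikes/pulse) and saturation voltage
   (95 % of the upper plateau).

A fully seeded synthetic recording generator (`retisort.synth`)
emulates the experiment — Poisson background firing, sigmoid
amplitude–response curves, distance-dependent responsiveness, Gaussian
noise, rectangular artifacts — with complete ground truth, so every
stage is testable without any recordings.

## Worked example

```python
import numpy as np
from scipy.stats import spearmanr
from retisort import PipelineConfig, run_pipeline
from retisort.synth import SynthConfig, simulate_recording, evaluate_against_truth

cfg = SynthConfig(n_rows=7, n_cols=7, amplitudes_v=(0.6, 1.05, 1.5),
                  n_trials=20, gap_s=1.2, seed=1)
rec, truth = simulate_recording(cfg)          # 49 channels, 73 s at 10 kHz
bundle = run_pipeline(rec, PipelineConfig(), out_dir="results", seed=1)

scores = evaluate_against_truth(bundle, truth)
print(f"detection F1      {scores['detection_f1']:.3f}")
print(f"sorting accuracy  {scores['sorting_accuracy']:.3f}")
print(f"sensitivity       {scores['response_sensitivity']:.3f}")
print(f"specificity       {scores['response_specificity']:.3f}")
for s in bundle["layers"]:
    print(f"layer {s.layer}: {s.n_responsive}/{s.n_units} responsive "
          f"({s.percentage:.1f} %)")
```

prints

```
detection F1      0.997
sorting accuracy  0.998
sensitivity       1.000
specificity       1.000
layer 1: 14/16 responsive (87.5 %)
layer 2: 16/32 responsive (50.0 %)
layer 3: 15/49 responsive (30.6 %)
```

The pipeline recovers essentially every planted spike (F1 is computed
against ground-truth spike times at ±0.5 ms), assigns them to the
correct planted unit, classifies every responsive/non-responsive unit
correctly, and reproduces the planted distance fall-off of
responsiveness (the generator's responsive probability decays with
ring index). `results/` contains the CSV/JSON tables for every stage
(spikes, waveforms, units, rasters, PSTHs, verdicts, layer statistics,
voltage-curve fit) plus a run manifest.

The same flow is available from the shell:

```sh
retisort simulate --out rec.h5 --truth truth.json --seed 1
retisort run-all --input rec.h5 --out results --seed 1
```

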