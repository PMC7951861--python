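import numpy as np
import pytest

from retisort.core_data import ElectrodeGeometry, Recording, StimulusEvent


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_recording():
    """2 channels x 6000 samples at 10 kHz with one mid-trace stimulus."""
    geom = ElectrodeGeometry.grid(1, 2, pitch=100.0)
    rng = np.random.default_rng(7)
    samples = rng.normal(0, 5, size=(2, 6000))
    stim = StimulusEvent(onset=2000, electrode=0, amplitude=0.9, cathode_width=0.001)
    return Recording(samples=samples, rate=10_000.0, geometry=geom, stimuli=[stim])


def make_spike_train(
    rng, n_samples=100_000, rate=10_000.0, n_spikes=50, amp=80.0, sigma=10.0
):
    """Noise trace with planted biphasic spikes at known sample indices."""
    from retisort.synth import biphasic_template

    signal = rng.normal(0, sigma, size=n_samples)
    tpl = biphasic_template(rate, amp)
    peak = int(np.argmax(np.abs(tpl)))
    # spikes well separated and away from the edges
    positions = np.sort(
        rng.choice(np.arange(200, n_samples - 200, 40), size=n_spikes, replace=False)
    )
    for p in positions:
        start = p - peak
        signal[start : start + len(tpl)] += tpl
    return signal, positions
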