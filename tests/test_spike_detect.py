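import numpy as np
import pytest
import pywt

from retisort.spike_detect import (
    DetectionConfig,
    DetectionResult,
    EnergyTrace,
    UndefinedSnrError,
    WaveletFilterBank,
    combine_subbands,
    compute_snr,
    default_threshold_grid,
    detect_channel,
    detect_peaks,
    energy_trace,
    optimize_threshold,
    reference_manual_rule,
    smooth_hamming,
    swt_decompose,
    teo,
)
from retisort.synth import score_detection

from conftest import make_spike_train


# --- independent à trous oracle: explicit upsampled filters, roll-and-sum ---


def atrous_oracle(signal, wavelet, levels):
    """Direct circular convolution with explicitly upsampled filters."""
    w = pywt.Wavelet(wavelet)

    def upsample(f, level):
        step = 2 ** (level - 1)
        out = np.zeros((len(f) - 1) * step + 1)
        out[::step] = f
        return out

    def circ(f, x):
        out = np.zeros_like(x)
        for m, fm in enumerate(f):
            if fm != 0.0:
                out += fm * np.roll(x, m)
        return out

    a = np.asarray(signal, dtype=float)
    approx, detail = [], []
    for j in range(1, levels + 1):
        lo = upsample(np.asarray(w.dec_lo), j)
        hi = upsample(np.asarray(w.dec_hi), j)
        detail.append(circ(hi, a))
        a = circ(lo, a)
        approx.append(a)
    return approx, detail


class TestSwt:
    @pytest.mark.parametrize("wavelet", ["haar", "db4"])
    def test_matches_brute_force_oracle(self, wavelet, rng):
        bank = WaveletFilterBank.from_wavelet(wavelet)
        for _ in range(25):
            n = int(rng.integers(64, 2049))
            x = rng.normal(size=n)
            coeffs = swt_decompose(x, bank, levels=3)
            oa, od = atrous_oracle(x, wavelet, 3)
            for j in range(3):
                assert np.max(np.abs(coeffs.approx[j] - oa[j])) < 1e-9
                assert np.max(np.abs(coeffs.detail[j] - od[j])) < 1e-9

    def test_constant_signal_has_zero_haar_detail(self):
        bank = WaveletFilterBank.from_wavelet("haar")
        coeffs = swt_decompose(np.ones(64), bank, levels=2)
        for d in coeffs.detail:
            assert np.max(np.abs(d)) < 1e-12

    def test_circular_shift_invariance(self, rng):
        bank = WaveletFilterBank.from_wavelet("haar")
        x = rng.normal(size=512)
        shift = 37
        c0 = swt_decompose(x, bank, levels=3)
        c1 = swt_decompose(np.roll(x, shift), bank, levels=3)
        for j in range(3):
            assert np.allclose(np.roll(c0.approx[j], shift), c1.approx[j],
                               atol=1e-10)
            assert np.allclose(np.roll(c0.detail[j], shift), c1.detail[j],
                               atol=1e-10)

    def test_lengths_preserved_at_every_level(self, rng):
        bank = WaveletFilterBank.from_wavelet("db4")
        x = rng.normal(size=300)
        coeffs = swt_decompose(x, bank, levels=3)
        assert all(len(a) == 300 for a in coeffs.approx)
        assert all(len(d) == 300 for d in coeffs.detail)

    def test_signal_shorter_than_filter_rejected(self):
        bank = WaveletFilterBank.from_wavelet("db4")
        with pytest.raises(ValueError, match="shorter"):
            swt_decompose(np.zeros(10), bank, levels=3)


class TestTeo:
    def test_constant_is_zero(self):
        assert np.max(np.abs(teo(np.full(100, 3.7)))) < 1e-12

    def test_ramp_is_one_at_interior(self):
        out = teo(np.arange(50, dtype=float))
        assert np.max(np.abs(out[1:-1] - 1.0)) < 1e-12

    def test_sinusoid_closed_form(self):
        A, omega = 2.5, 0.3
        n = np.arange(1000)
        out = teo(A * np.sin(omega * n))
        expected = A**2 * np.sin(omega) ** 2
        assert np.max(np.abs(out[1:-1] - expected)) < 1e-9

    def test_endpoints_zero_and_short_input_rejected(self):
        assert teo(np.arange(5.0))[0] == 0.0 and teo(np.arange(5.0))[-1] == 0.0
        with pytest.raises(ValueError):
            teo(np.array([1.0, 2.0]))


class TestSmoothHamming:
    def test_impulse_response_is_normalized_window(self):
        e = np.zeros(101)
        e[50] = 1.0
        out = smooth_hamming(e, 11)
        w = np.hamming(11)
        np.testing.assert_allclose(out[45:56], w / w.sum(), atol=1e-12)

    def test_constant_series_unchanged(self):
        np.testing.assert_allclose(smooth_hamming(np.full(200, 4.2), 11), 4.2)

    def test_reduces_noise_variance(self, rng):
        e = rng.normal(size=10_000)
        assert smooth_hamming(e, 11).var() < e.var()

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_hamming(np.zeros(100), 10)


class TestCombineSubbands:
    def test_sum_of_identical_bands_doubles(self, rng):
        b = rng.normal(size=100)
        np.testing.assert_allclose(combine_subbands([b, b], "sum").energy, 2 * b)

    def test_max_with_zero_band_clips_negative(self, rng):
        b = rng.normal(size=100)
        out = combine_subbands([b, np.zeros(100)], "max").energy
        np.testing.assert_allclose(out, np.maximum(b, 0))

    def test_sum_dominates_max_for_nonnegative_bands(self, rng):
        bands = [np.abs(rng.normal(size=64)) for _ in range(3)]
        s = combine_subbands(bands, "sum").energy
        m = combine_subbands(bands, "max").energy
        assert np.all(s >= m - 1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            combine_subbands([np.zeros(10), np.zeros(11)])


class TestDetectPeaks:
    def test_isolated_peaks_found_at_their_samples(self):
        e = np.zeros(1000)
        for i in (100, 500, 900):
            e[i] = 10.0
        np.testing.assert_array_equal(
            detect_peaks(EnergyTrace(e), 5.0, 10), [100, 500, 900]
        )

    def test_refractory_keeps_larger_of_close_pair(self):
        e = np.zeros(100)
        e[40], e[45] = 5.0, 8.0
        np.testing.assert_array_equal(detect_peaks(EnergyTrace(e), 1.0, 10), [45])

    def test_threshold_above_maximum_gives_empty(self):
        e = np.abs(np.sin(np.linspace(0, 20, 500)))
        assert detect_peaks(EnergyTrace(e), 2.0, 10).size == 0

    def test_count_non_increasing_in_threshold(self, rng):
        e = EnergyTrace(np.abs(rng.normal(size=5000)))
        counts = [detect_peaks(e, t, 10).size for t in np.linspace(0.1, 4, 30)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestDetectChannel:
    def test_recovers_planted_spikes(self, rng):
        signal, positions = make_spike_train(rng, amp=80.0, sigma=10.0)
        cfg = DetectionConfig()
        trace = energy_trace(signal, cfg)
        grid = default_threshold_grid(trace)
        theta, _, _ = optimize_threshold(
            [signal], grid, cfg, reference_counts=np.array([len(positions)])
        )
        det = detect_channel(signal, DetectionConfig(threshold=theta))
        precision, recall, _ = score_detection(
            positions / cfg.rate, det.indices / cfg.rate
        )
        assert precision >= 0.95
        assert recall >= 0.95

    def test_noise_quantile_threshold_rarely_fires(self, rng):
        # on pure noise a threshold at the 99.99th energy percentile leaves
        # ~10 exceedance samples per 1e5; detections are at most one per
        # exceedance sample and in practice fewer (smoothing clusters them)
        noise = rng.normal(0, 10, size=100_000)
        cfg = DetectionConfig()
        trace = energy_trace(noise, cfg)
        theta = float(np.quantile(trace.clipped, 0.9999))
        det = detect_channel(noise, DetectionConfig(threshold=theta))
        n_exceed = int(np.sum(trace.clipped > theta))
        assert det.n_spikes <= n_exceed <= 12

    def test_all_zero_signal_gives_empty_result(self):
        det = detect_channel(np.zeros(10_000), DetectionConfig(threshold=1.0))
        assert det.n_spikes == 0
        assert det.waveforms.shape == (0, 20)

    def test_waveform_peak_alignment(self, rng):
        signal, _ = make_spike_train(rng, n_spikes=20)
        cfg = DetectionConfig()
        trace = energy_trace(signal, cfg)
        theta, _, _ = optimize_threshold(
            [signal], default_threshold_grid(trace), cfg,
            reference_counts=np.array([20]),
        )
        det = detect_channel(signal, DetectionConfig(threshold=theta))
        assert det.n_spikes > 0
        peaks = np.argmax(np.abs(det.waveforms), axis=1)
        assert np.all(peaks == cfg.waveform_pre)


class TestReferenceManualRule:
    def test_thirteen_sigma_spike_detected(self, rng):
        x = rng.normal(0, 1, size=50_000)
        x[25_000] = 13.0
        assert 25_000 in reference_manual_rule(x)

    def test_ten_sigma_spike_below_rule(self, rng):
        x = rng.normal(0, 1, size=50_000)
        x = np.clip(x, -5, 5)  # no chance noise crossings
        x[25_000] = 10.0
        assert 25_000 not in reference_manual_rule(x)

    def test_zero_signal_gives_empty(self):
        assert reference_manual_rule(np.zeros(1000)).size == 0


class TestOptimizeThreshold:
    def test_single_trial_single_candidate_returned(self, rng):
        signal, _ = make_spike_train(rng, n_samples=20_000, n_spikes=10)
        theta, diff, snr = optimize_threshold(
            [signal], np.array([123.0]), DetectionConfig()
        )
        assert theta == 123.0
        assert diff.shape == snr.shape == (1,)

    def test_tie_broken_toward_larger_threshold(self):
        # constructed energy with one huge isolated peak: any threshold below
        # it detects exactly 1 spike, so all candidates tie
        signal = np.zeros(5000)
        signal[2500] = 1000.0
        theta, diff, _ = optimize_threshold(
            [signal], np.array([1.0, 2.0, 3.0]), DetectionConfig(),
            reference_counts=np.array([1]),
        )
        assert np.all(diff == diff[0])
        assert theta == 3.0

    def test_sweep_recovers_planted_count(self, rng):
        cfg = DetectionConfig()
        trials, counts = [], []
        for _ in range(5):
            s, p = make_spike_train(rng, n_samples=50_000, n_spikes=25)
            trials.append(s)
            counts.append(len(p))
        grid = default_threshold_grid(energy_trace(trials[0], cfg))
        theta, diff, _ = optimize_threshold(
            trials, grid, cfg, reference_counts=np.array(counts)
        )
        # difference curve high at both extremes, minimized in between
        assert diff[0] > diff.min() and diff[-1] > diff.min()
        for s, c in zip(trials, counts):
            det = detect_channel(s, DetectionConfig(threshold=theta))
            assert abs(det.n_spikes - c) <= 2

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            optimize_threshold([np.zeros(100)], np.array([]), DetectionConfig())


class TestComputeSnr:
    def _result(self, indices, waveforms, n=20):
        return DetectionResult(
            indices=np.asarray(indices), waveforms=np.asarray(waveforms),
            snr=np.nan, threshold=1.0,
        )

    def test_eq_arithmetic(self):
        signal = np.zeros(10_000)
        signal[100:110] = [1.0, -1.0] * 5  # noise band p2p = 2
        wf = np.zeros((1, 20))
        wf[0, 8], wf[0, 12] = 6.0, -4.0  # spike p2p = 10
        det = self._result([5000], wf)
        assert compute_snr(signal, det) == pytest.approx(25.0)

    def test_identical_p2p_gives_one(self):
        signal = np.zeros(10_000)
        signal[100], signal[101] = 5.0, -5.0
        wf = np.zeros((1, 20))
        wf[0, 8], wf[0, 12] = 5.0, -5.0
        assert compute_snr(signal, self._result([5000], wf)) == pytest.approx(1.0)

    def test_doubling_signal_quadruples_snr(self, rng):
        signal, _ = make_spike_train(rng, n_samples=50_000, n_spikes=10, amp=100.0)
        det = detect_channel(signal, DetectionConfig(threshold=1000.0))
        assert det.n_spikes > 0
        base = compute_snr(signal, det)
        det2 = DetectionResult(
            indices=det.indices, waveforms=2 * det.waveforms,
            snr=np.nan, threshold=1.0,
        )
        assert compute_snr(signal, det2) == pytest.approx(4 * base, rel=1e-9)

    def test_no_spikes_is_undefined(self):
        det = self._result(np.empty(0, dtype=int), np.empty((0, 20)))
        with pytest.raises(UndefinedSnrError):
            compute_snr(np.zeros(1000), det)
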