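"""Spike extraction chain and the closed-form d' fidelity statistic."""

import math

import numpy as np
import pytest

from mushbody.synthetic import SyntheticVoltageSpec, gen_voltage_trace, \
    movie_from_trace
from mushbody.voltage import (FluorMovie, FluorTrace, SpikeTrain,
                              SpikeWaveform, bleach_correct, burst_ratio,
                              detect_spikes, dprime, highpass_median,
                              robust_sd, spike_rate, sta_waveform,
                              svd_denoise)


class TestSvdDenoise:
    def test_rank_one_movie_keeps_one_component(self):
        mv = FluorMovie(np.outer(np.sin(np.linspace(0, 6, 50)) + 2,
                                 np.ones(20)))
        out = svd_denoise(mv, 0.95)
        assert out.meta["k"] == 1
        np.testing.assert_allclose(out.data, mv.data, atol=1e-10)

    def test_identity_denoiser_threshold_one_is_identity(self, rng):
        mv = FluorMovie(rng.normal(size=(30, 12)))
        out = svd_denoise(mv, 1.0, coeff_denoiser=lambda row: row)
        np.testing.assert_allclose(out.data, mv.data, atol=1e-9)

    def test_known_singular_values_select_k(self, rng):
        """Singular values (10, 3, 0.1): fractions 0.917 / 0.99990 / 1, so
        a 0.95 threshold keeps two components."""
        u, _ = np.linalg.qr(rng.normal(size=(40, 3)))
        v, _ = np.linalg.qr(rng.normal(size=(15, 3)))
        mv = FluorMovie(u @ np.diag([10.0, 3.0, 0.1]) @ v.T)
        assert svd_denoise(mv, 0.95).meta["k"] == 2

    def test_all_zero_movie(self):
        out = svd_denoise(FluorMovie(np.zeros((10, 5))))
        assert out.meta["k"] == 0
        assert not out.data.any()

    def test_coeff_denoiser_is_applied(self, rng):
        mv = FluorMovie(rng.normal(size=(20, 8)))
        out = svd_denoise(mv, 1.0, coeff_denoiser=lambda row: 0.0 * row)
        np.testing.assert_allclose(out.data, 0.0)

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            svd_denoise(FluorMovie(np.ones((5, 3))), 0.0)


class TestBleachCorrect:
    def test_exact_biexponential_flattens_to_one(self):
        t = np.arange(4000) / 1000.0
        y = 80 * (0.4 * np.exp(-t / 2.0) + 0.6 * np.exp(-t / 20.0))
        out = bleach_correct(FluorTrace(y))
        np.testing.assert_allclose(out.values, 1.0, atol=1e-4)
        assert not out.meta["bleach_fallback"]

    def test_constant_trace_unchanged(self):
        """A flat trace degenerates to constant amplitudes: the corrected
        trace stays flat to within the fit's slow-tail tolerance."""
        out = bleach_correct(FluorTrace(np.full(500, 7.0)))
        np.testing.assert_allclose(out.values, 1.0, atol=1e-2)

    def test_generator_roundtrip_recovers_kernels(self):
        """Bleach-correcting a synthetic trace leaves 1 + spike kernels;
        kernel amplitude is recovered within 5%."""
        spec = SyntheticVoltageSpec(duration=4.0, noise_sd=0.0,
                                    spike_amplitude=0.06,
                                    true_spike_times=(1.0, 2.0, 3.0))
        out = bleach_correct(gen_voltage_trace(spec))
        resid = out.values - np.median(out.values)
        assert resid.max() == pytest.approx(0.06, rel=0.05)

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError):
            bleach_correct(FluorTrace(np.ones(5)))


class TestHighpassMedian:
    def test_constant_maps_to_zero(self):
        out = highpass_median(FluorTrace(np.full(200, 3.3)))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_slow_ramp_vanishes_away_from_edges(self):
        out = highpass_median(FluorTrace(np.linspace(0, 1, 2000)), 40.0)
        inner = out.values[50:-50]
        # an even window centres on a half-sample: residual <= one step
        assert np.abs(inner).max() <= 1.01 / 1999

    def test_impulse_height_preserved(self):
        """A lone impulse in a flat trace survives median subtraction at
        full height (the 41-sample window median ignores one outlier)."""
        y = np.zeros(301)
        y[150] = 2.5
        out = highpass_median(FluorTrace(y), 41.0)
        assert out.values[150] == pytest.approx(2.5)


class TestDetectSpikes:
    def test_gaussian_noise_rarely_crosses_five_sd(self, rng):
        """Expected false positives below one for 1,000 samples at 5 s.d.
        (Gaussian tail bound: 1000 * P(|z|>5) << 1)."""
        fp = 0
        for seed in range(10):
            y = np.random.default_rng(seed).normal(0, 1.0, 1000)
            fp += len(detect_spikes(FluorTrace(y), threshold_sd=5.0))
        assert fp / 10 < 1.0

    def test_inserted_kernels_recovered_exactly(self):
        """Three 5x-noise kernels, threshold 3 s.d.: three detections at
        the inserted times (seeded noise realization)."""
        spec = SyntheticVoltageSpec(duration=0.8, noise_sd=0.01,
                                    spike_amplitude=0.05,
                                    true_spike_times=(0.2, 0.4, 0.6), seed=5)
        tr = bleach_correct(gen_voltage_trace(spec))
        hp = highpass_median(tr)
        train = detect_spikes(hp, threshold_sd=3.0)
        assert len(train) == 3
        np.testing.assert_allclose(train.spike_times, (0.2, 0.4, 0.6),
                                   atol=0.002)

    def test_zero_trace_gives_no_spikes(self):
        assert len(detect_spikes(FluorTrace(np.zeros(100)), 3.0)) == 0

    @pytest.mark.parametrize("cell,thr", [("PPL1-a3", 3.0),
                                          ("MBON-a2sc", 3.0),
                                          ("MBON-g1pedc", 2.0),
                                          ("MBON-a3", 2.5)])
    def test_cell_type_threshold_presets(self, cell, thr):
        train = detect_spikes(FluorTrace(np.zeros(100)), cell_type=cell)
        assert train.threshold_sd == thr

    def test_full_chain_high_snr_recovery(self):
        """generate -> bleach-correct -> high-pass -> detect recovers at
        least 95% of the ground truth with zero false positives when the
        spike amplitude is 5x the noise s.d."""
        rng = np.random.default_rng(42)
        truth = np.sort(rng.uniform(0.2, 9.8, 40))
        keep = np.concatenate([[True], np.diff(truth) > 0.05])
        truth = truth[keep]
        spec = SyntheticVoltageSpec(duration=10.0, noise_sd=0.01,
                                    spike_amplitude=0.08,
                                    bleach_taus=(30.0, 300.0),
                                    true_spike_times=tuple(truth), seed=0)
        hp = highpass_median(bleach_correct(gen_voltage_trace(spec)))
        det = detect_spikes(hp, threshold_sd=4.0).spike_times
        matched = sum(np.min(np.abs(det - t)) < 0.003 for t in truth)
        false_pos = sum(np.min(np.abs(truth - d)) >= 0.003 for d in det)
        assert matched >= 0.95 * truth.size
        assert false_pos == 0

    def test_robust_sd_ignores_spikes(self, rng):
        y = rng.normal(0, 1.0, 5000)
        y[::100] += 30.0
        assert robust_sd(y) == pytest.approx(1.0, rel=0.1)


class TestSpikeMetrics:
    def test_empty_train_zero_rate(self):
        r = spike_rate(SpikeTrain(np.empty(0), 1.0))
        assert not r.values.any()

    def test_regular_train_plateau(self):
        """A 50-Hz regular train reads 50 Hz in a 100-ms window."""
        times = np.arange(0.01, 2.0, 0.02)
        r = spike_rate(SpikeTrain(times, 2.0), window_ms=100.0)
        mid = r.values[500:1500]
        assert np.median(mid) == pytest.approx(50.0)

    def test_burst_peak_rate(self):
        """7 spikes inside 70 ms peak at 70 Hz with a 100-ms window."""
        times = 0.5 + np.arange(7) * 0.070 / 6
        r = spike_rate(SpikeTrain(times, 1.0), window_ms=100.0)
        assert r.values.max() == pytest.approx(70.0)

    def test_burst_ratio_enumeration(self):
        """Spikes at 0, 10, 100, 115 ms: two ISIs below 20 ms -> 2/4."""
        train = SpikeTrain(np.array([0.0, 0.010, 0.100, 0.115]), 0.2)
        assert burst_ratio(train) == pytest.approx(0.5)

    def test_burst_ratio_degenerate_cases(self):
        assert burst_ratio(SpikeTrain(np.array([0.05]), 0.1)) == 0.0
        regular = SpikeTrain(np.arange(0.1, 2.0, 0.2), 2.0)
        assert burst_ratio(regular) == 0.0
        assert math.isnan(burst_ratio(SpikeTrain(np.empty(0), 1.0)))


class TestStaWaveform:
    def _trace_with_kernels(self, n_spikes, noise_sd, seed=0):
        times = tuple(0.1 + 0.05 * np.arange(n_spikes))
        spec = SyntheticVoltageSpec(duration=0.1 + 0.05 * n_spikes + 0.1,
                                    noise_sd=noise_sd, spike_amplitude=0.05,
                                    true_spike_times=times, seed=seed)
        tr = gen_voltage_trace(spec)
        dff = tr.values / (100.0 * tr.meta["bleach"]) - 1.0
        return FluorTrace(dff), SpikeTrain(np.array(times), tr.duration)

    def test_identical_kernels_average_to_kernel(self):
        tr, train = self._trace_with_kernels(5, 0.0)
        wf = sta_waveform(tr, train, half_window_ms=10.0)
        assert wf.s.max() == pytest.approx(0.05, rel=1e-3)

    def test_noise_averages_down_with_spike_count(self):
        tr, train = self._trace_with_kernels(200, 0.005, seed=3)
        wf = sta_waveform(tr, train, half_window_ms=10.0)
        assert wf.s.max() == pytest.approx(0.05, abs=4 * 0.005 / math.sqrt(200))

    def test_interpolated_amplitude_at_least_bin_max(self):
        tr, train = self._trace_with_kernels(5, 0.0)
        wf = sta_waveform(tr, train, half_window_ms=10.0)
        assert wf.amplitude() >= wf.s.max() - 1e-12

    def test_no_complete_window_raises(self):
        tr = FluorTrace(np.zeros(20))
        with pytest.raises(ValueError):
            sta_waveform(tr, SpikeTrain(np.array([0.001]), 0.02),
                         half_window_ms=25.0)


class TestDPrime:
    def test_zero_waveform_is_degenerate(self):
        fid = dprime(SpikeWaveform(np.zeros(51)), f0=1000.0, nu=1000.0)
        assert fid.d_prime == 0.0 and fid.degenerate
        assert fid.mu0 == 0.0 and fid.mu1 == 0.0

    def test_closed_form_single_bin(self):
        """N=1, s=1, F0=nu: mu1-mu0 = ln 2, sigma = ln 2, d' = 1."""
        fid = dprime(SpikeWaveform(np.array([1.0])), f0=500.0, nu=500.0)
        assert fid.mu1 - fid.mu0 == pytest.approx(math.log(2))
        assert fid.sigma == pytest.approx(math.log(2))
        assert fid.d_prime == pytest.approx(1.0)

    def test_quadrupling_photon_flux_doubles_dprime(self, rng):
        s = np.abs(rng.normal(0, 0.05, 51))
        lo = dprime(SpikeWaveform(s), f0=1e4, nu=1e3)
        hi = dprime(SpikeWaveform(s), f0=4e4, nu=1e3)
        assert hi.d_prime == pytest.approx(2 * lo.d_prime)

    def test_monotone_in_uniform_signal_scaling(self):
        base = np.full(51, 0.01)
        ds = [dprime(SpikeWaveform(base * g), 1e4, 1e3).d_prime
              for g in np.linspace(0.1, 3.0, 12)]
        assert all(b >= a - 1e-12 for a, b in zip(ds, ds[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            dprime(SpikeWaveform(np.array([0.5])), f0=0.0, nu=1e3)
        with pytest.raises(ValueError):
            SpikeWaveform(np.array([-1.5]))


class TestIO:
    def test_movie_roundtrip_tiff_and_h5(self, tmp_path, rng):
        import h5py
        import tifffile
        from mushbody.voltage import read_movie
        data = rng.normal(10, 1, size=(20, 4, 5))
        tifffile.imwrite(tmp_path / "m.tif", data.astype(np.float32))
        mv = read_movie(tmp_path / "m.tif")
        assert mv.data.shape == (20, 20)
        with h5py.File(tmp_path / "m.h5", "w") as fh:
            fh["movie"] = data
        mv2 = read_movie(tmp_path / "m.h5")
        np.testing.assert_allclose(mv.data, mv2.data, rtol=1e-6)

    def test_trace_roundtrip_text(self, tmp_path, rng):
        from mushbody.voltage import read_trace, write_trace
        tr = FluorTrace(rng.normal(size=100), sampling_rate=1000.0)
        write_trace(tr, tmp_path / "t.tsv")
        back = read_trace(tmp_path / "t.tsv")
        np.testing.assert_allclose(back.values, tr.values, atol=1e-6)
        assert back.sampling_rate == pytest.approx(1000.0)
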