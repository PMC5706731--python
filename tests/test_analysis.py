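"""sLFP filtering, spectral peaks, spike phases, SI/OI, and rates."""

import numpy as np
import pytest

from obnet import analysis
from obnet.recording import Recording

FS = 2000.0


def tone(freq_hz, duration_s=3.0, amp=1.0, fs=FS, phase=0.0):
    t = np.arange(int(duration_s * fs)) / fs
    return amp * np.sin(2 * np.pi * freq_hz * t + phase), t


class TestBandpass:
    def test_passband_tone_preserved_zero_phase(self):
        x, t = tone(50.0)
        y = analysis.bandpass_filter(x, FS)
        mid = slice(1000, -1000)  # ignore filter edges
        amp = np.max(np.abs(y[mid]))
        assert amp == pytest.approx(1.0, rel=0.02)
        # zero phase: cross-correlation peak at zero lag (< 1 deg shift)
        lag = np.argmax(np.correlate(y[mid], x[mid], "full")) - (y[mid].size - 1)
        assert abs(lag) / FS * 50.0 * 360.0 < 1.0

    def test_dc_rejected(self):
        y = analysis.bandpass_filter(np.full(6000, 3.7), FS)
        assert np.max(np.abs(y[1000:-1000])) < 1e-4  # > 90 dB rejection

    def test_stopband_attenuated(self):
        x, _ = tone(5.0)
        y = analysis.bandpass_filter(x, FS)
        assert np.max(np.abs(y[1000:-1000])) < 0.1

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError):
            analysis.bandpass_filter(np.zeros(100), FS)


class TestPowerSpectrum:
    def test_known_tone_recovered_with_noise(self):
        rng = np.random.default_rng(0)
        x, _ = tone(32.4)
        x = x + rng.normal(0, 0.1, x.size)  # SNR 10 in amplitude
        spec = analysis.power_spectrum(analysis.bandpass_filter(x, FS), FS)
        assert spec.has_dominant_peak
        assert spec.peak_freq_hz == pytest.approx(32.4, abs=0.6)

    def test_white_noise_flagged_no_dominant_peak(self):
        rng = np.random.default_rng(1)
        x = analysis.bandpass_filter(rng.normal(0, 1, 6000), FS)
        spec = analysis.power_spectrum(x, FS)
        assert not spec.has_dominant_peak
        assert analysis.peak_frequency(spec) is None

    def test_dominant_of_two_tones(self):
        x1, _ = tone(30.0, amp=1.0)
        x2, _ = tone(60.0, amp=0.5)
        spec = analysis.power_spectrum(x1 + x2, FS)
        assert spec.peak_freq_hz == pytest.approx(30.0, abs=0.6)

    def test_resolution_below_spec(self):
        spec = analysis.power_spectrum(tone(40.0, duration_s=1.0)[0], FS)
        df = spec.freq_hz[1] - spec.freq_hz[0]
        assert df <= 0.6


class TestSpikePhases:
    def test_spike_at_peak_has_zero_phase(self):
        peaks = np.array([100.0, 130.0, 160.0])
        sample = analysis.spike_phases(np.array([130.0]), peaks)
        assert sample.phases[0] == pytest.approx(0.0)

    def test_midpoint_spike_has_phase_pi(self):
        peaks = np.array([100.0, 130.0])
        sample = analysis.spike_phases(np.array([115.0]), peaks)
        assert sample.phases[0] == pytest.approx(np.pi)

    def test_outside_spikes_excluded_and_counted(self):
        peaks = np.array([100.0, 130.0])
        sample = analysis.spike_phases(np.array([50.0, 115.0, 200.0]), peaks)
        assert sample.n == 1
        assert sample.n_excluded == 2

    def test_trough_locked_surrogate_recovers_pi_and_high_si(self):
        # spikes at the trough of a sinusoidal sLFP: mean phase pi, SI ~ 1
        x, t = tone(40.0, phase=np.pi / 2)  # cos: peaks at t = k/f
        peaks = analysis.slfp_peak_times(x, FS)
        period = 1000.0 / 40.0
        spikes = peaks[:-1] + period / 2.0
        sample = analysis.spike_phases(spikes, peaks)
        si = analysis.synchronization_index(sample)
        mean_phase = np.angle(np.exp(1j * sample.phases).mean()) % (2 * np.pi)
        assert si == pytest.approx(1.0, abs=1e-6)
        assert mean_phase == pytest.approx(np.pi, abs=0.05)


class TestSynchronizationIndex:
    def test_identical_phases_give_unity(self):
        assert analysis.synchronization_index(np.full(50, 1.3)) == pytest.approx(1.0)

    def test_cancelling_quadrature_phases_give_zero(self):
        phases = np.array([0.0, np.pi / 2, np.pi, 3 * np.pi / 2])
        assert analysis.synchronization_index(phases) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_random_phases_near_zero(self):
        # Monte-Carlo oracle: E[kappa] = sqrt(pi)/2/sqrt(N) ~ 0.009 for N=10^4
        rng = np.random.default_rng(2)
        kappas = [
            analysis.synchronization_index(rng.uniform(0, 2 * np.pi, 10_000))
            for _ in range(20)
        ]
        assert np.mean(kappas) == pytest.approx(0.009, abs=0.005)

    def test_empty_sample_reported_missing(self):
        assert analysis.synchronization_index(np.empty(0)) is None

    def test_invariant_under_global_rotation(self):
        rng = np.random.default_rng(3)
        phases = rng.vonmises(0.5, 2.0, 300) % (2 * np.pi)
        k1 = analysis.synchronization_index(phases)
        k2 = analysis.synchronization_index((phases + 1.234) % (2 * np.pi))
        assert k1 == pytest.approx(k2, rel=1e-9)


class TestOscillationIndex:
    def test_normalizing_condition_attains_unity(self):
        ref = [3.0, 7.0, 5.0]
        assert analysis.oscillation_index([7.0], ref) == pytest.approx(1.0)

    def test_linear_in_power(self):
        ref = [4.0, 8.0]
        assert analysis.oscillation_index([4.0], ref) == pytest.approx(0.5)

    def test_flat_spectrum_runs_contribute_low_power_not_zero(self):
        rng = np.random.default_rng(4)
        flat = analysis.bandpass_filter(rng.normal(0, 0.2, 6000), FS)
        spec = analysis.power_spectrum(flat, FS)
        assert not spec.has_dominant_peak
        oi = analysis.oscillation_index([spec.peak_power], [100 * spec.peak_power])
        assert 0.0 < oi < 1.0


class TestRatesAndHistograms:
    def _recording(self):
        spikes = {
            "MC": [np.linspace(100.0, 1000.0, 10)],  # 10 spikes
            "GC": [np.array([300.0]), np.array([])],
            "PGC": [],
        }
        v = np.zeros((1, 2400))
        return Recording(spikes=spikes, mc_voltage=v, sample_dt_ms=0.5)

    def test_rate_is_count_over_window(self):
        rec = self._recording()
        out = analysis.rates_and_histograms(rec, (0.0, 1000.0))
        assert out.mean_rates_hz["MC"] == pytest.approx(9.0)  # 9 spikes in [0, 1000)
        assert out.mean_rates_hz["GC"] == pytest.approx(0.5)

    def test_histogram_conserves_total_count(self):
        rec = self._recording()
        out = analysis.rates_and_histograms(rec, (0.0, 1200.0))
        assert out.histograms["MC"].sum() == 10
        assert np.all(np.diff(out.hist_edges_ms) == pytest.approx(5.0))

    def test_poisson_surrogate_rate_recovery(self):
        rng = np.random.default_rng(5)
        train = np.sort(rng.uniform(0, 10_000.0, rng.poisson(200)))
        rec = Recording(
            spikes={"MC": [train], "GC": [], "PGC": []},
            mc_voltage=np.zeros((1, 20000)),
            sample_dt_ms=0.5,
        )
        out = analysis.rates_and_histograms(rec, (0.0, 10_000.0))
        assert out.mean_rates_hz["MC"] == pytest.approx(20.0, abs=2.0)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            analysis.rates_and_histograms(self._recording(), (500.0, 500.0))
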