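"""Integrator invariants and calibrated isolated-cell behaviour.

The isolated-cell checks exercise the calibration anchors: mixed-mode
firing with a ~29 Hz subthreshold spectral peak at 0.2 nA, the 44 Hz
fast-STO variant, quiescence at rest, monotone STO frequency with
depolarization, and full-amplitude sub-millisecond dendritic propagation.
"""

import numpy as np
import pytest

from obnet import cells, engine
from obnet.engine import SimulationConfig


@pytest.fixture(scope="module")
def mc():
    return cells.build_mitral_cell()


def _sto_peak(cell, inj_na, duration_ms=2500.0):
    rec = engine.simulate_cell(cell, i_inj_na=inj_na, duration_ms=duration_ms, dt_ms=0.02)
    rate = engine.firing_rate(rec, "MC")
    peak = engine.sto_peak_frequency(rec.mc_voltage[0], rec.sample_rate_hz)
    return rate, peak


class TestIsolatedMitralCell:
    def test_quiescent_at_rest(self, mc):
        rec = engine.simulate_cell(mc, i_inj_na=0.0, duration_ms=2000.0, dt_ms=0.02)
        assert rec.spikes["MC"][0].size == 0
        assert rec.mc_voltage[0, -1] < -55.0  # settles a few mV below STO onset

    def test_mixed_mode_sto_peak_near_29_hz(self, mc):
        rate, peak = _sto_peak(mc, 0.2)
        assert rate > 2.0  # spikes ride the STOs
        assert peak == pytest.approx(29.0, rel=0.10)

    def test_fast_kinetics_shift_peak_to_44_hz(self, mc):
        fast = cells.set_fast_sto_kinetics(mc)
        rate_fast, peak = _sto_peak(fast, 0.2)
        rate_ctrl, _ = _sto_peak(mc, 0.2)
        assert peak == pytest.approx(44.0, rel=0.10)
        # conductance scalings preserve the firing rate
        assert rate_fast == pytest.approx(rate_ctrl, rel=0.15)

    def test_reverted_kinetics_restore_29_hz(self, mc):
        back = cells.set_default_sto_kinetics(cells.set_fast_sto_kinetics(mc))
        _, peak = _sto_peak(back, 0.2)
        assert peak == pytest.approx(29.0, rel=0.10)

    def test_sto_frequency_increases_with_depolarization(self, mc):
        peaks = [_sto_peak(mc, i)[1] for i in (0.15, 0.2, 0.25)]
        assert peaks[0] <= peaks[1] + 0.5
        assert peaks[1] <= peaks[2] + 0.5

    def test_substituted_cell_matches_f_i_curve(self, mc):
        sub = cells.substitute_nap_with_cat(
            mc, cells.CationSubstitution(SimulationConfig().g_cat_ms_cm2)
        )
        for inj in (0.15, 0.2, 0.25, 0.3):
            r_ctrl, _ = _sto_peak(mc, inj)
            r_sub, _ = _sto_peak(sub, inj)
            assert r_sub == pytest.approx(r_ctrl, rel=0.15, abs=1.0)

    def test_substituted_cell_loses_29_hz_resonance(self, mc):
        sub = cells.substitute_nap_with_cat(
            mc, cells.CationSubstitution(SimulationConfig().g_cat_ms_cm2)
        )
        rec_c = engine.simulate_cell(mc, i_inj_na=0.2, duration_ms=2500.0, dt_ms=0.02)
        rec_s = engine.simulate_cell(sub, i_inj_na=0.2, duration_ms=2500.0, dt_ms=0.02)

        def band_power(rec):
            fs = rec.sample_rate_hz
            v = np.minimum(rec.mc_voltage[0][int(500 * fs / 1000):], -40.0)
            v = v - v.mean()
            spec = np.abs(np.fft.rfft(v * np.hanning(v.size), n=2**16)) ** 2
            freq = np.fft.rfftfreq(2**16, d=1 / fs)
            return spec[(freq >= 26.0) & (freq <= 32.0)].max()

        assert band_power(rec_s) < 0.5 * band_power(rec_c)


class TestDendriticPropagation:
    def test_full_amplitude_submillisecond_propagation(self, mc):
        rec = engine.simulate_cell(
            mc,
            i_inj_na=2.0,
            duration_ms=50.0,
            dt_ms=0.005,
            sample_dt_ms=0.005,
            inj_window_ms=(20.0, 23.0),
        )
        t = rec.time_ms()
        v_soma = rec.mc_voltage[0]
        v_dist = rec.extra_traces["extra"][-1]  # 500 um compartment

        def first_crossing(v):
            idx = np.nonzero((v[1:] >= 0.0) & (v[:-1] < 0.0))[0]
            assert idx.size > 0
            return t[idx[0] + 1]

        latency = first_crossing(v_dist) - first_crossing(v_soma)
        assert 0.0 <= latency < 1.0
        amp_soma = v_soma.max() - v_soma[0]
        amp_dist = v_dist.max() - v_dist[0]
        assert amp_dist >= 0.8 * amp_soma


class TestEngineInvariants:
    def test_network_determinism(self):
        cfg = SimulationConfig(dt_ms=0.02, odor_duration_ms=300.0, t_orn_ms=100.0)
        a = engine.run_simulation(cfg)
        b = engine.run_simulation(cfg)
        np.testing.assert_array_equal(a.mc_voltage, b.mc_voltage)
        for pop in ("MC", "GC", "PGC"):
            for ta, tb in zip(a.spikes[pop], b.spikes[pop]):
                np.testing.assert_array_equal(ta, tb)

    def test_quiescent_network_without_input(self):
        cfg = SimulationConfig(
            dt_ms=0.02,
            odor_duration_ms=1000.0,
            # negligible odor amplitudes: effectively no afferent drive
            u0_lo=1e-9, u0_hi=2e-9, us_lo=3e-9, us_hi=4e-9,
            bg_rate_hz=0.0,
        )
        rec = engine.run_simulation(cfg)
        assert sum(t.size for p in rec.spikes.values() for t in p) == 0

    def test_voltages_bounded_in_control_run(self):
        cfg = SimulationConfig(dt_ms=0.02, odor_duration_ms=500.0)
        rec = engine.run_simulation(cfg)
        assert np.max(np.abs(rec.mc_voltage)) < 200.0

    def test_spike_times_strictly_increasing(self):
        cfg = SimulationConfig(dt_ms=0.02, odor_duration_ms=500.0)
        rec = engine.run_simulation(cfg)
        for pop in ("MC", "GC", "PGC"):
            for train in rec.spikes[pop]:
                if train.size > 1:
                    assert np.all(np.diff(train) > 0)

    def test_config_override_validates_keys(self):
        with pytest.raises(ValueError, match="not_a_key"):
            SimulationConfig().override(not_a_key=1.0)

    def test_gaba_conductance_trace_recorded(self):
        cfg = SimulationConfig(dt_ms=0.02, odor_duration_ms=400.0)
        rec = engine.run_simulation(cfg)
        assert rec.gaba_conductance is not None
        assert rec.gaba_conductance.shape == rec.mc_voltage.shape
        assert np.all(rec.gaba_conductance >= 0.0)
        assert rec.gaba_conductance.max() > 0.0  # odor drives GC release


class TestInterneuronActivity:
    def test_gc_spontaneous_rate_low(self):
        """Without MC drive, background noise evokes ~1 Hz GC spiking."""
        gc = cells.build_granule_cell()
        cfg = SimulationConfig()
        rec = engine.simulate_cell(
            gc, i_inj_na=0.0, duration_ms=10_000.0, dt_ms=0.02,
            bg_rate_hz=cfg.bg_rate_hz, bg_g_ns=cfg.bg_g_ns,
        )
        rate = rec.spikes["GC"][0].size / 10.0
        assert 0.2 <= rate <= 2.0

    def test_gc_network_without_excitation_matches_spontaneous(self):
        """Blocking MC->GC synapses leaves GCs at their background rate."""
        cfg = SimulationConfig(dt_ms=0.02, odor_duration_ms=1000.0, w_mc_gc=0.0)
        rec = engine.run_simulation(cfg)
        from obnet import analysis

        out = analysis.rates_and_histograms(rec, cfg.analysis_window_ms)
        assert out.mean_rates_hz["GC"] <= 2.0


class TestNetworkScaling:
    @pytest.mark.parametrize("n_gc", [225])
    def test_larger_gc_population_keeps_gamma(self, n_gc):
        """Scaling GCs up (with 100/n_gc conductance renormalization)
        preserves the gamma rhythm and MC rates."""
        from obnet import scenarios

        cfg = SimulationConfig(dt_ms=0.02, odor_duration_ms=1200.0, n_gc=n_gc)
        rec = engine.run_simulation(cfg)
        m = scenarios.analyze_recording(rec, cfg.analysis_window_ms)
        assert m["has_dominant_peak"]
        assert 20.0 <= m["peak_freq_hz"] <= 60.0
        assert 5.0 <= m["mc_rate_hz"] <= 25.0
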