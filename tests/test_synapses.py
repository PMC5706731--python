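"""Synapse model: activation sigmoid, Mg block, gating kinetics, currents."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from obnet import synapses as syn


@pytest.fixture(params=["AMPA", "NMDA", "GABA_A"])
def spec(request):
    return {
        "AMPA": syn.ampa_spec(),
        "NMDA": syn.nmda_spec(),
        "GABA_A": syn.gaba_a_spec(),
    }[request.param]


class TestPresynapticActivation:
    def test_half_activation_at_threshold(self, spec):
        assert syn.presynaptic_activation(spec.theta_mv, spec) == pytest.approx(0.5)

    def test_graded_gaba_value(self):
        # GABA_A: theta -40, sigma 2 -> F(-30) = 1/(1+e^-5)
        f = syn.presynaptic_activation(-30.0, syn.gaba_a_spec())
        assert f == pytest.approx(1.0 / (1.0 + math.exp(-5.0)), rel=1e-12)

    def test_spike_gating_negligible_subthreshold(self):
        # AMPA: theta 0, sigma 0.2 -> essentially zero at -60 mV
        assert syn.presynaptic_activation(-60.0, syn.ampa_spec()) < 1e-10

    def test_graded_vs_spike_gated_regimes(self):
        # a presynaptic cell held at -45 mV transmits through GABA_A but
        # not through AMPA/NMDA: inhibition is graded, excitation spike-gated
        v = -45.0
        assert syn.presynaptic_activation(v, syn.gaba_a_spec()) >= 0.07
        assert syn.presynaptic_activation(v, syn.ampa_spec()) < 1e-10
        assert syn.presynaptic_activation(v, syn.nmda_spec()) < 1e-10

    @given(st.floats(-100, 60), st.floats(-100, 60))
    def test_monotone_non_decreasing(self, v1, v2):
        spec = syn.gaba_a_spec()
        f1 = syn.presynaptic_activation(v1, spec)
        f2 = syn.presynaptic_activation(v2, spec)
        if v1 < v2:
            assert f1 <= f2

    @given(st.floats(-60, -20), st.floats(-60, -20))
    def test_strictly_increasing_in_graded_range(self, v1, v2):
        # strict increase where F is numerically resolvable (graded regime)
        spec = syn.gaba_a_spec()
        f1 = syn.presynaptic_activation(v1, spec)
        f2 = syn.presynaptic_activation(v2, spec)
        if v1 + 1e-9 < v2:
            assert f1 < f2


class TestMgBlock:
    def test_no_mg_no_block(self):
        v = np.linspace(-90, 40, 27)
        assert np.allclose(syn.mg_block(v, 0.0), 1.0)

    def test_printed_value_at_zero_mv(self):
        assert syn.mg_block(0.0, 1.0) == pytest.approx(1.0 / (1.0 + 1.0 / 3.57), rel=1e-12)

    def test_monotone_increasing_in_v(self):
        v = np.linspace(-90, 40, 200)
        b = syn.mg_block(v, 1.0)
        assert np.all(np.diff(b) > 0)

    def test_identity_for_non_nmda(self):
        assert syn.mg_block(-70.0, syn.ampa_spec()) == 1.0
        assert syn.mg_block(-70.0, syn.gaba_a_spec()) == 1.0
        assert syn.mg_block(-70.0, syn.nmda_spec()) < 1.0


class TestGatingKinetics:
    def test_pure_decay_closed_form(self):
        spec = syn.ampa_spec()
        state = syn.GatingState(s=0.8)
        dt, n = 0.1, 50
        for _ in range(n):
            state = syn.step_gating(state, -80.0, dt, spec)  # F ~ 0
        assert state.s == pytest.approx(0.8 * math.exp(-n * dt / spec.tau_decay_ms), rel=1e-6)

    def test_saturating_fixed_point(self):
        # F = 1 held: s -> alpha/(alpha+beta) = 1/(1 + tau_rise/tau_decay)
        spec = syn.ampa_spec()
        state = syn.GatingState()
        for _ in range(2000):
            state = syn.step_gating(state, 40.0, 0.05, spec)
        assert state.s == pytest.approx(1.0 / (1.0 + 1.0 / 5.5), rel=1e-3)

    def test_nmda_accumulates_over_spike_trains(self):
        # ten spikes at 25 ms intervals accumulate far beyond 5x one spike
        spec = syn.nmda_spec()

        def run(n_spikes):
            state, t, dt = syn.GatingState(), 0.0, 0.05
            peak = 0.0
            while t < n_spikes * 25.0:
                in_spike = (t % 25.0) < 1.0 and t // 25.0 < n_spikes
                state = syn.step_gating(state, 40.0 if in_spike else -70.0, dt, spec)
                peak = max(peak, state.s)
                t += dt
            return peak

        single = run(1)
        assert 0 < single < 0.05
        assert run(10) > 5.0 * single

    def test_exponential_update_matches_fine_euler(self, spec):
        # oracle: explicit Euler at 1000x resolution on a random voltage path
        rng = np.random.default_rng(42)
        v_path = rng.uniform(-80, 40, size=200)
        dt = 0.05
        state = syn.GatingState()
        s_euler = 0.0
        for v in v_path:
            state = syn.step_gating(state, v, dt, spec)
            f = syn.presynaptic_activation(v, spec)
            fine = dt / 1000.0
            for _ in range(1000):
                s_euler += fine * (spec.alpha * f * (1 - s_euler) - spec.beta * s_euler)
        assert state.s == pytest.approx(s_euler, rel=1e-4, abs=1e-9)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-120, 60), min_size=1, max_size=100), st.floats(0.001, 5.0))
    def test_s_bounded_for_arbitrary_traces(self, v_path, dt):
        spec = syn.gaba_a_spec()
        state = syn.GatingState()
        for v in v_path:
            state = syn.step_gating(state, v, dt, spec)
            assert 0.0 <= state.s <= 1.0

    def test_dt_must_be_positive(self):
        with pytest.raises(ValueError):
            syn.step_gating(syn.GatingState(), 0.0, 0.0, syn.ampa_spec())


class TestSynapticCurrent:
    def test_zero_at_reversal(self, spec):
        i = syn.synaptic_current(syn.GatingState(s=0.7), spec.e_syn_mv, spec)
        assert i == pytest.approx(0.0, abs=1e-15)

    def test_gaba_outward_current_value(self):
        # W=2, g=2 nS, s=1, V=-40, E=-80 -> +0.16 nA outward
        spec = syn.gaba_a_spec(weight=2.0)
        i = syn.synaptic_current(syn.GatingState(s=1.0), -40.0, spec)
        assert i == pytest.approx(0.16, rel=1e-12)

    def test_final_max_conductance_is_weighted(self):
        assert syn.gaba_a_spec(weight=2.0).g_max_ns == pytest.approx(4.0)
        assert syn.ampa_spec(weight=3.0).g_max_ns == pytest.approx(6.0)

    def test_nmda_block_reduces_hyperpolarized_current(self):
        # driving force aside, B(V) suppresses NMDA at -70 vs -20 mV
        spec = syn.nmda_spec()
        ratio = syn.mg_block(-70.0, spec) / syn.mg_block(-20.0, spec)
        assert ratio < 0.30


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kwargs", [{"weight": -1.0}, {"tau_decay_ms": 0.0}, {"g_syn_ns": -2.0}]
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            base = dict(
                kind="AMPA", g_syn_ns=2.0, weight=1.0, e_syn_mv=0.0,
                theta_mv=0.0, sigma_mv=0.2, tau_rise_ms=1.0, tau_decay_ms=5.5,
            )
            base.update(kwargs)
            syn.SynapseSpec(**base)
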