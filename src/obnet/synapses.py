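"""Synaptic model: weighted conductances, first-order gating, and NMDA Mg block.

The synaptic current onto a postsynaptic compartment is

    I_syn = W * g_syn * s * B(V_post) * (V_post - E_syn)

where ``s`` is the fraction of open channels, driven by an instantaneous
sigmoid ``F`` of the *presynaptic* membrane potential

    ds/dt = alpha * F(V_pre) * (1 - s) - beta * s,
    F(V)  = 1 / (1 + exp(-(V - theta_syn) / sigma)).

Excitatory synapses (AMPA/NMDA) use a high, steep threshold (theta = 0 mV,
sigma = 0.2 mV), so release is effectively spike-gated.  GABA_A synapses use
theta = -40 mV and sigma = 2 mV, so inhibition is graded in the presynaptic
subthreshold voltage — the dendrodendritic release mode of granule and
periglomerular cells.  ``B(V)`` is the magnesium block for NMDA receptors
and identically 1 otherwise.

Units: voltages mV, times ms, conductances nS, currents nA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

AMPA = "AMPA"
NMDA = "NMDA"
GABA_A = "GABA_A"

#: Default Mg2+ concentration (mM) used in the NMDA block.
DEFAULT_MG_MM = 1.0


@dataclass(frozen=True)
class SynapseSpec:
    """Static parameters of one synapse type (optionally weighted)."""

    kind: str
    g_syn_ns: float  # maximal conductance before weighting, nS
    weight: float  # dimensionless synaptic weight W
    e_syn_mv: float  # reversal potential
    theta_mv: float  # half-activation of the presynaptic sigmoid
    sigma_mv: float  # slope of the presynaptic sigmoid
    tau_rise_ms: float  # tau_alpha
    tau_decay_ms: float  # tau_beta
    mg_mm: float = DEFAULT_MG_MM  # used only for NMDA

    def __post_init__(self) -> None:
        if self.kind not in (AMPA, NMDA, GABA_A):
            raise ValueError(f"unknown synapse kind: {self.kind!r}")
        for name in ("g_syn_ns", "tau_rise_ms", "tau_decay_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.weight < 0:
            raise ValueError(f"weight must be >= 0, got {self.weight}")
        if self.mg_mm < 0:
            raise ValueError(f"mg_mm must be >= 0, got {self.mg_mm}")

    @property
    def alpha(self) -> float:
        """Opening rate 1/tau_rise (1/ms)."""
        return 1.0 / self.tau_rise_ms

    @property
    def beta(self) -> float:
        """Closing rate 1/tau_decay (1/ms)."""
        return 1.0 / self.tau_decay_ms

    @property
    def g_max_ns(self) -> float:
        """Final maximal conductance W * g_syn (nS)."""
        return self.weight * self.g_syn_ns

    def with_weight(self, weight: float) -> "SynapseSpec":
        return replace(self, weight=weight)

    def with_decay(self, tau_decay_ms: float) -> "SynapseSpec":
        return replace(self, tau_decay_ms=tau_decay_ms)


def ampa_spec(weight: float = 1.0) -> SynapseSpec:
    return SynapseSpec(AMPA, 2.0, weight, 0.0, 0.0, 0.2, 1.0, 5.5)


def nmda_spec(weight: float = 1.0, mg_mm: float = DEFAULT_MG_MM) -> SynapseSpec:
    return SynapseSpec(NMDA, 1.0, weight, 0.0, 0.0, 0.2, 52.0, 343.0, mg_mm)


def gaba_a_spec(weight: float = 1.0, tau_decay_ms: float = 18.0) -> SynapseSpec:
    return SynapseSpec(GABA_A, 2.0, weight, -80.0, -40.0, 2.0, 1.25, tau_decay_ms)


@dataclass
class GatingState:
    """Dynamic open fraction of one synapse."""

    s: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.s <= 1.0:
            raise ValueError(f"s must lie in [0, 1], got {self.s}")


def presynaptic_activation(v_pre, spec: SynapseSpec):
    """Instantaneous release sigmoid F(V_pre) in (0, 1).

    Spike-gated for AMPA/NMDA (theta 0 mV, sigma 0.2 mV); graded for
    GABA_A (theta -40 mV, sigma 2 mV).
    """
    v_pre = np.asarray(v_pre, dtype=float)
    out = 1.0 / (1.0 + np.exp(-(v_pre - spec.theta_mv) / spec.sigma_mv))
    return float(out) if out.ndim == 0 else out


def mg_block(v, spec_or_mg):
    """Voltage-dependent Mg2+ block B(V).

    ``B(V) = 1 / (1 + Mg * exp(-0.062 V) / 3.57)`` for NMDA synapses and
    identically 1 for AMPA and GABA_A.  Accepts either a SynapseSpec or a
    bare Mg concentration in mM (treated as NMDA).
    """
    v = np.asarray(v, dtype=float)
    if isinstance(spec_or_mg, SynapseSpec):
        if spec_or_mg.kind != NMDA:
            out = np.ones_like(v)
            return float(out) if out.ndim == 0 else out
        mg = spec_or_mg.mg_mm
    else:
        mg = float(spec_or_mg)
    out = 1.0 / (1.0 + mg * np.exp(-0.062 * v) / 3.57)
    return float(out) if out.ndim == 0 else out


def step_gating(state: GatingState, v_pre: float, dt_ms: float, spec: SynapseSpec) -> GatingState:
    """Advance the open fraction by one timestep.

    Uses the exact exponential solution of the first-order kinetics for F
    held constant over the step:

        s(t+dt) = s_inf + (s - s_inf) * exp(-dt * (alpha F + beta)),
        s_inf   = alpha F / (alpha F + beta).

    Unconditionally keeps s in [0, 1] for any dt.
    """
    if dt_ms <= 0:
        raise ValueError(f"dt_ms must be > 0, got {dt_ms}")
    f = presynaptic_activation(v_pre, spec)
    rate = spec.alpha * f + spec.beta
    s_inf = spec.alpha * f / rate
    s_new = s_inf + (state.s - s_inf) * math.exp(-dt_ms * rate)
    return GatingState(s=min(1.0, max(0.0, s_new)))


def synaptic_current(state: GatingState, v_post: float, spec: SynapseSpec) -> float:
    """Postsynaptic current in nA (positive = outward/hyperpolarizing)."""
    b = mg_block(v_post, spec)
    g_ns = spec.g_max_ns * state.s * b
    return g_ns * (v_post - spec.e_syn_mv) * 1e-3  # nS * mV = pA -> nA
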