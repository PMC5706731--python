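"""Fixed-timestep network integrator.

The coupled compartmental/synaptic system is advanced with a semi-implicit
scheme: membrane voltages are solved implicitly along each cell's
compartment tree (a Hines-ordered elimination, the stability class of
Crank-Nicolson cable steps), while channel gates and synaptic open
fractions use exact exponential (Rush-Larsen) updates with rates frozen
over the step.  This is unconditionally stable for the stiff spine/neck
couplings at any timestep; the default dt is 10 us (configurable down to
2 us), with a convergence test asserting timestep insensitivity.

Fast Na+ and delayed-rectifier K+ channels use standard Traub-Miles
kinetics; the MC persistent sodium (instantaneous sigmoid) and slow
potassium (first-order, tau_KS) currents generate the subthreshold
resonance.  Spikes are somatic upward crossings of 0 mV with a 2 ms
detection lockout.

Internal units: mV, ms, mS, uF, uA.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
from numba import njit

from . import cells as _cells
from . import network as _network
from . import stimuli as _stimuli
from .cells import (
    CationSubstitution,
    GranuleCell,
    MitralCell,
    PeriglomerularCell,
    build_granule_cell,
    build_mitral_cell,
    build_periglomerular_cell,
    load_cell_params,
    set_fast_sto_kinetics,
    substitute_nap_with_cat,
)
from .recording import Recording

NS_TO_MS = 1e-6  # nS -> mS
NA_TO_UA = 1e-3  # nA -> uA

SPIKE_THRESHOLD_MV = 0.0
SPIKE_LOCKOUT_MS = 2.0
DIVERGENCE_MV = 200.0


class SimulationDiverged(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationConfig:
    """Fully resolved run configuration (network + stimuli + integrator).

    Weight and kinetic keys mirror the documented override names
    (``w_gc_mc``, ``w_mc_gc``, ``w_pgc_mc``, ``w_mc_pgc``,
    ``tau_decay_gaba``, ``us_lo``/``us_hi``, ``u0_lo``/``u0_hi``, ...).
    """

    # network
    n_mc: int = 25
    n_gc: int = 100
    p_connect: float = 0.3
    seed: int = 1
    # synaptic weights and kinetics
    w_mc_pgc: float = 1.0
    w_mc_gc: float = 1.0
    w_pgc_mc: float = 4.0
    w_gc_mc: float = 2.0
    tau_decay_gaba: float = 18.0  # GC->MC GABA_A decay (ms); PGC->MC stays 18
    mg_mm: float = 1.0
    # odor input
    u0_lo: float = 0.1
    u0_hi: float = 0.2
    us_lo: float = 0.2
    us_hi: float = 1.0
    r: float = 100.0
    t_orn_ms: float = 500.0
    odor_duration_ms: float = 2000.0
    osn_gain_mc: float = 0.90
    osn_gain_pgc: float = 0.13
    # background noise
    bg_rate_hz: float = 100.0
    bg_g_ns: float = 0.4
    # cell manipulations
    sto_removed: bool = False
    sto_fast: bool = False
    g_cat_ms_cm2: float = 0.36
    # integrator
    dt_ms: float = 0.01
    sample_dt_ms: float = 0.5
    record_gaba: bool = True

    @property
    def duration_ms(self) -> float:
        return self.t_orn_ms + self.odor_duration_ms

    @property
    def analysis_window_ms(self) -> tuple[float, float]:
        """Odor epoch excluding the first 200 ms transient."""
        return (self.t_orn_ms + 200.0, self.duration_ms)

    def override(self, **kwargs) -> "SimulationConfig":
        unknown = set(kwargs) - set(self.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return replace(self, **kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Numba kernel
# ---------------------------------------------------------------------------


@njit(cache=False, fastmath=True)
def _vtrap(x, y):
    # x / (exp(x/y) - 1) with the removable singularity handled
    if abs(x / y) < 1e-6:
        return y * (1.0 - x / y / 2.0)
    return x / (np.exp(x / y) - 1.0)


@njit(cache=False, fastmath=True)
def _simulate(
    dt,
    n_steps,
    sample_every,
    # compartments
    parent,
    g_ax,
    cm,
    v,
    gna,
    gkdr,
    gleak,
    gnap,
    gks,
    gcat,
    gahp,
    ena,
    ek,
    eleak,
    ecat,
    tau_ks,
    vshift,
    nap_vhalf,
    nap_k,
    ks_vhalf,
    ks_k,
    ahp_vhalf,
    ahp_k,
    ahp_tau_on,
    ahp_tau_off,
    m,
    h,
    ngate,
    w,
    z,
    # spike detection
    soma_comp,
    # synapses
    syn_pre,
    syn_post,
    syn_gmax,
    syn_e,
    syn_theta,
    syn_sigma,
    syn_alpha,
    syn_beta,
    syn_mg,
    syn_s,
    syn_mc_row,
    # background noise (AMPA-like conductance events, E = 0 mV)
    bg_comp,
    bg_times,
    bg_off,
    bg_jump,
    bg_decay,
    # OSN drive (current injection, uA)
    osn_comp,
    osn_u0,
    osn_us,
    osn_r,
    osn_t_on,
    # constant current injection (uA)
    inj_comp,
    inj_amp,
    inj_t0,
    inj_t1,
    # recording
    rec_v_comp,
    rec_extra_comp,
    record_gaba,
):
    nc = v.size
    n_cells = soma_comp.size
    n_syn = syn_pre.size
    n_bg = bg_comp.size
    n_samples = (n_steps + sample_every - 1) // sample_every

    v_trace = np.empty((rec_v_comp.size, n_samples))
    extra_trace = np.empty((rec_extra_comp.size, n_samples))
    n_gaba_rows = rec_v_comp.size if record_gaba else 0
    gaba_trace = np.zeros((n_gaba_rows, n_samples))

    max_spikes = int(n_cells * (n_steps * dt / 1000.0) * 200.0) + 1024
    spike_cell = np.empty(max_spikes, dtype=np.int32)
    spike_time = np.empty(max_spikes, dtype=np.float64)
    n_spikes = 0
    last_spike = np.full(n_cells, -1e9)
    v_soma_prev = np.empty(n_cells)
    for c in range(n_cells):
        v_soma_prev[c] = v[soma_comp[c]]

    bg_g = np.zeros(n_bg)
    bg_ptr = np.zeros(n_bg, dtype=np.int64)

    diag = np.empty(nc)
    rhs = np.empty(nc)

    err_comp = -1
    err_time = -1.0

    for step in range(n_steps):
        t = step * dt

        # ---- sample (state at time t) ----
        if step % sample_every == 0:
            k = step // sample_every
            for i in range(rec_v_comp.size):
                v_trace[i, k] = v[rec_v_comp[i]]
            for i in range(rec_extra_comp.size):
                extra_trace[i, k] = v[rec_extra_comp[i]]
            if record_gaba:
                for j in range(n_syn):
                    row = syn_mc_row[j]
                    if row >= 0:
                        gaba_trace[row, k] += syn_gmax[j] * syn_s[j] / NS_TO_MS

        # ---- synaptic gating (exact exponential, F frozen over dt) ----
        for j in range(n_syn):
            vp = v[syn_pre[j]]
            f = 1.0 / (1.0 + np.exp(-(vp - syn_theta[j]) / syn_sigma[j]))
            af = syn_alpha[j] * f
            rate = af + syn_beta[j]
            s_inf = af / rate
            syn_s[j] = s_inf + (syn_s[j] - s_inf) * np.exp(-dt * rate)

        # ---- channel gates (Rush-Larsen with Traub-Miles rates) ----
        for c in range(nc):
            vc = v[c]
            if gna[c] > 0.0:
                vs_ = vc - vshift[c]
                am = 0.32 * _vtrap(-(vs_ + 54.0), 4.0)
                bm = 0.28 * _vtrap(vs_ + 27.0, 5.0)
                ah = 0.128 * np.exp(-(vs_ + 50.0) / 18.0)
                bh = 4.0 / (1.0 + np.exp(-(vs_ + 27.0) / 5.0))
                an = 0.032 * _vtrap(-(vs_ + 52.0), 5.0)
                bn = 0.5 * np.exp(-(vs_ + 57.0) / 40.0)
                sm = am + bm
                sh = ah + bh
                sn = an + bn
                m[c] = am / sm + (m[c] - am / sm) * np.exp(-dt * sm)
                h[c] = ah / sh + (h[c] - ah / sh) * np.exp(-dt * sh)
                ngate[c] = an / sn + (ngate[c] - an / sn) * np.exp(-dt * sn)
            if gks[c] > 0.0:
                winf = 1.0 / (1.0 + np.exp(-(vc - ks_vhalf) / ks_k))
                w[c] = winf + (w[c] - winf) * np.exp(-dt / tau_ks[c])
            if gahp[c] > 0.0:
                zinf = 1.0 / (1.0 + np.exp(-(vc - ahp_vhalf) / ahp_k))
                tz = ahp_tau_on + (ahp_tau_off[c] - ahp_tau_on) * (1.0 - zinf)
                z[c] = zinf + (z[c] - zinf) * np.exp(-dt / tz)

        # ---- assemble the implicit voltage system ----
        for c in range(nc):
            vc = v[c]
            g_sum = gleak[c]
            ge_sum = gleak[c] * eleak[c]
            if gna[c] > 0.0:
                g_na_eff = gna[c] * m[c] * m[c] * m[c] * h[c]
                g_k_eff = gkdr[c] * ngate[c] ** 4
                g_sum += g_na_eff + g_k_eff
                ge_sum += g_na_eff * ena[c] + g_k_eff * ek[c]
            if gnap[c] > 0.0:
                p_inf = 1.0 / (1.0 + np.exp(-(vc - nap_vhalf) / nap_k))
                g_nap_eff = gnap[c] * p_inf
                g_sum += g_nap_eff
                ge_sum += g_nap_eff * ena[c]
            if gks[c] > 0.0:
                g_ks_eff = gks[c] * w[c]
                g_sum += g_ks_eff
                ge_sum += g_ks_eff * ek[c]
            if gahp[c] > 0.0:
                g_ahp_eff = gahp[c] * z[c]
                g_sum += g_ahp_eff
                ge_sum += g_ahp_eff * ek[c]
            if gcat[c] > 0.0:
                g_sum += gcat[c]
                ge_sum += gcat[c] * ecat[c]
            diag[c] = cm[c] / dt + g_sum
            rhs[c] = cm[c] / dt * vc + ge_sum

        # synaptic conductances (B evaluated at the current postsynaptic V)
        for j in range(n_syn):
            p = syn_post[j]
            g = syn_gmax[j] * syn_s[j]
            if syn_mg[j] > 0.0:
                g /= 1.0 + syn_mg[j] * np.exp(-0.062 * v[p]) / 3.57
            diag[p] += g
            rhs[p] += g * syn_e[j]

        # background conductance events (reversal 0 mV)
        for i in range(n_bg):
            bg_g[i] *= bg_decay
            while bg_ptr[i] < bg_off[i + 1] - bg_off[i] and bg_times[bg_off[i] + bg_ptr[i]] <= t:
                bg_g[i] += bg_jump
                bg_ptr[i] += 1
            diag[bg_comp[i]] += bg_g[i]

        # OSN drive
        for i in range(osn_comp.size):
            ramp = 0.5 * (np.tanh(3.0 * (t - osn_t_on) / osn_r - 3.0) + 1.0)
            rhs[osn_comp[i]] += osn_u0[i] + (osn_us[i] - osn_u0[i]) * ramp

        # constant injections
        for i in range(inj_comp.size):
            if inj_t0[i] <= t < inj_t1[i]:
                rhs[inj_comp[i]] += inj_amp[i]

        # ---- Hines solve (parents precede children) ----
        for c in range(nc):
            p = parent[c]
            if p >= 0:
                diag[c] += g_ax[c]
                diag[p] += g_ax[c]
        for c in range(nc - 1, 0, -1):
            p = parent[c]
            if p >= 0:
                f = g_ax[c] / diag[c]
                diag[p] -= f * g_ax[c]
                rhs[p] += f * rhs[c]
        for c in range(nc):
            p = parent[c]
            if p < 0:
                v[c] = rhs[c] / diag[c]
            else:
                v[c] = (rhs[c] + g_ax[c] * v[p]) / diag[c]

        # ---- spike detection and divergence check ----
        for c in range(n_cells):
            vs = v[soma_comp[c]]
            if vs > DIVERGENCE_MV or vs < -DIVERGENCE_MV or np.isnan(vs):
                err_comp = soma_comp[c]
                err_time = t
                return (
                    spike_cell[:n_spikes],
                    spike_time[:n_spikes],
                    v_trace,
                    extra_trace,
                    gaba_trace,
                    err_comp,
                    err_time,
                )
            if (
                vs >= SPIKE_THRESHOLD_MV
                and v_soma_prev[c] < SPIKE_THRESHOLD_MV
                and t - last_spike[c] > SPIKE_LOCKOUT_MS
                and n_spikes < max_spikes
            ):
                spike_cell[n_spikes] = c
                spike_time[n_spikes] = t + dt
                n_spikes += 1
                last_spike[c] = t
            v_soma_prev[c] = vs

    return (
        spike_cell[:n_spikes],
        spike_time[:n_spikes],
        v_trace,
        extra_trace,
        gaba_trace,
        err_comp,
        err_time,
    )


# ---------------------------------------------------------------------------
# Array assembly
# ---------------------------------------------------------------------------


def _gate_steady_state(v):
    """Traub-Miles gate steady states at a holding voltage."""

    def vtrap(x, y):
        x = np.asarray(x, dtype=float)
        return np.where(np.abs(x / y) < 1e-6, y * (1 - x / y / 2), x / np.expm1(x / y))

    am = 0.32 * vtrap(-(v + 54.0), 4.0)
    bm = 0.28 * vtrap(v + 27.0, 5.0)
    ah = 0.128 * np.exp(-(v + 50.0) / 18.0)
    bh = 4.0 / (1.0 + np.exp(-(v + 27.0) / 5.0))
    an = 0.032 * vtrap(-(v + 52.0), 5.0)
    bn = 0.5 * np.exp(-(v + 57.0) / 40.0)
    return am / (am + bm), ah / (ah + bh), an / (an + bn)


class _Assembler:
    """Accumulates compartments, synapses, and inputs into flat arrays."""

    def __init__(self) -> None:
        self.parent: list[int] = []
        self.g_ax: list[float] = []
        self.cm: list[float] = []
        self.gch: dict[str, list[float]] = {ch: [] for ch in _cells.CHANNELS}
        self.ena: list[float] = []
        self.ek: list[float] = []
        self.eleak: list[float] = []
        self.ecat: list[float] = []
        self.tau_ks: list[float] = []
        self.ahp_tau_off: list[float] = []
        self.vshift: list[float] = []
        self.v0: list[float] = []
        self.soma_comp: list[int] = []
        self.pop: list[str] = []
        self.syn: list[tuple] = []  # (pre, post, gmax_ms, e, theta, sigma, alpha, beta, mg, mc_row)
        self.bg_comp: list[int] = []
        self.osn: list[tuple] = []  # (comp, u0_ua, us_ua, r, t_on)
        self.inj: list[tuple] = []  # (comp, amp_ua, t0, t1)

    def add_cell(
        self,
        comps: list[_cells.Compartment],
        parents: list[int],
        g_ax: list[float],
        population: str,
        e_na: float,
        e_k: float,
        tau_ks_ms: float = 10.0,
        e_cat: float = 0.0,
        spike_shift_mv: float = 0.0,
        ahp_tau_off_ms: float = 150.0,
        v_init: float | None = None,
    ) -> int:
        """Append one cell; returns the global index of its root compartment."""
        base = len(self.parent)
        for k, comp in enumerate(comps):
            p = parents[k]
            self.parent.append(base + p if p >= 0 else -1)
            self.g_ax.append(g_ax[k])
            self.cm.append(comp.cm_uf_cm2 * comp.area_cm2)
            for ch in _cells.CHANNELS:
                self.gch[ch].append(comp.g_abs_ms(ch))
            self.ena.append(e_na)
            self.ek.append(e_k)
            self.eleak.append(comp.e_leak_mv)
            self.ecat.append(e_cat)
            self.tau_ks.append(tau_ks_ms)
            self.ahp_tau_off.append(ahp_tau_off_ms)
            self.vshift.append(spike_shift_mv)
            self.v0.append(comp.e_leak_mv if v_init is None else v_init)
        self.soma_comp.append(base)
        self.pop.append(population)
        return base

    def add_synapse(self, pre, post, spec, gmax_scale=1.0, mc_row=-1):
        gmax = spec.g_max_ns * gmax_scale * NS_TO_MS
        mg = spec.mg_mm if spec.kind == "NMDA" else 0.0
        self.syn.append(
            (pre, post, gmax, spec.e_syn_mv, spec.theta_mv, spec.sigma_mv, spec.alpha, spec.beta, mg, mc_row)
        )


# ---------------------------------------------------------------------------
# Network construction and runs
# ---------------------------------------------------------------------------


def build_network_cells(cfg: SimulationConfig, params: dict | None = None):
    """Instantiate the three prototype cells with the config's manipulations."""
    if params is None:
        params = load_cell_params()
    mc = build_mitral_cell(params)
    if cfg.sto_fast:
        mc = set_fast_sto_kinetics(mc)
    if cfg.sto_removed:
        mc = substitute_nap_with_cat(mc, CationSubstitution(cfg.g_cat_ms_cm2))
    gc = build_granule_cell(params)
    pgc = build_periglomerular_cell(params)
    return mc, gc, pgc


def run_simulation(
    cfg: SimulationConfig,
    params: dict | None = None,
    connections: _network.ConnectionTable | None = None,
) -> Recording:
    """Build the network for ``cfg`` and integrate it; returns a Recording.

    Deterministic given (config, seed, dt).  Raises SimulationDiverged if
    any somatic voltage leaves +-200 mV.
    """
    from . import synapses as syn

    mc_proto, gc_proto, pgc_proto = build_network_cells(cfg, params)
    net_cfg = _network.NetworkConfig(
        n_mc=cfg.n_mc, n_gc=cfg.n_gc, p_connect=cfg.p_connect, seed=cfg.seed
    )
    streams = net_cfg.seed_streams()
    if connections is None:
        connections = _network.build_connections(net_cfg, streams["connectivity"])
    odor = _stimuli.draw_odor_pattern(
        cfg.n_mc,
        streams["odor"],
        u0_bounds=(cfg.u0_lo, cfg.u0_hi),
        us_bounds=(cfg.us_lo, cfg.us_hi),
        r=cfg.r,
        t_orn_ms=cfg.t_orn_ms,
    )
    asm = _Assembler()
    asm.nap_vhalf_mv = mc_proto.nap_vhalf_mv
    asm.nap_k_mv = mc_proto.nap_k_mv
    asm.ks_vhalf_mv = mc_proto.ks_vhalf_mv
    asm.ks_k_mv = mc_proto.ks_k_mv
    asm.ahp_vhalf_mv = mc_proto.ahp_vhalf_mv
    asm.ahp_k_mv = mc_proto.ahp_k_mv
    asm.ahp_tau_on_ms = mc_proto.ahp_tau_on_ms
    asm.ahp_tau_off_ms = mc_proto.ahp_tau_off_ms

    # --- mitral cells ---
    mc_comps = mc_proto.compartments()
    mc_parents = mc_proto.parents()
    mc_gax = mc_proto.axial_conductances()
    mc_base = []
    for i in range(cfg.n_mc):
        base = asm.add_cell(
            mc_comps,
            mc_parents,
            mc_gax,
            "MC",
            mc_proto.e_na_mv,
            mc_proto.e_k_mv,
            mc_proto.tau_ks_ms,
            mc_proto.e_cat_mv,
            spike_shift_mv=mc_proto.spike_shift_mv,
            ahp_tau_off_ms=mc_proto.ahp_tau_off_ms,
        )
        mc_base.append(base)
        asm.bg_comp.append(base)  # soma
        asm.osn.append(
            (
                base + 1,  # tuft
                cfg.osn_gain_mc * odor.u0_na[i] * NA_TO_UA,
                cfg.osn_gain_mc * odor.us_na[i] * NA_TO_UA,
                cfg.r,
                cfg.t_orn_ms,
            )
        )

    # --- granule cells (spine count from the connection table) ---
    contacts_by_gc: dict[int, list[int]] = {}
    for row in range(connections.n_contacts):
        contacts_by_gc.setdefault(int(connections.gc_id[row]) - 1, []).append(row)
    gc_base = []
    gc_spine_comp: dict[int, int] = {}  # contact row -> spine compartment
    for g in range(cfg.n_gc):
        rows = contacts_by_gc.get(g, [])
        spines = gc_proto.make_spines(len(rows))
        comps = [gc_proto.body, *spines]
        parents = [-1] + [0] * len(spines)
        g_ax = [0.0] + [gc_proto.neck_g_ns * NS_TO_MS] * len(spines)
        base = asm.add_cell(
            comps, parents, g_ax, "GC", gc_proto.e_na_mv, gc_proto.e_k_mv,
            spike_shift_mv=gc_proto.spike_shift_mv,
            ahp_tau_off_ms=gc_proto.ahp_tau_off_ms,
        )
        gc_base.append(base)
        asm.bg_comp.append(base)
        for k, row in enumerate(rows):
            gc_spine_comp[row] = base + 1 + k

    # --- periglomerular cells ---
    pgc_base = []
    for i in range(cfg.n_mc):
        comps = [pgc_proto.body, pgc_proto.spine]
        base = asm.add_cell(
            comps,
            [-1, 0],
            [0.0, pgc_proto.neck_g_ns * NS_TO_MS],
            "PGC",
            pgc_proto.e_na_mv,
            pgc_proto.e_k_mv,
            spike_shift_mv=pgc_proto.spike_shift_mv,
        )
        pgc_base.append(base)
        asm.bg_comp.append(base)
        asm.osn.append(
            (
                base + 1,  # spine
                cfg.osn_gain_pgc * odor.u0_na[i] * NA_TO_UA,
                cfg.osn_gain_pgc * odor.us_na[i] * NA_TO_UA,
                cfg.r,
                cfg.t_orn_ms,
            )
        )

    # --- synapses ---
    ampa_gc = syn.ampa_spec(cfg.w_mc_gc)
    nmda_gc = syn.nmda_spec(cfg.w_mc_gc, cfg.mg_mm)
    gaba_gc = syn.gaba_a_spec(cfg.w_gc_mc, cfg.tau_decay_gaba)
    ampa_pgc = syn.ampa_spec(cfg.w_mc_pgc)
    nmda_pgc = syn.nmda_spec(cfg.w_mc_pgc, cfg.mg_mm)
    gaba_pgc = syn.gaba_a_spec(cfg.w_pgc_mc, 18.0)
    inh_scale = net_cfg.inhibition_scale

    for row in range(connections.n_contacts):
        mc_i = int(connections.mc_id[row]) - 1
        comp = int(connections.compartment[row])  # 1..7
        dend = mc_base[mc_i] + 1 + comp
        spine = gc_spine_comp[row]
        asm.add_synapse(dend, spine, ampa_gc)
        asm.add_synapse(dend, spine, nmda_gc)
        asm.add_synapse(spine, dend, gaba_gc, gmax_scale=inh_scale, mc_row=mc_i)

    for i in range(cfg.n_mc):
        tuft = mc_base[i] + 1
        spine = pgc_base[i] + 1
        asm.add_synapse(tuft, spine, ampa_pgc)
        asm.add_synapse(tuft, spine, nmda_pgc)
        asm.add_synapse(spine, tuft, gaba_pgc)

    # --- background noise trains ---
    noise = _stimuli.BackgroundNoise(cfg.bg_rate_hz, cfg.bg_g_ns)
    trains = _stimuli.poisson_background(
        noise, cfg.duration_ms, streams["noise"], n_cells=len(asm.bg_comp)
    )

    rec = _run_assembled(asm, cfg, trains, rec_v_rows=mc_base)
    rec.meta.update(
        {
            "config_hash": cfg.config_hash(),
            "seed": cfg.seed,
            "dt_ms": cfg.dt_ms,
            "odor_u0_na": odor.u0_na.tolist(),
            "odor_us_na": odor.us_na.tolist(),
        }
    )
    return rec


def _run_assembled(
    asm: _Assembler,
    cfg: SimulationConfig,
    bg_trains: list[np.ndarray],
    rec_v_rows: list[int],
    extra_comps: list[int] | None = None,
    duration_ms: float | None = None,
) -> Recording:
    duration = cfg.duration_ms if duration_ms is None else duration_ms
    n_steps = int(round(duration / cfg.dt_ms))
    sample_every = max(1, int(round(cfg.sample_dt_ms / cfg.dt_ms)))

    v0 = np.asarray(asm.v0)
    m0, h0, n0 = _gate_steady_state(v0 - np.asarray(asm.vshift))
    gna = np.asarray(asm.gch["na"])
    gks = np.asarray(asm.gch["ks"])
    w0 = np.zeros_like(v0)
    # KS gate starts at its steady state for the initial voltage
    # (vhalf/k are MC-wide scalars; harmless for cells without KS)
    ks_vhalf = _first_mc_attr(asm, "ks_vhalf_mv")
    ks_k = _first_mc_attr(asm, "ks_k_mv")
    w0[:] = 1.0 / (1.0 + np.exp(-(v0 - ks_vhalf) / ks_k))

    if asm.syn:
        syn_arr = np.array(asm.syn, dtype=float)
        syn_pre = syn_arr[:, 0].astype(np.int32)
        syn_post = syn_arr[:, 1].astype(np.int32)
        syn_cols = [syn_arr[:, k] for k in range(2, 9)]
        syn_mc_row = syn_arr[:, 9].astype(np.int32)
    else:
        syn_pre = np.empty(0, dtype=np.int32)
        syn_post = np.empty(0, dtype=np.int32)
        syn_cols = [np.empty(0) for _ in range(7)]
        syn_mc_row = np.empty(0, dtype=np.int32)
    syn_gmax, syn_e, syn_theta, syn_sigma, syn_alpha, syn_beta, syn_mg = syn_cols

    bg_times = (
        np.concatenate(bg_trains) if bg_trains else np.empty(0)
    )
    bg_off = np.concatenate(([0], np.cumsum([t.size for t in bg_trains]))).astype(np.int64)
    bg_decay = float(np.exp(-cfg.dt_ms / 5.5))

    osn = np.array(asm.osn, dtype=float) if asm.osn else np.empty((0, 5))
    inj = np.array(asm.inj, dtype=float) if asm.inj else np.empty((0, 4))

    out = _simulate(
        cfg.dt_ms,
        n_steps,
        sample_every,
        np.asarray(asm.parent, dtype=np.int32),
        np.asarray(asm.g_ax),
        np.asarray(asm.cm),
        v0.copy(),
        gna,
        np.asarray(asm.gch["kdr"]),
        np.asarray(asm.gch["leak"]),
        np.asarray(asm.gch["nap"]),
        gks,
        np.asarray(asm.gch["cat"]),
        np.asarray(asm.gch["ahp"]),
        np.asarray(asm.ena),
        np.asarray(asm.ek),
        np.asarray(asm.eleak),
        np.asarray(asm.ecat),
        np.asarray(asm.tau_ks),
        np.asarray(asm.vshift),
        _first_mc_attr(asm, "nap_vhalf_mv"),
        _first_mc_attr(asm, "nap_k_mv"),
        ks_vhalf,
        ks_k,
        _first_mc_attr(asm, "ahp_vhalf_mv"),
        _first_mc_attr(asm, "ahp_k_mv"),
        _first_mc_attr(asm, "ahp_tau_on_ms"),
        np.asarray(asm.ahp_tau_off),
        m0.copy(),
        h0.copy(),
        n0.copy(),
        w0,
        np.zeros_like(v0),
        np.asarray(asm.soma_comp, dtype=np.int32),
        syn_pre,
        syn_post,
        syn_gmax.copy(),
        syn_e,
        syn_theta,
        syn_sigma,
        syn_alpha,
        syn_beta,
        syn_mg,
        np.zeros(syn_pre.size),
        syn_mc_row,
        np.asarray(asm.bg_comp, dtype=np.int32),
        bg_times,
        bg_off,
        cfg.bg_g_ns * NS_TO_MS,
        bg_decay,
        osn[:, 0].astype(np.int32),
        osn[:, 1].copy(),
        osn[:, 2].copy(),
        cfg.r,
        cfg.t_orn_ms,
        inj[:, 0].astype(np.int32),
        inj[:, 1].copy(),
        inj[:, 2].copy(),
        inj[:, 3].copy(),
        np.asarray(rec_v_rows, dtype=np.int32),
        np.asarray(extra_comps if extra_comps else [], dtype=np.int32),
        cfg.record_gaba,
    )
    spike_cell, spike_time, v_trace, extra_trace, gaba_trace, err_comp, err_time = out
    if err_comp >= 0:
        raise SimulationDiverged(
            f"voltage diverged in compartment {err_comp} at t = {err_time:.3f} ms"
        )

    spikes: dict[str, list[np.ndarray]] = {"MC": [], "GC": [], "PGC": []}
    for c, pop in enumerate(asm.pop):
        times = spike_time[spike_cell == c]
        spikes[pop].append(np.sort(times))

    return Recording(
        spikes=spikes,
        mc_voltage=v_trace,
        sample_dt_ms=cfg.sample_dt_ms,
        gaba_conductance=gaba_trace if cfg.record_gaba else None,
        extra_traces={"extra": extra_trace} if extra_trace.size else {},
        meta={"dt_ms": cfg.dt_ms},
    )


def _first_mc_attr(asm: _Assembler, attr: str) -> float:
    # NaP/KS sigmoid parameters are shared network-wide; stored on the
    # assembler by run_simulation/simulate_cell before the kernel call.
    defaults = {
        "nap_vhalf_mv": -50.0,
        "nap_k_mv": 5.0,
        "ks_vhalf_mv": -45.0,
        "ks_k_mv": 7.0,
        "ahp_vhalf_mv": -20.0,
        "ahp_k_mv": 5.0,
        "ahp_tau_on_ms": 5.0,
        "ahp_tau_off_ms": 150.0,
    }
    return getattr(asm, attr, defaults[attr])


# ---------------------------------------------------------------------------
# Isolated-cell simulations (calibration and cell-level tests)
# ---------------------------------------------------------------------------


def simulate_cell(
    cell: MitralCell | GranuleCell | PeriglomerularCell,
    i_inj_na: float = 0.0,
    duration_ms: float = 2000.0,
    dt_ms: float = 0.01,
    sample_dt_ms: float = 0.1,
    inj_window_ms: tuple[float, float] | None = None,
    bg_rate_hz: float = 0.0,
    bg_g_ns: float = 0.0,
    seed: int = 0,
) -> Recording:
    """Simulate one isolated cell with a somatic current injection.

    For a MitralCell the soma voltage is recorded as trace row 0 and every
    other compartment (tuft, dendrite 1..7) in ``extra_traces['extra']``
    rows 0..7.  No synapses; optional background noise.
    """
    asm = _Assembler()
    if isinstance(cell, MitralCell):
        asm.add_cell(
            cell.compartments(),
            cell.parents(),
            cell.axial_conductances(),
            "MC",
            cell.e_na_mv,
            cell.e_k_mv,
            cell.tau_ks_ms,
            cell.e_cat_mv,
            spike_shift_mv=cell.spike_shift_mv,
            ahp_tau_off_ms=cell.ahp_tau_off_ms,
        )
        asm.nap_vhalf_mv = cell.nap_vhalf_mv
        asm.nap_k_mv = cell.nap_k_mv
        asm.ks_vhalf_mv = cell.ks_vhalf_mv
        asm.ks_k_mv = cell.ks_k_mv
        asm.ahp_vhalf_mv = cell.ahp_vhalf_mv
        asm.ahp_k_mv = cell.ahp_k_mv
        asm.ahp_tau_on_ms = cell.ahp_tau_on_ms
        asm.ahp_tau_off_ms = cell.ahp_tau_off_ms
        extra = list(range(1, 2 + _cells.N_DENDRITE_COMPARTMENTS))
    elif isinstance(cell, GranuleCell):
        asm.add_cell(
            [cell.body], [-1], [0.0], "GC", cell.e_na_mv, cell.e_k_mv,
            spike_shift_mv=cell.spike_shift_mv,
            ahp_tau_off_ms=cell.ahp_tau_off_ms,
        )
        extra = []
    else:
        asm.add_cell(
            [cell.body, cell.spine],
            [-1, 0],
            [0.0, cell.neck_g_ns * NS_TO_MS],
            "PGC",
            cell.e_na_mv,
            cell.e_k_mv,
            spike_shift_mv=cell.spike_shift_mv,
        )
        extra = [1]

    t0, t1 = inj_window_ms if inj_window_ms is not None else (0.0, duration_ms)
    if i_inj_na != 0.0:
        asm.inj.append((0, i_inj_na * NA_TO_UA, t0, t1))

    cfg = SimulationConfig(
        dt_ms=dt_ms,
        sample_dt_ms=sample_dt_ms,
        record_gaba=False,
        bg_rate_hz=bg_rate_hz,
        bg_g_ns=bg_g_ns,
    )
    rng = np.random.default_rng(seed)
    noise = _stimuli.BackgroundNoise(bg_rate_hz, bg_g_ns)
    trains = _stimuli.poisson_background(noise, duration_ms, rng, n_cells=1)
    if bg_rate_hz <= 0:
        trains = [np.empty(0)]
    else:
        asm.bg_comp.append(0)  # soma/body receives the background events
    return _run_assembled(
        asm, cfg, trains, rec_v_rows=[0], extra_comps=extra, duration_ms=duration_ms
    )


def sto_peak_frequency(
    v_mv: np.ndarray,
    fs_hz: float,
    clip_mv: float = -40.0,
    band_hz: tuple[float, float] = (10.0, 100.0),
    skip_ms: float = 500.0,
) -> float:
    """Dominant subthreshold spectral peak of a (spike-clipped) voltage trace.

    Spikes are removed by ceiling-clipping the trace at ``clip_mv``; the
    power spectrum of the remaining fluctuation is zero-padded for <=0.1 Hz
    resolution and the in-band argmax is refined by quadratic fit.
    """
    skip = int(skip_ms * fs_hz / 1000.0)
    x = np.minimum(np.asarray(v_mv, dtype=float)[skip:], clip_mv)
    x = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(max(x.size, int(fs_hz / 0.1)))))
    spec = np.abs(np.fft.rfft(x * np.hanning(x.size), n=nfft)) ** 2
    freq = np.fft.rfftfreq(nfft, d=1.0 / fs_hz)
    in_band = (freq >= band_hz[0]) & (freq <= band_hz[1])
    idx = np.nonzero(in_band)[0]
    k = idx[np.argmax(spec[idx])]
    y0, y1, y2 = spec[k - 1], spec[k], spec[k + 1]
    denom = y0 - 2 * y1 + y2
    shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
    return float(freq[k] + shift * (freq[1] - freq[0]))


def firing_rate(rec: Recording, pop: str = "MC", skip_ms: float = 500.0) -> float:
    """Mean somatic firing rate (Hz) after a settling period."""
    total = 0
    for train in rec.spikes[pop]:
        total += np.count_nonzero(train >= skip_ms)
    dur_s = (rec.duration_ms - skip_ms) * 1e-3
    n = max(1, len(rec.spikes[pop]))
    return total / n / dur_s
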