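"""Compartmental cell models: mitral, granule, and periglomerular cells.

All three cell types are Hodgkin-Huxley-type conductance-based models.
The mitral cell (MC) is the resonant principal neuron: a soma, an apical
tuft (the glomerular compartment receiving OSN input and the PGC synapse),
and a seven-compartment, 500 um lateral dendrite carrying the reciprocal
GC contacts.  Its subthreshold oscillations (STOs, ~29 Hz at 0.2 nA) arise
from the interplay of a persistent sodium current I_NaP (instantaneous
sigmoidal activation) with a slow potassium current I_KS (first-order
activation, time constant tau_KS = 10 ms).  Granule cells (GCs) are a
spiking body plus one spine per MC contact; periglomerular cells (PGCs)
are a body plus a single spine forming the reciprocal tuft synapse.

Channel conductance densities are calibrated values recorded in
``parameters.yaml``; the calibration anchors are the isolated-cell
behaviours (29 Hz STO at 0.2 nA, 44 Hz after the fast-STO modification,
full-amplitude dendritic spike propagation in < 1 ms) and the population
rate targets (GC ~1 Hz spontaneous, low odor-evoked GC rates).
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .network import dendritic_compartment_for_distance  # re-exported

N_DENDRITE_COMPARTMENTS = 7
DENDRITE_LENGTH_UM = 500.0

#: Channel names understood by the engine.
CHANNELS = ("na", "kdr", "leak", "nap", "ks", "cat", "ahp")


class ConfigurationError(ValueError):
    """Raised for invalid cell or synapse parameters, naming the field."""


@dataclass
class Compartment:
    """One isopotential cable segment.

    Conductance densities are in mS/cm^2, geometry in um, capacitance in
    uF/cm^2.  Axial coupling to neighbours is derived from geometry and
    the cell's axial resistivity (or an explicit neck conductance for
    spines).  Dynamic state (voltage, gating variables) lives in the
    simulation engine; gating variables are held in [0, 1] at every step.
    """

    name: str
    length_um: float
    diam_um: float
    cm_uf_cm2: float = 1.0
    channels: dict[str, float] = field(default_factory=dict)  # mS/cm^2
    e_leak_mv: float = -65.0

    def __post_init__(self) -> None:
        for nm, val in (("length_um", self.length_um), ("diam_um", self.diam_um), ("cm_uf_cm2", self.cm_uf_cm2)):
            if val <= 0:
                raise ConfigurationError(f"{self.name}.{nm} must be > 0, got {val}")
        for ch, g in self.channels.items():
            if ch not in CHANNELS:
                raise ConfigurationError(f"{self.name}: unknown channel {ch!r}")
            if g < 0:
                raise ConfigurationError(f"{self.name}.channels.{ch} must be >= 0, got {g}")

    @property
    def area_cm2(self) -> float:
        """Lateral cylinder area (cm^2)."""
        return math.pi * self.diam_um * self.length_um * 1e-8

    def g_abs_ms(self, channel: str) -> float:
        """Absolute conductance (mS) of one channel over this compartment."""
        return self.channels.get(channel, 0.0) * self.area_cm2

    def axial_half_resistance(self, ra_ohm_cm: float) -> float:
        """Resistance (MOhm... internal units: mV/ms/mS) of half this
        compartment's core, used to couple neighbour midpoints."""
        radius_cm = self.diam_um * 1e-4 / 2.0
        half_len_cm = self.length_um * 1e-4 / 2.0
        r_ohm = ra_ohm_cm * half_len_cm / (math.pi * radius_cm**2)
        return r_ohm * 1e-3  # Ohm -> kOhm so that 1/r is in mS


def axial_conductance_ms(a: Compartment, b: Compartment, ra_ohm_cm: float) -> float:
    """Series axial conductance (mS) between midpoints of two neighbours."""
    return 1.0 / (a.axial_half_resistance(ra_ohm_cm) + b.axial_half_resistance(ra_ohm_cm))


@dataclass(frozen=True)
class CationSubstitution:
    """Ohmic cation current replacing I_NaP to ablate STOs.

    I_CAT = g_CAT (v - E_CAT) is added to every compartment that carried
    I_NaP, with the conductance chosen to preserve MC firing rates.
    """

    g_cat_ms_cm2: float = 0.26
    e_cat_mv: float = 0.0


@dataclass
class MitralCell:
    soma: Compartment
    tuft: Compartment
    dendrite: list[Compartment]  # exactly 7, proximal -> distal, 500 um total
    ra_ohm_cm: float = 70.0
    tau_ks_ms: float = 10.0
    spike_shift_mv: float = 10.0  # depolarizing shift of Na/Kdr kinetics
    e_na_mv: float = 50.0
    e_k_mv: float = -90.0
    e_cat_mv: float = 0.0
    #: sigmoid parameters of the NaP and KS activation curves
    nap_vhalf_mv: float = -50.0
    nap_k_mv: float = 5.0
    ks_vhalf_mv: float = -45.0
    ks_k_mv: float = 7.0
    #: slow spike-triggered AHP (K+) current: gate charges at suprathreshold
    #: voltages with tau_on and relaxes with tau_off, pacing sparse spiking
    ahp_vhalf_mv: float = -20.0
    ahp_k_mv: float = 5.0
    ahp_tau_on_ms: float = 5.0
    ahp_tau_off_ms: float = 150.0
    sto_kinetics: str = "default"  # "default" | "fast"

    def __post_init__(self) -> None:
        if len(self.dendrite) != N_DENDRITE_COMPARTMENTS:
            raise ConfigurationError(
                f"dendrite must have {N_DENDRITE_COMPARTMENTS} compartments, got {len(self.dendrite)}"
            )
        if self.tau_ks_ms <= 0:
            raise ConfigurationError(f"tau_ks_ms must be > 0, got {self.tau_ks_ms}")

    @property
    def has_nap(self) -> bool:
        return any(c.channels.get("nap", 0.0) > 0 for c in self.compartments())

    def compartments(self) -> list[Compartment]:
        """Ordered root-first: soma, tuft, dendrite 1..7."""
        return [self.soma, self.tuft, *self.dendrite]

    def parents(self) -> list[int]:
        """Parent index per compartment (soma is the root)."""
        return [-1, 0, 0] + list(range(2, 2 + N_DENDRITE_COMPARTMENTS - 1))

    def axial_conductances(self) -> list[float]:
        comps = self.compartments()
        return [0.0] + [
            axial_conductance_ms(comps[i], comps[p], self.ra_ohm_cm)
            for i, p in enumerate(self.parents())
            if p >= 0
        ]


@dataclass
class GranuleCell:
    body: Compartment
    spine_template: Compartment  # one instance per MC contact
    neck_g_ns: float = 2.0
    spike_shift_mv: float = 10.0
    ahp_tau_off_ms: float = 150.0
    e_na_mv: float = 50.0
    e_k_mv: float = -90.0

    def make_spines(self, n: int) -> list[Compartment]:
        return [replace(copy.deepcopy(self.spine_template), name=f"spine{k}") for k in range(n)]


@dataclass
class PeriglomerularCell:
    body: Compartment
    spine: Compartment
    neck_g_ns: float = 2.0
    spike_shift_mv: float = 10.0
    ahp_tau_off_ms: float = 150.0
    e_na_mv: float = 50.0
    e_k_mv: float = -90.0


# ---------------------------------------------------------------------------
# Parameter file
# ---------------------------------------------------------------------------


def load_cell_params(path: str | Path | None = None) -> dict:
    """Load and validate the cell parameter file (YAML key-value schema)."""
    if path is None:
        text = resources.files("obnet").joinpath("parameters.yaml").read_text()
    else:
        text = Path(path).read_text()
    params = yaml.safe_load(text)
    for cell in ("mitral", "granule", "periglomerular"):
        if cell not in params:
            raise ConfigurationError(f"parameter file missing section {cell!r}")
    return params


def _compartment_from(params: dict, name: str) -> Compartment:
    try:
        return Compartment(
            name=name,
            length_um=params["length_um"],
            diam_um=params["diam_um"],
            cm_uf_cm2=params.get("cm_uf_cm2", 1.0),
            channels=dict(params.get("channels", {})),
            e_leak_mv=params.get("e_leak_mv", -65.0),
        )
    except KeyError as exc:
        raise ConfigurationError(f"{name}: missing field {exc.args[0]!r}") from exc


def build_mitral_cell(params: dict | None = None) -> MitralCell:
    """Construct an MC from a parameter set (defaults from parameters.yaml)."""
    if params is None:
        params = load_cell_params()
    p = params["mitral"]
    dend = p["dendrite"]
    n = int(dend.get("n", N_DENDRITE_COMPARTMENTS))
    seg_len = dend.get("total_length_um", DENDRITE_LENGTH_UM) / n
    seg = dict(dend)
    seg.pop("n", None)
    seg.pop("total_length_um", None)
    seg["length_um"] = seg_len
    dendrite = [_compartment_from(seg, f"dend{k + 1}") for k in range(n)]
    return MitralCell(
        soma=_compartment_from(p["soma"], "soma"),
        tuft=_compartment_from(p["tuft"], "tuft"),
        dendrite=dendrite,
        ra_ohm_cm=p.get("ra_ohm_cm", 70.0),
        tau_ks_ms=p.get("tau_ks_ms", 10.0),
        spike_shift_mv=p.get("spike_shift_mv", 10.0),
        e_na_mv=p.get("e_na_mv", 50.0),
        e_k_mv=p.get("e_k_mv", -90.0),
        nap_vhalf_mv=p.get("nap_vhalf_mv", -50.0),
        nap_k_mv=p.get("nap_k_mv", 5.0),
        ks_vhalf_mv=p.get("ks_vhalf_mv", -45.0),
        ks_k_mv=p.get("ks_k_mv", 7.0),
        ahp_vhalf_mv=p.get("ahp_vhalf_mv", -20.0),
        ahp_k_mv=p.get("ahp_k_mv", 5.0),
        ahp_tau_on_ms=p.get("ahp_tau_on_ms", 5.0),
        ahp_tau_off_ms=p.get("ahp_tau_off_ms", 150.0),
    )


def build_granule_cell(params: dict | None = None) -> GranuleCell:
    if params is None:
        params = load_cell_params()
    p = params["granule"]
    return GranuleCell(
        body=_compartment_from(p["body"], "body"),
        spine_template=_compartment_from(p["spine"], "spine"),
        neck_g_ns=p.get("neck_g_ns", 2.0),
        spike_shift_mv=p.get("spike_shift_mv", 10.0),
        ahp_tau_off_ms=p.get("ahp_tau_off_ms", 150.0),
        e_na_mv=p.get("e_na_mv", 50.0),
        e_k_mv=p.get("e_k_mv", -90.0),
    )


def build_periglomerular_cell(params: dict | None = None) -> PeriglomerularCell:
    if params is None:
        params = load_cell_params()
    p = params["periglomerular"]
    return PeriglomerularCell(
        body=_compartment_from(p["body"], "body"),
        spine=_compartment_from(p["spine"], "spine"),
        neck_g_ns=p.get("neck_g_ns", 2.0),
        spike_shift_mv=p.get("spike_shift_mv", 10.0),
        e_na_mv=p.get("e_na_mv", 50.0),
        e_k_mv=p.get("e_k_mv", -90.0),
    )


# ---------------------------------------------------------------------------
# Cell-level manipulations
# ---------------------------------------------------------------------------


def substitute_nap_with_cat(
    cell: MitralCell, sub: CationSubstitution = CationSubstitution()
) -> MitralCell:
    """Replace I_NaP with an ohmic cation current in every compartment that
    carried it (the STO-ablation manipulation).  The cation conductance is
    sized to preserve the MC firing rate at matched current injections."""
    if not cell.has_nap:
        raise ConfigurationError("cell has no I_NaP (substitution already applied?)")
    out = copy.deepcopy(cell)
    for comp in out.compartments():
        if comp.channels.get("nap", 0.0) > 0:
            comp.channels["nap"] = 0.0
            comp.channels["cat"] = sub.g_cat_ms_cm2
    out.e_cat_mv = sub.e_cat_mv
    return out


def cation_current_ua_cm2(v_mv: float, sub: CationSubstitution) -> float:
    """I_CAT = g_CAT (v - E_CAT), in uA/cm^2 (negative = inward)."""
    return sub.g_cat_ms_cm2 * (v_mv - sub.e_cat_mv)


FAST_STO_TAU_KS_MS = 5.0
FAST_STO_GKS_FACTOR = 1.6
FAST_STO_GNAP_FACTOR = 1.3


def set_fast_sto_kinetics(cell: MitralCell) -> MitralCell:
    """Speed up the intrinsic STO: tau_KS 10 -> 5 ms, g_KS x1.6, g_NaP x1.3.

    The conductance scalings keep STO amplitude and firing rate roughly
    unchanged while raising the intrinsic frequency from ~29 to ~44 Hz.
    """
    if cell.sto_kinetics == "fast":
        raise ConfigurationError("fast STO kinetics already applied")
    out = copy.deepcopy(cell)
    out.tau_ks_ms = FAST_STO_TAU_KS_MS
    for comp in out.compartments():
        if "ks" in comp.channels:
            comp.channels["ks"] *= FAST_STO_GKS_FACTOR
        if "nap" in comp.channels:
            comp.channels["nap"] *= FAST_STO_GNAP_FACTOR
    out.sto_kinetics = "fast"
    return out


def set_default_sto_kinetics(cell: MitralCell) -> MitralCell:
    """Invert the fast-STO modification (round trip back to defaults)."""
    if cell.sto_kinetics != "fast":
        raise ConfigurationError("cell is not in fast-STO configuration")
    out = copy.deepcopy(cell)
    out.tau_ks_ms = 10.0
    for comp in out.compartments():
        if "ks" in comp.channels:
            comp.channels["ks"] /= FAST_STO_GKS_FACTOR
        if "nap" in comp.channels:
            comp.channels["nap"] /= FAST_STO_GNAP_FACTOR
    out.sto_kinetics = "default"
    return out
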