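"""Torus geometry, cell placement, and dendrodendritic wiring.

The model olfactory bulb is a 1 mm x 1 mm sheet wrapped onto a torus.
Mitral cells (MCs) and their column-paired periglomerular cells (PGCs) sit
on one square grid, granule cells (GCs) on a finer grid over the same
domain.  Each MC forms a reciprocal dendrodendritic contact with each GC
independently with probability p (default 0.3); the contact sits on one of
the seven MC lateral-dendrite compartments, chosen by the toroidal
soma-to-GC distance.  Each MC additionally pairs with exactly one PGC (its
own column) at the tuft.

When the GC population is scaled up, per-synapse GC->MC conductances are
scaled by 100 / n_gc so the expected total GABA_A conductance per MC is
size-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO

import numpy as np
import pandas as pd

N_DENDRITE_COMPARTMENTS = 7
#: Maximal toroidal distance on the unit torus (mm): sqrt(2)/2.
D_MAX_MM = float(np.sqrt(2.0) / 2.0)


@dataclass(frozen=True)
class NetworkConfig:
    """Population sizes, geometry, and wiring parameters."""

    n_mc: int = 25
    n_gc: int = 100
    p_connect: float = 0.3
    domain_mm: float = 1.0
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("n_mc", "n_gc"):
            n = getattr(self, name)
            root = int(round(np.sqrt(n)))
            if root * root != n:
                raise ValueError(f"{name} must be a perfect square, got {n}")
        if not 0.0 <= self.p_connect <= 1.0:
            raise ValueError(f"p_connect must lie in [0, 1], got {self.p_connect}")

    @property
    def n_pgc(self) -> int:
        return self.n_mc

    @property
    def mc_grid(self) -> int:
        return int(round(np.sqrt(self.n_mc)))

    @property
    def gc_grid(self) -> int:
        return int(round(np.sqrt(self.n_gc)))

    @property
    def inhibition_scale(self) -> float:
        """Per-synapse GC->MC conductance scale: 100 / n_gc."""
        return scale_inhibition_for_size(self.n_gc)

    def seed_streams(self) -> dict[str, np.random.Generator]:
        """Named independent RNG sub-streams derived from the master seed.

        Separate streams for connectivity, odor draws, and background noise
        let sweeps hold the wiring fixed while varying the noise.
        """
        ss = np.random.SeedSequence(self.seed)
        kids = ss.spawn(3)
        return {
            "connectivity": np.random.default_rng(kids[0]),
            "odor": np.random.default_rng(kids[1]),
            "noise": np.random.default_rng(kids[2]),
        }


def scale_inhibition_for_size(n_gc: int) -> float:
    if n_gc <= 0:
        raise ValueError(f"n_gc must be > 0, got {n_gc}")
    return 100.0 / n_gc


def flatten_index(i: int, j: int, n: int) -> int:
    """1-based linear id z = N*i + j + 1 for grid cell (column i, row j)."""
    if not (0 <= i < n and 0 <= j < n):
        raise ValueError(f"grid index ({i}, {j}) out of range for N={n}")
    return n * i + j + 1


def grid_positions(n: int, domain_mm: float = 1.0) -> np.ndarray:
    """Positions (mm) of an n x n grid with equal spacing, cell-centred.

    Cell (i, j) sits at ((i + 0.5)/n, (j + 0.5)/n) * domain; rows ordered
    by the z = n*i + j + 1 linear id.
    """
    idx = np.arange(n * n)
    i, j = divmod(idx, n)
    return np.column_stack(((i + 0.5) / n, (j + 0.5) / n)) * domain_mm


def toroidal_distance(a, b, domain_mm: float = 1.0) -> np.ndarray | float:
    """Euclidean distance with per-axis wraparound on the torus."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    delta = np.abs(a - b)
    delta = np.minimum(delta, domain_mm - delta)
    d = np.sqrt((delta**2).sum(axis=-1))
    return float(d) if d.ndim == 0 else d


def dendritic_compartment_for_distance(
    d_mm, d_max_mm: float = D_MAX_MM
) -> np.ndarray | int:
    """Map soma-to-GC distance to a lateral-dendrite compartment (1..7).

    [0, d_max] is partitioned into 7 equal bins; the mapping is monotone
    non-decreasing so nearby GCs contact proximal compartments and the
    most distant contact the 500 um tip.
    """
    d = np.asarray(d_mm, dtype=float)
    if np.any(d < 0) or np.any(d > d_max_mm * (1 + 1e-12)):
        raise ValueError(f"distance outside [0, {d_max_mm}]: {d_mm}")
    comp = np.minimum(
        (d / d_max_mm * N_DENDRITE_COMPARTMENTS).astype(int) + 1,
        N_DENDRITE_COMPARTMENTS,
    )
    return int(comp) if comp.ndim == 0 else comp


@dataclass
class ConnectionTable:
    """Reciprocal MC-GC contacts plus the MC-PGC column pairing.

    Each MC-GC row is one reciprocal dendrodendritic contact: an excitatory
    MC->GC site and a graded inhibitory GC->MC site at the same
    (mc, gc, compartment, spine) tuple.  ``spine`` numbers the GC's spines
    (one per contact, 0-based within each GC).
    """

    mc_id: np.ndarray  # 1-based MC linear ids
    gc_id: np.ndarray  # 1-based GC linear ids
    compartment: np.ndarray  # MC dendritic compartment 1..7
    distance_mm: np.ndarray
    spine: np.ndarray  # per-GC spine index, 0-based
    mc_pgc_pairs: np.ndarray  # shape (n_mc, 2): (mc_id, pgc_id), identical columns

    @property
    def n_contacts(self) -> int:
        return self.mc_id.size

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mc_id": self.mc_id,
                "gc_id": self.gc_id,
                "compartment": self.compartment,
                "distance_mm": self.distance_mm,
                "spine": self.spine,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, n_mc: int = 25) -> "ConnectionTable":
        df = pd.read_csv(path)
        ids = np.arange(1, n_mc + 1)
        return cls(
            mc_id=df["mc_id"].to_numpy(),
            gc_id=df["gc_id"].to_numpy(),
            compartment=df["compartment"].to_numpy(),
            distance_mm=df["distance_mm"].to_numpy(),
            spine=df["spine"].to_numpy(),
            mc_pgc_pairs=np.column_stack((ids, ids)),
        )


def build_connections(
    cfg: NetworkConfig, rng: np.random.Generator | None = None
) -> ConnectionTable:
    """Wire the network: Bernoulli(p) MC-GC contacts, column MC-PGC pairs.

    Deterministic given the config's connectivity seed stream.  Contacts
    are at most one per MC-GC pair; the dendritic compartment is assigned
    from the toroidal MC-soma-to-GC distance.
    """
    if rng is None:
        rng = cfg.seed_streams()["connectivity"]
    mc_pos = grid_positions(cfg.mc_grid, cfg.domain_mm)
    gc_pos = grid_positions(cfg.gc_grid, cfg.domain_mm)

    # pairwise toroidal distances, shape (n_mc, n_gc)
    dist = toroidal_distance(mc_pos[:, None, :], gc_pos[None, :, :], cfg.domain_mm)
    mask = rng.random((cfg.n_mc, cfg.n_gc)) < cfg.p_connect
    mc_idx, gc_idx = np.nonzero(mask)

    d = dist[mc_idx, gc_idx]
    comp = dendritic_compartment_for_distance(d, D_MAX_MM * cfg.domain_mm)

    # number each GC's spines 0..k-1 in contact order
    order = np.argsort(gc_idx, kind="stable")
    spine = np.empty_like(gc_idx)
    counts = np.bincount(gc_idx, minlength=cfg.n_gc)
    starts = np.concatenate(([0], np.cumsum(counts)))
    within = np.arange(gc_idx.size) - np.repeat(starts[:-1], counts)
    spine[order] = within

    ids = np.arange(1, cfg.n_mc + 1)
    return ConnectionTable(
        mc_id=mc_idx + 1,
        gc_id=gc_idx + 1,
        compartment=np.asarray(comp),
        distance_mm=d,
        spine=spine,
        mc_pgc_pairs=np.column_stack((ids, ids)),
    )
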