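"""Afferent drive: sigmoidal OSN odor input and Poisson background excitation.

Each glomerular column receives an olfactory-sensory-neuron current

    I_OSN(t) = u0 + 0.5 (u_s - u0) [tanh(3 (t - t_orn) / r - 3) + 1]

rising from a baseline ``u0`` (pure-air input) to a steady state ``u_s``
around odor onset ``t_orn``; ``r`` sets the transition rate.  Per-column
values of u0 and u_s are drawn from uniform distributions, producing the
heterogeneous afferent activation pattern that constitutes a simulated
odorant.  The same column timecourse drives both the mitral-cell tuft and
the column's periglomerular cell.

All cells additionally receive uncorrelated Poisson trains of AMPA-like
conductance events (instantaneous step, 5.5 ms exponential decay),
representing unspecific background excitation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class OdorInput:
    """Per-column odor drive parameters (arrays of length n_columns)."""

    u0_na: np.ndarray  # baseline current, nA
    us_na: np.ndarray  # steady-state current, nA
    r: float = 100.0  # transition-rate parameter
    t_orn_ms: float = 500.0  # odor-onset time

    def __post_init__(self) -> None:
        self.u0_na = np.atleast_1d(np.asarray(self.u0_na, dtype=float))
        self.us_na = np.atleast_1d(np.asarray(self.us_na, dtype=float))
        if self.u0_na.shape != self.us_na.shape:
            raise ValueError("u0_na and us_na must have matching shapes")

    @property
    def n_columns(self) -> int:
        return self.u0_na.size


def osn_current(t_ms, odor: OdorInput) -> np.ndarray:
    """Evaluate the OSN drive (nA) at time(s) ``t_ms`` for every column.

    Returns an array of shape ``t.shape + (n_columns,)``; continuous and,
    for u_s > u0, non-decreasing in t with limits u0 and u_s.
    """
    t = np.asarray(t_ms, dtype=float)
    ramp = 0.5 * (np.tanh(3.0 * (t[..., None] - odor.t_orn_ms) / odor.r - 3.0) + 1.0)
    return odor.u0_na + (odor.us_na - odor.u0_na) * ramp


def draw_odor_pattern(
    n_columns: int,
    rng: np.random.Generator,
    u0_bounds: tuple[float, float] = (0.1, 0.2),
    us_bounds: tuple[float, float] = (0.2, 1.0),
    r: float = 100.0,
    t_orn_ms: float = 500.0,
) -> OdorInput:
    """Draw independent uniform (u0, u_s) pairs for each column.

    The u_s bounds are the sweep handles for input-heterogeneity studies
    (upper bound varied over {0.4, 0.6, 0.8, 1.0} nA, lower bound over
    {0.2, 0.4, 0.6, 0.8} nA).
    """
    u0_lo, u0_hi = u0_bounds
    us_lo, us_hi = us_bounds
    if not u0_lo < u0_hi:
        raise ValueError(f"invalid u0 bounds: {u0_bounds}")
    if not us_lo < us_hi:
        raise ValueError(f"invalid u_s bounds: {us_bounds}")
    return OdorInput(
        u0_na=rng.uniform(u0_lo, u0_hi, size=n_columns),
        us_na=rng.uniform(us_lo, us_hi, size=n_columns),
        r=r,
        t_orn_ms=t_orn_ms,
    )


@dataclass(frozen=True)
class BackgroundNoise:
    """Parameters of the per-cell Poisson background excitation.

    Rates and event amplitudes are calibrated (not taken from a printed
    table) so that granule cells fire at roughly 1 Hz with no odor present
    while mitral cells show only sparse spontaneous spiking.
    """

    rate_hz: float
    g_jump_ns: float
    tau_decay_ms: float = 5.5

    def __post_init__(self) -> None:
        if self.rate_hz < 0:
            raise ValueError(f"rate_hz must be >= 0, got {self.rate_hz}")
        if self.g_jump_ns < 0:
            raise ValueError(f"g_jump_ns must be >= 0, got {self.g_jump_ns}")


def poisson_background(
    noise: BackgroundNoise,
    duration_ms: float,
    rng: np.random.Generator,
    n_cells: int = 1,
) -> list[np.ndarray]:
    """Homogeneous Poisson event times (ms) for each of ``n_cells`` cells.

    Trains are drawn independently per cell ("uncorrelated").  Each event
    later produces an instantaneous AMPA-like conductance step decaying
    with ``tau_decay_ms``.
    """
    rate_per_ms = noise.rate_hz * 1e-3
    trains: list[np.ndarray] = []
    for _ in range(n_cells):
        if rate_per_ms == 0.0:
            trains.append(np.empty(0))
            continue
        n = rng.poisson(rate_per_ms * duration_ms)
        trains.append(np.sort(rng.uniform(0.0, duration_ms, size=n)))
    return trains
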