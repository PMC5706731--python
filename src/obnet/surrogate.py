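"""Surrogate recordings with known ground truth for validating the analysis.

A surrogate replaces the simulator output with construction-controlled
signals: MC "somatic voltages" are a sinusoid at a chosen oscillation
frequency plus white noise, and spike times are drawn so their phases
within the oscillation cycle follow a von Mises distribution with a chosen
concentration and preferred phase.  Analysis metrics (peak frequency,
synchronization index, rates) can then be checked against the parameters
that generated the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .recording import Recording


@dataclass(frozen=True)
class SurrogateSpec:
    freq_hz: float = 32.4
    rate_hz: float = 14.0  # per-cell mean spike rate
    concentration: float = 2.0  # von Mises kappa; 0 = uniform phases
    preferred_phase: float = 0.0  # radians, 0 = at the sLFP peak
    n_cells: int = 25
    duration_ms: float = 3000.0
    noise_mv: float = 0.1  # white-noise SD added to each trace
    amplitude_mv: float = 1.0
    sample_dt_ms: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate_hz < 0:
            raise ValueError(f"rate_hz must be >= 0, got {self.rate_hz}")
        if self.duration_ms <= 0:
            raise ValueError(f"duration_ms must be > 0, got {self.duration_ms}")
        if self.concentration < 0:
            raise ValueError(f"concentration must be >= 0, got {self.concentration}")


def make_surrogate_recording(spec: SurrogateSpec) -> Recording:
    """Build a Recording whose oscillation frequency, locking strength and
    rates are known by construction.

    The cosine trace peaks at t = k / f, so a spike with cycle phase phi
    is placed at t = (k + phi / 2pi) / f, matching the phase convention
    (phi = 0 at the sLFP peak).
    """
    rng = np.random.default_rng(spec.seed)
    t = np.arange(int(spec.duration_ms / spec.sample_dt_ms)) * spec.sample_dt_ms
    carrier = spec.amplitude_mv * np.cos(2 * np.pi * spec.freq_hz * t * 1e-3)
    traces = carrier + rng.normal(0.0, spec.noise_mv, size=(spec.n_cells, t.size))

    period_ms = 1000.0 / spec.freq_hz
    n_cycles = int(spec.duration_ms / period_ms)
    trains: list[np.ndarray] = []
    for _ in range(spec.n_cells):
        n_spikes = rng.poisson(spec.rate_hz * spec.duration_ms * 1e-3)
        cycles = rng.integers(0, n_cycles, size=n_spikes)
        if spec.concentration == 0.0:
            phi = rng.uniform(0.0, 2 * np.pi, size=n_spikes)
        elif np.isinf(spec.concentration):
            phi = np.full(n_spikes, spec.preferred_phase)
        else:
            phi = stats.vonmises.rvs(
                spec.concentration,
                loc=spec.preferred_phase,
                size=n_spikes,
                random_state=rng,
            )
        phi = np.mod(phi, 2 * np.pi)
        times = np.unique((cycles + phi / (2 * np.pi)) * period_ms)
        trains.append(times)

    return Recording(
        spikes={"MC": trains, "GC": [], "PGC": []},
        mc_voltage=traces,
        sample_dt_ms=spec.sample_dt_ms,
        meta={"surrogate": True, "spec": spec.__dict__.copy()},
    )


def expected_si(concentration: float) -> float:
    """Population vector strength implied by a von Mises phase distribution:
    the mean resultant length R = I1(kappa) / I0(kappa)."""
    from scipy.special import i0, i1

    if concentration == 0.0:
        return 0.0
    if np.isinf(concentration):
        return 1.0
    return float(i1(concentration) / i0(concentration))
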