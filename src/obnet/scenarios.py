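"""Scenario registry, multi-seed runner, and parameter sweeps.

Every manipulation studied with this model is a named scenario: a set of
config-key overrides applied to the default (control) network.  Metrics
(population firing rates, sLFP spectral peak frequency and power,
synchronization index) are computed per seed and averaged; the oscillation
index of a condition is its mean sLFP peak power normalized to the largest
peak power among the control seeds of the same study.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis
from .engine import SimulationConfig, SimulationDiverged, run_simulation
from .recording import Recording

logger = logging.getLogger("obnet")

DEFAULT_SEEDS = tuple(range(1, 11))
QUICK_SEEDS = tuple(range(1, 6))

#: Named manipulations (overrides relative to the control configuration).
SCENARIOS: dict[str, dict] = {
    "control": {},
    "sto_removed": {"sto_removed": True},
    "sto_fast": {"sto_fast": True},
    "sto_fast_fast_gaba": {"sto_fast": True, "tau_decay_gaba": 3.0},
    "fast_gaba": {"tau_decay_gaba": 3.0},
    "slow_gaba": {"tau_decay_gaba": 30.0},
    "pgc_half": {"w_pgc_mc": 2.0},
    "pgc_blocked": {"w_pgc_mc": 0.0},
    "pgc_double": {"w_pgc_mc": 8.0},
    "no_gc_inhibition": {"w_gc_mc": 0.0},
    "wgcmc_3x": {"w_gc_mc": 6.0},
    "wgcmc_3x_pgc_half": {"w_gc_mc": 6.0, "w_pgc_mc": 2.0},
    "wmcgc_half": {"w_mc_gc": 0.5},
    "wmcgc_8x": {"w_mc_gc": 8.0},
    "input_upper_04": {"us_hi": 0.4},
    "input_lower_08": {"us_lo": 0.8},
    "ngc_225": {"n_gc": 225},
    "ngc_400": {"n_gc": 400},
}

#: Sweep value sets used by the corresponding studies.
SWEEPS: dict[str, list[float]] = {
    "tau_decay_gaba": [3.0, 9.0, 15.0, 18.0, 24.0, 30.0],
    "w_gc_mc": [0.0, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0],
    "w_mc_gc": [0.5, 1.0, 2.0, 4.0, 8.0],
    "w_pgc_mc": [0.0, 2.0, 4.0, 6.0, 8.0, 10.0],
    "us_hi": [0.4, 0.6, 0.8, 1.0],
    "us_lo": [0.2, 0.4, 0.6, 0.8],
}


def quick_profile(cfg: SimulationConfig | None = None) -> SimulationConfig:
    """Scaled-down profile: 1.5 s odor, dt = 20 us (5 seeds by default)."""
    cfg = cfg or SimulationConfig()
    return cfg.override(odor_duration_ms=1500.0, dt_ms=0.02)


@dataclass
class ScenarioResult:
    """Per-seed and seed-averaged summary metrics of one condition."""

    name: str
    per_seed: pd.DataFrame  # one row per seed
    overrides: dict = field(default_factory=dict)
    failed_seeds: list[int] = field(default_factory=list)

    METRICS = ("mc_rate_hz", "gc_rate_hz", "pgc_rate_hz", "peak_freq_hz", "si", "peak_power")

    def mean(self, metric: str) -> float:
        return float(self.per_seed[metric].mean())

    def sd(self, metric: str) -> float:
        return float(self.per_seed[metric].std(ddof=1))

    def summary(self) -> dict[str, float]:
        out: dict[str, float] = {"name": self.name, "n_seeds": len(self.per_seed)}
        for m in self.METRICS:
            out[m] = self.mean(m)
            out[m + "_sd"] = self.sd(m)
        return out


def analyze_recording(rec: Recording, window_ms: tuple[float, float]) -> dict:
    """All summary metrics of one run, on the odor analysis window."""
    fs = rec.sample_rate_hz
    slfp_full = analysis.compute_slfp(rec)
    i0 = int(window_ms[0] / rec.sample_dt_ms)
    i1 = int(window_ms[1] / rec.sample_dt_ms)
    slfp = slfp_full[i0:i1]
    spec = analysis.power_spectrum(slfp, fs)
    peaks = analysis.slfp_peak_times(slfp, fs, t0_ms=window_ms[0])
    mc_spikes = np.concatenate(
        [t[(t >= window_ms[0]) & (t < window_ms[1])] for t in rec.spikes["MC"]]
    )
    phases = analysis.spike_phases(mc_spikes, peaks)
    si = analysis.synchronization_index(phases)
    rates = analysis.rates_and_histograms(rec, window_ms, slfp=slfp)
    return {
        "mc_rate_hz": rates.mean_rates_hz.get("MC", 0.0),
        "gc_rate_hz": rates.mean_rates_hz.get("GC", 0.0),
        "pgc_rate_hz": rates.mean_rates_hz.get("PGC", 0.0),
        "peak_freq_hz": spec.peak_freq_hz,
        "peak_power": spec.peak_power,
        "has_dominant_peak": spec.has_dominant_peak,
        "si": np.nan if si is None else si,
        "n_mc_spikes": int(phases.n),
    }


def population_phases(
    rec: Recording, window_ms: tuple[float, float]
) -> dict[str, analysis.PhaseSample]:
    """Spike phases relative to sLFP peaks for each population.

    Used for phase-preference statistics: MC and GC spikes are
    phase-constrained within the gamma cycle while PGC spikes are not.
    """
    slfp_full = analysis.compute_slfp(rec)
    i0 = int(window_ms[0] / rec.sample_dt_ms)
    i1 = int(window_ms[1] / rec.sample_dt_ms)
    peaks = analysis.slfp_peak_times(
        slfp_full[i0:i1], rec.sample_rate_hz, t0_ms=window_ms[0]
    )
    out = {}
    for pop, trains in rec.spikes.items():
        spikes = (
            np.concatenate([t[(t >= window_ms[0]) & (t < window_ms[1])] for t in trains])
            if trains
            else np.empty(0)
        )
        out[pop] = analysis.spike_phases(spikes, peaks)
    return out


def run_scenario(
    name: str,
    seeds: tuple[int, ...] = DEFAULT_SEEDS,
    base: SimulationConfig | None = None,
    overrides: dict | None = None,
    out_dir: str | Path | None = None,
    keep_recordings: bool = False,
) -> ScenarioResult:
    """Run one scenario over a seed batch and summarize it.

    A seed whose simulation diverges is recorded in ``failed_seeds`` and
    excluded (with a warning); the batch continues.
    """
    if name not in SCENARIOS:
        raise KeyError(
            f"unknown scenario {name!r}; registered: {sorted(SCENARIOS)}"
        )
    base = base or SimulationConfig()
    merged = dict(SCENARIOS[name])
    merged.update(overrides or {})
    rows, failed, recs = [], [], []
    for seed in seeds:
        cfg = base.override(seed=int(seed), **merged)
        t0 = time.time()
        try:
            rec = run_simulation(cfg)
        except SimulationDiverged as exc:
            logger.warning("scenario %s seed %d failed: %s", name, seed, exc)
            failed.append(int(seed))
            continue
        row = {"seed": int(seed)} | analyze_recording(rec, cfg.analysis_window_ms)
        row["wall_s"] = time.time() - t0
        row["config_hash"] = cfg.config_hash()
        rows.append(row)
        if keep_recordings:
            recs.append(rec)
    result = ScenarioResult(
        name=name, per_seed=pd.DataFrame(rows), overrides=merged, failed_seeds=failed
    )
    if out_dir is not None:
        _write_artifacts(result, base, out_dir)
    if keep_recordings:
        result.recordings = recs  # type: ignore[attr-defined]
    return result


def sweep(
    param: str,
    values,
    seeds: tuple[int, ...] = DEFAULT_SEEDS,
    base: SimulationConfig | None = None,
    scenario: str = "control",
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """One ScenarioResult row per parameter value, seed-averaged.

    The wiring is shared across values for a given seed index (the
    connectivity stream depends only on the master seed), so the sweep
    isolates the manipulated parameter.
    """
    base = base or SimulationConfig()
    if param not in SimulationConfig.__dataclass_fields__:
        raise KeyError(f"unknown config key {param!r}")
    rows = []
    for val in values:
        if isinstance(val, str):
            raise TypeError(f"non-numeric value {val!r} for key {param!r}")
        res = run_scenario(
            scenario, seeds=seeds, base=base, overrides={param: val}
        )
        row = res.summary()
        row[param] = val
        rows.append(row)
    df = pd.DataFrame(rows)
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        df.to_csv(Path(out_dir) / f"sweep_{param}.csv", index=False)
    return df


def oscillation_indices(
    results: dict[str, ScenarioResult], reference: str = "control"
) -> dict[str, float]:
    """OI per condition, normalized to the max control-seed peak power."""
    ref = results[reference].per_seed["peak_power"].to_numpy()
    return {
        name: analysis.oscillation_index(res.per_seed["peak_power"].to_numpy(), ref)
        for name, res in results.items()
    }


def _write_artifacts(result: ScenarioResult, base: SimulationConfig, out_dir) -> None:
    d = Path(out_dir) / result.name
    d.mkdir(parents=True, exist_ok=True)
    result.per_seed.to_csv(d / "per_seed.csv", index=False)
    with open(d / "summary.json", "w") as fh:
        json.dump(result.summary(), fh, indent=2)
    resolved = base.override(**result.overrides)
    with open(d / "config.json", "w") as fh:
        json.dump(
            {
                "scenario": result.name,
                "overrides": result.overrides,
                "config": resolved.__dict__ | {},
                "config_hash": resolved.config_hash(),
                "failed_seeds": result.failed_seeds,
            },
            fh,
            indent=2,
            default=str,
        )
    logger.info("scenario %s: artifacts in %s", result.name, d)
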