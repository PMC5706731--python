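"""Run output container shared by the simulation engine and surrogates."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

POPULATIONS = ("MC", "GC", "PGC")


@dataclass
class Recording:
    """Spikes and sampled traces from one simulated (or surrogate) run.

    ``spikes`` maps a population name to one array of spike times (ms,
    somatic upward crossings of 0 mV) per cell.  ``mc_voltage`` holds the
    somatic membrane potential of every MC at ``sample_dt_ms`` resolution
    (sample k is at time k * sample_dt_ms).  ``gaba_conductance`` optionally
    holds each MC's cumulative GC-mediated GABA_A conductance (nS) on the
    same time base, and ``extra_traces`` any designated compartment
    voltages.  ``meta`` records config hash, seed, and dt.
    """

    spikes: dict[str, list[np.ndarray]]
    mc_voltage: np.ndarray  # (n_mc, n_samples), mV
    sample_dt_ms: float
    gaba_conductance: np.ndarray | None = None
    extra_traces: dict[str, np.ndarray] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pop, trains in self.spikes.items():
            for k, t in enumerate(trains):
                if t.size > 1 and np.any(np.diff(t) <= 0):
                    raise ValueError(f"spike times not strictly increasing: {pop}[{k}]")

    @property
    def n_samples(self) -> int:
        return self.mc_voltage.shape[1]

    @property
    def duration_ms(self) -> float:
        return self.n_samples * self.sample_dt_ms

    @property
    def sample_rate_hz(self) -> float:
        return 1000.0 / self.sample_dt_ms

    def time_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.sample_dt_ms

    # -- plain-text serialization (one directory per recording) ----------

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        with open(d / "spikes.tsv", "w") as fh:
            fh.write("cell_label\tt_ms\n")
            for pop, trains in self.spikes.items():
                for k, train in enumerate(trains):
                    for t in train:
                        fh.write(f"{pop}_{k + 1}\t{t:.4f}\n")
        header = f"# sample_dt_ms={self.sample_dt_ms}"
        np.savetxt(d / "mc_voltage.tsv", self.mc_voltage.T, header=header, comments="")
        if self.gaba_conductance is not None:
            np.savetxt(
                d / "gaba_conductance.tsv",
                self.gaba_conductance.T,
                header=header,
                comments="",
            )

    @classmethod
    def load(cls, directory) -> "Recording":
        d = Path(directory)
        with open(d / "mc_voltage.tsv") as fh:
            sample_dt = float(fh.readline().split("=")[1])
        mc_voltage = np.loadtxt(d / "mc_voltage.tsv", skiprows=1).T
        mc_voltage = np.atleast_2d(mc_voltage)
        spikes: dict[str, dict[int, list[float]]] = {p: {} for p in POPULATIONS}
        with open(d / "spikes.tsv") as fh:
            next(fh)
            for line in fh:
                label, t = line.split("\t")
                pop, idx = label.rsplit("_", 1)
                spikes[pop].setdefault(int(idx) - 1, []).append(float(t))
        out: dict[str, list[np.ndarray]] = {}
        for pop, by_cell in spikes.items():
            n = max(by_cell, default=-1) + 1
            if pop == "MC":
                n = max(n, mc_voltage.shape[0])
            out[pop] = [np.asarray(by_cell.get(k, []), dtype=float) for k in range(n)]
        gaba = None
        if (d / "gaba_conductance.tsv").exists():
            gaba = np.atleast_2d(np.loadtxt(d / "gaba_conductance.tsv", skiprows=1).T)
        return cls(
            spikes=out,
            mc_voltage=mc_voltage,
            sample_dt_ms=sample_dt,
            gaba_conductance=gaba,
        )
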