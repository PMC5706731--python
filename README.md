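# obnet — olfactory bulb network gamma simulator

`obnet` is a conductance-based simulator of the mammalian olfactory bulb
circuit for studying how odor-evoked gamma-band oscillations arise.  It
implements an inhibition-coupled resonant-oscillator architecture
("pyramidal resonance interneuron network gamma", PRING): mitral cells
(MCs) with intrinsic ~29 Hz subthreshold oscillations (from persistent
Na+ and slow K+ currents) are wired reciprocally to granule cells (GCs)
whose graded dendrodendritic GABA_A inhibition periodically resets the MC
oscillation phase, while periglomerular cells (PGCs) supply feedforward,
intensity-normalizing inhibition at the glomerular tuft.  The package is
aimed at computational neuroscientists who want a compact, reproducible
testbed for gamma oscillogenesis mechanisms (PING vs resonance-based
coupling) and their manipulations.

The model: 25 MC/PGC columns and 100 GCs on a 1 mm x 1 mm torus, each MC
contacting each GC with probability p = 0.3 on a distance-mapped
compartment of its 500 um lateral dendrite.  Synaptic currents follow

    I = W * g_syn * s * B(V) * (V - E_syn),
    ds/dt = alpha * F(V_pre) * (1 - s) - beta * s,

with spike-gated AMPA/NMDA excitation (NMDA carries the Mg2+ block B(V))
and graded GABA_A inhibition (half-activation at -40 mV).  The simulated
LFP is the 10-100 Hz band-passed mean MC somatic potential; spike phase
locking is quantified by the vector-strength synchronization index
kappa = (1/N) |sum_i e^{i phi_i}|.

## Worked example

Run the control odor condition over two seeds at the scaled-down profile
and print the seed-averaged summary:

```bash
obnet run --scenario control --quick --seeds 2 --out runs
```

Library equivalent:

```python
from obnet import scenarios

result = scenarios.run_scenario(
    "control", seeds=(1, 2), base=scenarios.quick_profile()
)
print(result.summary())
```

which prints (abridged):

```
mc_rate_hz    11.8     # mean odor-evoked mitral cell rate (Hz)
gc_rate_hz     4.7     # granule cells spike sparsely, well below gamma
peak_freq_hz  35.0     # dominant sLFP spectral peak, gamma band
si             0.60    # MC spike phase locking to the sLFP (0..1)
```

Despite every MC firing at its own input-determined rate (heterogeneous
drives 0.2-1.0 nA), the population produces one coherent gamma rhythm to
which MC spikes are phase-locked — the core phenomenon the model exists
to explain.  Registered scenarios (`obnet list-scenarios`) cover the full
set of manipulations: STO removal (`sto_removed`), faster STO kinetics
(`sto_fast`), GABA_A decay changes (`fast_gaba`, `slow_gaba`), weight
blocks and scalings (`no_gc_inhibition`, `wmcgc_8x`, `pgc_half`, ...), and
GC population scaling (`ngc_225`, `ngc_400`).  Parameter sweeps:

```bash
obnet sweep --param tau_decay_gaba --quick
```

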