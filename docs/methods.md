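# Methods

## Model overview

`obnet` simulates a reduced olfactory bulb (OB): 25 mitral cells (MCs) and
their 25 column-paired periglomerular cells (PGCs) on a 5x5 grid, and 100
granule cells (GCs) on a 10x10 grid, all on a 1 mm x 1 mm sheet wrapped
onto a torus so that distances and connectivity have no boundary effects.
Each MC connects reciprocally to each GC independently with probability
p = 0.3; the dendrodendritic contact is placed on one of the seven
compartments of the MC's 500 um lateral dendrite according to the toroidal
soma-to-GC distance (seven equal-width distance bins over [0, sqrt(2)/2] mm,
so nearby GCs contact proximal dendrite and the farthest contact the tip).
Each MC also forms one reciprocal synapse with its own column's PGC at the
apical tuft.

The circuit implements an inhibition-coupled resonant-oscillator (PRING)
architecture: MCs are intrinsic subthreshold oscillators; GC-mediated
GABA_A inhibition periodically resets the MC oscillation phase, producing a
network gamma rhythm faster than the intrinsic oscillation and paced
largely by the inhibitory decay time constant.

## Cells

All cells are Hodgkin-Huxley-type compartmental models.  Spiking uses
Traub-Miles Na+/K+ kinetics shifted +10 mV (spike threshold near -42 mV),
which keeps the delayed-rectifier window current out of the subthreshold
range so that the subthreshold dynamics are governed by the currents below.

**Mitral cell** (soma, tuft, 7-compartment 500 um lateral dendrite,
axial resistivity 70 Ohm cm):

- *I_NaP*, persistent sodium: instantaneous sigmoidal activation
  (V1/2 = -50 mV, k = 5 mV), uniform density in all compartments.
- *I_KS*, slow potassium: first-order activation with a fixed time constant
  tau_KS = 10 ms (the resonance timescale), V1/2 = -42.1 mV, k = 5.5 mV.
- *I_AHP*, a slow spike-triggered K+ current: its gate charges only at
  suprathreshold voltages (V1/2 = -20 mV, charge time constant 5 ms) and
  relaxes with ~172 ms (100 ms in GCs).  This current paces sparse spiking: without it the
  cell fires on every subthreshold-oscillation (STO) crest and the
  mixed-mode regime (sparse spikes riding STOs) does not exist.  It plays
  the role of the Ca-dependent/slow K+ machinery of detailed MC models.

The NaP/KS conductance densities, leak, and resting level were calibrated
numerically (random search on the isolated cell) against four anchors:
quiescence with no input; a dominant subthreshold spectral peak at
29 Hz under a sustained 0.2 nA somatic injection (mixed-mode firing
~10 Hz); 44 Hz after the fast-STO modification (tau_KS 10 -> 5 ms,
g_KS x1.6, g_NaP x1.3) with the firing rate preserved within ~10%; and
monotone STO frequency across 0.15/0.2/0.25 nA.  The frozen values live in
`src/obnet/parameters.yaml`.  The subthreshold peak is measured on the
ceiling-clipped (-40 mV) voltage after discarding a 500 ms transient.

Dendritic compartments carry active Na+/K+ densities sufficient for
full-amplitude spike propagation; the 0 mV crossing at the 500 um tip lags
the somatic crossing by ~0.1 ms (< 1 ms), so contact position has little
effect on lateral signaling latency.

**STO ablation.** `substitute_nap_with_cat` replaces I_NaP with an ohmic
cation current I_CAT = g_CAT (v - E_CAT), E_CAT = 0 mV, in every
compartment that carried I_NaP.  The cation conductance is chosen by rate
matching: g_CAT = 0.36 mS/cm^2 reproduces the control f-I curve over
0.1-0.3 nA within ~15% in this parameterization while abolishing the
29 Hz resonance.

**Granule cell**: one spiking body (12 x 10 um) plus one passive spine per
MC contact, coupled through a 1 nS neck conductance.  The body carries the
same AHP mechanism (weaker, 1 mS/cm^2): it caps GC firing under strong
excitation (e.g. 8x MC->GC weight) at near-physiological rates while
leaving the sparse control regime intact.  Body leak and rest were set so
that background noise alone evokes ~1 Hz spontaneous spiking and the
default odor condition evokes ~4-5 Hz.

**Periglomerular cell**: body plus a single spine forming the reciprocal
tuft synapse.  The spine receives a scaled copy of the column's OSN
current, so PGC graded GABA release onto the tuft tracks input intensity —
the feedforward, intensity-normalizing inhibition of the glomerular layer.
PGC spiking is driven by sensory input and noise rather than by the
network rhythm and remains phase-unlocked.

## Synapses

Currents follow I = W g_syn s B(V)(V - E_syn) with first-order gating
ds/dt = alpha F(V_pre)(1 - s) - beta s and the instantaneous release
sigmoid F = 1/(1 + exp(-(V_pre - theta)/sigma)).  Parameters are the
standard set: AMPA g = 2 nS (tau 1/5.5 ms), NMDA g = 1 nS (tau 52/343 ms)
with Mg2+ block B(V) = 1/(1 + [Mg] exp(-0.062 V)/3.57) at [Mg] = 1 mM
(configurable; the physiological convention), GABA_A g = 2 nS
(tau 1.25/18 ms, E = -80 mV).  Excitatory synapses use theta = 0 mV,
sigma = 0.2 mV (spike-gated); GABA_A uses theta = -40 mV, sigma = 2 mV
(graded in the presynaptic subthreshold voltage).  Default weights:
W_MC->PGC = 1, W_MC->GC = 1, W_PGC->MC = 4, W_GC->MC = 2.  The decay
constant override `tau_decay_gaba` applies to the GC->MC synapses (the
manipulated pathway); PGC->MC keeps 18 ms.  When the GC population is
scaled up (225, 400), each GC->MC conductance is multiplied by 100/n_GC so
the expected total inhibition per MC is size-invariant.

Gating is advanced by the exact exponential update for F frozen over one
step, which is unconditionally bounded in [0, 1] for any dt.  There are no
synaptic delays beyond cable propagation.

## Inputs

Odor drive per column: I_OSN(t) = u0 + 0.5 (u_s - u0)[tanh(3(t-t_orn)/r - 3) + 1]
with r = 100 and per-column uniform draws u0 in (0.1, 0.2) nA and u_s in
(0.2, 1.0) nA (both sweepable).  The same column timecourse is injected
into the MC tuft (gain 0.90) and the PGC spine (gain 0.13); the gains are
calibration constants converting the nominal OSN current into effective
drive at each target and were set at the network level (see below).
Background excitation: independent Poisson trains of AMPA-like conductance
steps (100 Hz, 0.4 nS, 5.5 ms decay) onto every soma, calibrated so GCs
fire ~1 Hz spontaneously and MCs show sparse spontaneous spiking.  Neither
rate nor amplitude is printed in the source study; these are declared
model constants.

Protocol: 500 ms pre-odor baseline, odor onset t_orn = 500 ms, odor held
for 2 s (1.5 s in the scaled-down profile); the analysis window is the
odor epoch excluding its first 200 ms.

## Numerics

Fixed-timestep semi-implicit integration: voltages are solved implicitly
along each cell's compartment tree per step (Hines-ordered elimination,
with membrane conductances evaluated at the current state), channel gates
and synaptic open fractions use exponential (Rush-Larsen) updates.  The
scheme is unconditionally stable for the stiff spine-neck couplings.
Default dt = 10 us; the scaled-down profile uses 20 us.  Halving dt leaves
seed-averaged statistics and mean rates essentially unchanged, but the
network is weakly chaotic: the dt-truncation difference acts as a tiny
perturbation that decorrelates individual trajectories within a few
hundred milliseconds, so single-run spectral-peak estimates retain a few
percent of realization scatter between timesteps (the strict
trajectory-level convergence test documents this).  Spikes are somatic
upward crossings of 0 mV with a 2 ms
detection lockout; traces are sampled at 0.5 ms (2 kHz).  Any |V| >
200 mV aborts the run with a diagnostic naming the compartment and time.
All randomness (wiring, odor draws, noise trains) comes from named
sub-streams spawned from one master seed, so wiring can be held fixed
while noise varies, and identical (config, seed, dt) gives bit-identical
spike times.

## Analysis

The simulated LFP is the mean MC somatic potential, band-passed 10-100 Hz
by a zero-phase (forward-backward) FIR filter of ~fs/3 taps.  The power
spectrum is an FFT of the windowed sLFP zero-padded to <= 0.6 Hz bins;
the reported peak frequency refines the in-band argmax by a quadratic fit.
A condition "has a dominant peak" when the ~6 Hz-smoothed in-band spectrum
exceeds twice its median (smoothing suppresses single-bin noise, whose
chi-squared fluctuations would otherwise register as peaks).  MC spikes
are converted to phases by linear interpolation between consecutive sLFP
maxima (phi = 0 at the peak); the synchronization index is the circular
resultant length of those phases, reported as missing (not zero) when
there are no spikes.  The oscillation index of a condition is its mean
sLFP peak power divided by the largest peak power among the control seeds
of the same study.  Phase-preference uniformity (PGC vs MC/GC) is tested
with the Rayleigh statistic.

Surrogate recordings (sinusoidal "voltages" plus von Mises-distributed
spike phases) provide construction-known ground truth for every analysis
metric; round-trip tests recover frequency within one spectral bin and SI
within its sampling interval.

## Network-level calibration

With cell models frozen, two gains were calibrated at the network level:
the MC tuft OSN gain (0.90) and the PGC spine OSN gain (0.13), targeting
the control condition's mean MC rate, GC rate, gamma peak frequency, and
synchronization index simultaneously.  The scaled-down profile used
throughout testing (5 seeds, 1.5 s odor, dt 20 us) reflects the same
conditions at reduced cost; the full profile (10 seeds, 2 s odor,
dt 10 us) is available through the CLI.

## What the synthetic conditions do and do not show

All inputs are generated internally; there is no recorded data anywhere in
the pipeline.  The odor model is a static sigmoid per column — no sniffing
dynamics, receptor chemistry, or trial-to-trial input correlation — and
background activity is homogeneous Poisson.  Passing tests therefore
demonstrate the internal consistency of the circuit mechanism (resonance,
graded inhibition, phase reset, PING-like decay dependence) and the
recovery of stated quantitative anchors under these idealized drives, not
fidelity to any particular experimental recording.

## Known limitations

- Channel kinetics are a standard reduced parameterization calibrated to
  printed anchors, not a reproduction of any specific published channel
  set; trace-level agreement with detailed MC models is not claimed.
- The network operating point is more excitation-dominated than the
  reference dynamics: the inhibition-paced rhythm sits a few Hz above the
  nominal control frequency on some seeds, and conditions that disrupt
  entrainment (fast-STO cells with slow inhibition, very slow GABA decay)
  can settle into subharmonic rhythms rather than pure irregularity.
- GC spines are passive; NMDA spike generation in spines and GC dendritic
  spikes are not modeled.
- The spike-phase algorithm (linear interpolation between sLFP peaks) is a
  declared convention; other phase definitions shift SI slightly.
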