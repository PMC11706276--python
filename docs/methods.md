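# Methods

`navclamp` simulates the biophysical characterization of Na_v_1.2
sodium-channel variants — wild-type plus eleven engineered and pathogenic
mutants, several of which partly or completely lack fast inactivation — and
embeds the variant current in a hybrid axon-initial-segment (AIS) neuron to
study the neuron-scale consequences.  This note describes the models, the
calibration conventions, the numerical choices, and what the synthetic data
do and do not establish.

Units throughout: mV, ms, pA, nS, pF.  Inward current is negative.

## Channel model

Each Na_v_1.2 variant is a conductance-based channel

    I = g_max · m · h · (V − E_Na),         E_Na = +65 mV

with a single activation gate `m` and a single inactivation gate `h`.

**Why m¹ and not m³.**  The variant parameters are measured quantities
defined at the conductance level: the midpoint and slope of the Boltzmann
fit to peak G/G_max.  With a single activation gate the steady-state
conductance curve *is* that Boltzmann, so a simulated activation protocol
analysed through the standard pipeline returns the configured midpoint
without an exponent-induced shift.  An m³ channel whose per-gate midpoint
had been back-shifted would work too, but couples the midpoint to the slope
and makes the parameter file harder to read against the published table.

**Steady states.**

    m_inf(V) = 1 / (1 + exp(−(V − V½,act)/k_act))
    h_inf(V) = p + (1 − p) / (1 + exp((V − V½,inact)/k_inact))

`p = persistent_frac` is the floor of the inactivation gate: the fraction
of conductance that never inactivates.  For fully inactivating channels it
is a small number matched to the measured persistent current; for the
non-inactivating group (N1662D, L1657P, Q1494A, Q1494L) it is a declared
model parameter, 0.8 by default, chosen so that the current remaining 40 ms
into a depolarizing step comfortably exceeds the 50% of peak that defines
the non-inactivating phenotype.  Q1494E (0.3) and Q1494K (0.15) are
intermediate: they inactivate partially and are analysed as such.  Slope
factors are not part of the published characterization; both default to
6 mV (typical neuronal Na_v magnitudes) and every midpoint/τ recovered by
the pipeline is insensitive to k across 4–9 mV (tested).

**Kinetics.**  Gate time constants are model choices anchored to the one
published kinetic quantity, the recovery time constant:

* τ_m(V) = 0.2·τ_act + 0.8·τ_act·σ(−(V − V½,act)/15), with τ_act = 0.05 ms,
  i.e. 0.01–0.05 ms.  Activation must be 1–2 orders of magnitude faster
  than inactivation so that the peak of m·h tracks m_inf; with slower
  activation the peak-conductance activation fit acquires a +1 mV-scale
  bias that varies across variants (measured during design), violating the
  round-trip requirement below.  Because gate updates are exponential-Euler
  (exact for constant V), the very short τ_m costs nothing numerically.
* τ_h(V) is an interpolation in log-τ space: an affine function of a broad
  rising sigmoid (centred at −65 mV, slope 15 mV) plus a bell built from a
  sum of two sigmoids centred on the availability midpoint (half-width
  12 mV, slope 7 mV, gain 4).  The two free affine coefficients are solved
  exactly so that τ_h(−120 mV) equals the published recovery τ and
  τ_h(−10 mV) equals `tau_inact_ms` (default 3.0 ms).  Working in log-τ
  guarantees positivity for any anchor pair.  The bell makes inactivation
  slowest near its own midpoint, as in real channels; its main numerical
  role is to flatten the peak-droop factor across the activation range.

All protocol epochs are long relative to τ_h everywhere they need to be:
the 100-ms prepulse reaches steady state (τ_h ≤ ~12 ms at its slowest), the
20-ms P1 pulse fully develops inactivation, and the persistent measurement
at 40 ms is far beyond the transient.

## Calibration against the measured characterization

Two model parameters are not measured directly and are solved so that the
*simulated measurement* reproduces the measured value, keeping simulation
and analysis self-consistent:

* `g_max`: peak current is linear in it, so one probe run at −10 mV fixes
  it against the published peak current density (cell capacitance defaults
  to 10 pF).
* the persistent floor `p`: the measured persistent percent differs from
  100·p by the peak-droop factor (the transient peak slightly under-reads
  m_inf because h decays during the activation rise) and by the
  availability tail at −10 mV; a two-step secant on the actual simulated
  measurement solves p so that the pipeline returns the published percent.
  Without this, a variant like F1651C (availability midpoint −38.9 mV,
  whose tail at −10 mV is not negligible) would read ~6% instead of 4.86%.

## Voltage-clamp protocols and analysis

Protocols (holding −120 mV, 50 kHz sampling): activation (40-ms steps, −80
to +55 mV in 5-mV increments), steady-state inactivation (100-ms prepulses
−80 to +20 mV, then 20 ms at −10 mV), recovery from fast inactivation
(paired 20-ms pulses to −10 mV separated by a −120 mV interval of 0.1–30 ms,
eleven log-spread intervals), and a 45-ms persistent-current step to −10 mV.
The recovery pulse geometry (20 ms at −10 mV) is a declared choice; the
0.1-ms interval anchors the difference-based analysis below.

Analysis conventions:

* Peak = most negative sample in the step, ignoring the first 0.1 ms
  (capacitive-artifact convention, harmless on clean traces).
* Conductance G = I/(V − V_rev); sweeps within 10 mV of the reversal are
  excluded; G/G_max is fit with a rising Boltzmann.
* Availability curves are normalized to the most hyperpolarized prepulse
  and the non-inactivating floor (availability after the most depolarized
  prepulse) is subtracted and the curve renormalized before the falling
  Boltzmann fit.  For fully inactivating channels this subtraction is a
  numerical no-op; for channels with a floor it is what makes the midpoint
  identifiable at all (without it a 15% floor biases the fitted midpoint by
  ~4 mV).
* Persistent current: 100·I(40 ms)/I_peak on the −10 mV sweep; values
  ≥ 50% are flagged ND instead of reported as a number.
* Recovery: *standard* mode fits I/I_max = 1 − exp(−t/τ) to P2/P1 peak
  ratios.  *Inactivated-fraction* mode takes the P1−P2 peak difference,
  normalizes its recovery to the 0.1-ms reference interval and fits the
  same exponential anchored at that reference, y = 1 − exp(−(t − 0.1)/τ) —
  the exact closed form of the normalized difference signal.  The package
  defaults to the difference mode whenever the floor is ≥ 2%, because the
  P2/P1 ratio then never starts from zero availability and the plain fit is
  biased low by 8–29% (measured); the difference signal is exactly
  exponential for any floor.
* Boltzmann fits are initialized from the half-maximum crossing, bounded
  (k ∈ [0.1, 50]), and rejected as `FitError` when the data are flat, the
  residual indicates a noise-dominated signal, or the fitted midpoint falls
  outside the sampled range.  Exponential fits initialize τ by log-linear
  regression of 1 − y.

**Round-trip requirement.**  For every packaged variant the full
simulate-then-analyse chain recovers the configured activation and
availability midpoints within 1 mV, the recovery τ within 10%, and (after
floor calibration) the persistent percent within the published precision.
With the kinetic defaults above the worst activation-midpoint error across
all twelve variants is 0.28 mV, and halving the 0.02-ms sampling step moves
every fitted parameter by < 0.1%.

## Hybrid AIS neuron (virtual dynamic clamp)

A single compartment (c_m = 20 pF, leak 0.4 nS to −75 mV) carries an
in-silico delayed-rectifier K⁺ conductance (n⁴), an in-silico Na_v_1.6
conductance (m³h), and the "external" Na_v_1.2 variant current produced by
the same channel model used in voltage clamp, scaled by `na12_fraction` of
a wild-type-equivalent reference conductance (7.014 nS, set so that a 0.2
fraction of N1662D delivers ~80 pA of peak current).  The dynamic-clamp
settings double the Kv base conductance and use 0.4 of the Na_v_1.6 base.

The frozen default parameters are the product of a deliberate calibration
against the qualitative phenotypes the model is asked to show, and several
choices deserve explanation:

* **Input resistance (leak 0.4 nS).**  A +12 pA step must passively carry
  the membrane from −75 mV into the −45 mV range where the Na_v_1.2
  activation foot can ignite a regenerative plateau; with a 1-nS leak the
  non-inactivating plateau can never start within the ±24 pA stimulus
  family.
* **High-threshold Kv (n-gate midpoint −5 mV, slope 5 mV).**  The Kv must
  be silent at the Na_v_1.2 plateau (−20…−8 mV) so that 25–80 pA of
  non-inactivating current can hold a depolarized plateau, yet strong at
  spike voltages so that action potentials repolarize and the plateau is
  capped below 0 mV (no spurious spike detections during plateau onset).
* **Slowly deactivating Kv (τ_n ≈ 4 ms when open, ~50 ms near −50 mV).**
  The loaded conductance carries the post-spike trajectory down through the
  −45…−30 mV corridor (where n⁴ has no steady-state opening and nothing
  else repolarizes) and its slow decay is the inter-spike clock.
* **Na_v_1.6** activates at −48 mV per gate (conductance midpoint ≈ −40 mV)
  so that rheobase (~4 pA) falls inside the stimulus family; its steep
  inactivation (midpoint −50 mV, slope 3.5 mV) keeps the window current at
  −35…−25 mV in the single-pA range, below the leak's restoring margin, so
  firing does not latch into depolarization block at moderate stimuli.
  Recovery from inactivation is slow (up to ~30 ms) around the −55…−70 mV
  inter-spike dwell, which caps the input–output relation: at the largest
  steps availability erodes and firing collapses into a depolarized
  quiescent state — the bell-shaped input–output relation familiar from
  dynamic-clamp recordings.

Integration is exponential-Euler for the gates and for the voltage (V
relaxes each step toward the instantaneous conductance-weighted reversal),
dt = 0.02 ms.  Spikes are upward 0-mV crossings separated by ≥ 2 ms.
"Sustained depolarization" means the mean V_m over the final 200 ms of the
step exceeds −30 mV with no spikes in the final 500 ms; both window lengths
and the −30 mV level are operational definitions.

**What the model reproduces** (all under the frozen defaults): a
non-inactivating variant alone produces a sustained depolarized plateau
with zero spikes; the plateau level grows monotonically with the
implemented fraction (Pearson r ≈ 0.99 over 0.1–0.4); Na_v_1.6 alone fires
repetitively across the stimulus family; a 0.1 fraction of N1662D raises
firing at several amplitudes (most visibly by rescuing firing at steps
where Na_v_1.6 alone collapses); a 0.2 fraction transitions, at the largest
step, from firing into sustained depolarization; wild-type current never
produces a plateau at any fraction.

**Known limitations.**  Two phenotypes of the reduced three-conductance
model fall short of their physiological counterparts.  (i) Spike-frequency
adaptation is marginal: with only a non-inactivating n⁴ Kv and an m³h
Na_v_1.6, every candidate adaptation variable either reloads fully each
spike cycle or, in the Kv-clocked firing regime the other phenotypes
require, shortens rather than lengthens the inter-spike intervals.  The
default model shows non-shortening, weakly increasing intervals near
rheobase, and the test suite asserts exactly that, no more.  (ii) The
still-inactivating gain-of-function variants (F1651C, M1501V/T, P1658S,
A1659V) do not fire measurably more than wild-type at matched conductance:
their depolarized availability and enlarged persistent current increase
both the spike-triggered Kv reload (slowing the clock) and the inter-spike
drive (speeding it) with near-cancelling net effect.  The corresponding
test states the expected phenotype and currently fails; reproducing it
likely requires the richer channel repertoire (slow K⁺ components,
Markov-state Na gating) of a full AIS model, which is outside this
package's scope.  Quantitative voltages and frequencies of the hybrid
neuron are not claims of this package at all — only the qualitative
phenotypes listed above are.

## Synthetic data

`synthetic.sample_cells` draws per-cell parameter sets from independent
normals centred on the packaged means with population SD = SEM·√n
reconstructed from the published errors (SEM and n are published; the SD is
not).  Per-cell parameter correlations are unknown and not modelled.
`add_recording_noise` adds white Gaussian current noise filtered with a
4-pole Butterworth low-pass at the 10-kHz acquisition cut-off (zero-phase);
the post-filter SD equals σ times the filter's noise gain, which the test
suite verifies against the filter coefficients.  The generator does not
emulate capacitive transients, seal leak, series-resistance error or −P/4
subtraction — synthetic traces are ideal leak-free channel currents plus
noise — so parameter-recovery results bound estimator behaviour under
noise and biological spread, not under uncorrected recording artifacts.

`recovery_experiment` runs the complete loop (sample → simulate all four
protocols → add noise → fit everything → aggregate): with 20 wild-type
cells at 5-pA noise the mean fitted activation midpoint stays within 1 mV
of the generating mean with ≥ 90% fit success; noise-only cells (near-zero
sampled density) are rejected by the fit-quality gate and counted as
failures.

## Problem sizes and runtime

Voltage-clamp simulation is closed-form per constant-voltage epoch, so a
full 12-variant characterization takes well under a second.  Hybrid-neuron
episodes integrate 1.1 s of membrane time at 0.02 ms per step; the complete
phenotype suite (~150 episodes) runs in about a minute on one core.  The
default test suite finishes in well under two minutes.
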