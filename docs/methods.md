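# Methods

This document records the model design, measurement conventions and
known limitations of `habephys`. Everything here is implemented and
tested in the package; numbers quoted are reproduced by the test suite
and by `scripts/acceptance.py`.

## Biophysical model

Two compartments — a neuron and a coupled non-neuronal (glial) cell —
are integrated together with fixed-step RK4 at dt = 0.025 ms
(fs = 20 kHz), with numba-compiled kernels. The neuron carries leak,
spike (Na/K, Wang–Buzsáki-style kinetics with small maximal
conductances), T-type calcium, SK, H and adaptation currents; the
glial compartment carries leak, its own T-type conductance and a
CNG-like depolarizing conductance. The two are joined by an ohmic
gap-junction conductance `g_gap`. If the membrane potential leaves
±200 mV, the run aborts with `SimulationDiverged`.

Key design choices:

- **T-type kinetics.** Activation `mT_half = −48 mV` places the
  regeneration threshold (~−53 mV) above the −60 mV hold, so rebound
  bursts fire on release; inactivation `hT_half = −67 mV` (slope 3.5)
  with slow recovery (τ ≈ 1 s hyperpolarized, 80 ms depolarized) means
  only a sustained conditioning hyperpolarization re-primes the
  channel — afterhyperpolarization tails cannot retrigger it, which
  suppresses spurious T/SK relaxation oscillations.

- **CNG plateau termination.** The CNG gate obeys
  `ds/dt = α·H(V_g − θ_CNG)·(1 − s) − β·s`. If θ_CNG sat below the
  plateau voltage the plateau would be self-sustaining; θ_CNG is
  instead placed above the plateau but below the glial rebound-spike
  peak, so `s` charges only during the trigger transient and then
  decays with time constant 1/β of a few seconds. That decay is the
  seconds-long depolarizing plateau.

- **Trigger selectivity.** The glial T conductance inactivates around
  the glial resting potential (`hT_half_glia = −80 mV`), so it is
  primed only by hyperpolarization relayed through the gap junction.
  Without this, tonic neuronal firing during depolarizing steps leaked
  enough depolarization into the glia to trigger plateaus and
  depolarization-block the neuron.

- **Firing phenotypes.** High-frequency (HF) cells sustain firing at
  +100 pA via a high sodium-availability floor (`p_Na_floor = 0.85`);
  low-frequency (LF) cells stop firing early because availability runs
  down to a much lower floor (0.35). Frequency adaptation index
  (FAI) = final rate (last 200 ms) / initial rate (first ISI); HF iff
  FAI ≤ 0.8.

- **Spontaneous-activity variants** (silent, tonic, bursting) are
  specified as target resting potentials (−68, −42, −63 mV) with the
  neuronal leak reversal solved from the coupled-rest equation, because
  the gap junction otherwise drags strongly coupled cells ~10 mV below
  the nominal leak reversal. Bursting uses fast
  Ornstein–Uhlenbeck noise (σ = 20, τ = 5 ms).

- **Pharmacology** is parameter surgery, never a code path: TTX zeroes
  `g_Na`; apamin/BAPTA zero SK in both compartments; Z944 and high
  nickel zero both T conductances; low nickel scales CNG ×0.2 and
  T ×0.8; L-cis-diltiazem zeroes CNG; carbenoxolone/meclofenamate zero
  the gap junction. A test asserts each drug touches only its declared
  parameters.

With the default parameter sets this reproduces the target
phenomenology: T-block abolishes both RDP types; SK block prolongs
both; CNG or gap-junction block converts the long RDP (~5.6 s) into a
short one (~0.3 s) with <3% peak change while leaving the short
phenotype essentially untouched; long-RDP duration grows with
conditioning amplitude (0, ~0.15 s, ~5.4 s, ~5.6 s at −10/−20/−40/−100
pA) and plateaus between −40 and −100 pA.

## Feature measurement

- Traces are filtered with a 4th-order 10 Hz Bessel filter applied
  forward–backward (zero phase). Baseline is the mean of the filtered
  trace over the 500 ms before step onset.
- **RDP duration**: time the filtered post-offset trace spends above
  baseline + 10 mV, from first crossing to final return; a censored
  flag is set when the trace has not returned by the end of the
  record. An independent oracle rescans the raw samples; the fast
  implementation is sample-exact against it.
- Spike detection, rebound-oscillation counting, adaptation indices,
  sag ratio and passive properties each have analogous brute-force
  oracles in the test suite.
- **Spontaneous classification**: spike trains are split at ≥300 ms
  gaps; a burst is a cluster of ≥3 spikes spanning <3 s riding a
  filtered wave ≥5 mV above baseline, where baseline for spontaneous
  records is the 20th percentile of the filtered trace (the median
  sits on the events themselves in plateau-rich cells). The span test
  rejects continuous tonic trains; the gap split rejects tonic trains
  with occasional pauses.

Note that an area-preserving lowpass filter does not return the
interspike envelope: spikes contribute several millivolts of average
depolarizing area, so the filtered trace of a spiking plateau rides
~7 mV above the corresponding TTX trace. Tests therefore assert that
filtering removes spikes and preserves the plateau within 10 mV of the
TTX envelope, not exact equality.

## Classification

Subtypes are short/long (duration threshold θ = 400 ms) × HF/LF
(FAI θ = 0.8). Thresholds can be re-derived from data: a variational
Bayesian GMM (scikit-learn `BayesianGaussianMixture`,
Dirichlet-distribution weights, up to 10 components, 10 seeded
restarts, standardized features with optional log-duration) is fit,
effective components (weight ≥ 0.01) are ordered by mean, and for each
candidate split between adjacent component means the empty band
between the highest member point below and the lowest member point
above is computed; θ is the midpoint of the widest band. This reduces
to the simple two-component midpoint when there are two clusters and
stays correct when the mixture splits a broad group into several
components. On synthetic cohorts the pipeline recovers the true
long-RDP fraction within the 99% binomial interval, two well-separated
clusters at ≥99% assignment accuracy, and a five-cluster layout in
≥90% of seeds.

Behavioural phenotyping of stressed mice uses the standard
social-interaction criteria (interaction time and ratio) and
reproduces the published per-animal labels exactly
(9 susceptible / 9 resilient / 1 intermediate).

## Coupling analysis

- **Synchrony** is the Spearman correlation of the filtered pair over
  step onset → 3 s after offset, decimated to ~1 kHz; coupled iff
  ρ > 0.5. Pairs whose filtered excursion is under 0.5 mV are reported
  as ρ = 0 / uncoupled: rank correlation is scale-free and would
  otherwise amplify sub-millivolt numerical drift in flat traces.
- **Amplitude ratio** = filtered rebound peak above baseline / peak
  hyperpolarizing deflection, with a 0.5 mV dead band absorbing the
  zero-phase filter's step-edge overshoot.
- **Dye coupling** uses strict intensity criteria per ROI: neurobiotin
  positive iff mean > surround mean + 2 SD; Alexa negative iff
  mean < surround mean + 0.5 SD; coupled iff NB+ ∧ Alexa− ∧ not the
  recorded cell; double-positives are excluded. `coupling_summary`
  aggregates per-recording coupled counts into incidence and
  marker-positive fractions and optionally compares two conditions
  with a Mann–Whitney U test.

## Statistics

Chi-squared contingency tests report per-cell adjusted standardized
residuals `r_ij = (O−E)/sqrt(E(1−R_i/N)(1−C_j/N))` with two-sided
normal marks; the implementation is verified elementwise against the
formula at 1e-12. The two-sample KS test uses the exact distribution
for small samples and matches full permutation enumeration; Pearson
and Spearman correlations match closed-form references at 1e-6. Type-I
error for the chi-squared and paired-t workflows is calibrated at
0.05 ± 0.02 over 1000 null replicates. Multiple comparisons use
Holm–Šidák.

## Pipeline and I/O

Traces are stored as CSV (`time_s,v_mV,i_pA`, `%.17g`) plus a JSON
sidecar (sampling rate, sample count, metadata); reads use
round-trip float parsing, so write→read is bit-exact. Time-grid gaps
are rejected with the offending CSV line number. The pipeline
(simulate → features → classify → stats) is deterministic for a fixed
config — feature and label tables are byte-identical across reruns —
and writes a provenance record with the config hash and library
versions. Degenerate group tables (a class absent everywhere, e.g.
tiny cohorts) are reported as counts with an explanatory note instead
of a chi-squared test.

## Known limitations

- The model is phenomenological: kinetic constants were chosen to
  reproduce the qualitative pharmacology and duration structure, not
  fitted to voltage-clamp data.
- The spontaneous-depolarization/RDP-duration correlation is verified
  across noise seeds on the default phenotype parameter sets; under
  multiplicative conductance jitter the fixed +10 mV crossing is
  fragile for wave peaks near threshold.
- The filtered-envelope offset described above means filtered spiking
  traces sit several mV above their spike-free counterparts; analyses
  compare filtered traces to filtered traces.
- Exact KS p-values are only used when n·m ≤ 10⁴; larger samples fall
  back to the asymptotic distribution.
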