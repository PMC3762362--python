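# Methods

## The kinetic scheme

The simulator and the analysis share one model of diVCA-stimulated branch
formation. Arp2/3 complexes in solution, a fraction f_AV of them carrying
a diVCA dimer, bind the side of a mother filament with per-subunit
second-order rate constant k_A+. A filament-bound diVCA-Arp2/3 complex
(the *nascent branch*) decays through two competing first-order channels:

* intact dissociation of the whole complex from the filament, rate k_A−
  (the dominant channel);
* release of diVCA alone, rate k_V−\*, leaving an *activated*
  filament-bound Arp2/3 complex.

Because the two clocks are exponential, the nascent-branch lifetime is
exponential with mean tau_V\* = 1/(k_A− + k_V−\*), the release probability
is f_V− = k_V−\*/(k_A− + k_V−\*), and the winning channel is independent
of the decay time — which is what licenses the estimator
k_V−\* = f_V−/tau_V\*.

An activated complex nucleates a daughter filament with probability p_nuc
and is then permanent (complexes that form branches are never observed to
dissociate); otherwise it detaches at rate `k_act_minus`. Arrivals without
diVCA detach at k_A− and nucleate with the small probability `p_nuc_bare`.

Two of these parameters are not determined by the experiments the model
emulates and are package choices:

* `p_nuc` — only a fraction of activated complexes form branches; the
  default 0.31 is the ratio of the branching and release fractions in the
  reference wild-type data (f_B/f_V− = 0.008/0.026).
* `k_act_minus` = 0.2 s⁻¹ — the fate of activated complexes that never
  nucleate is kinetically unresolved; the default keeps them bound long
  enough (mean 5 s) to be scored as release events by the 0.15 s
  persistence criterion, while still clearing the site.

`KineticParams.from_construct` loads the four measured construct columns
(wild type and the V\*, C\*, A\* mutants), deriving k_A− = 1/tau_V\* −
k_V−\* per construct. Default concentrations are the imaging conditions:
5 nM diVCA, 5 nM Arp2/3, 1 µM actin. The per-subunit k_A+ is converted to
per-site rates with an actin linear density of 370 subunits/µm (2.7 nm
axial rise) on 0.4 µm resolvable segments (148 subunits).

## Observation model

True molecular events are degraded in this order:

1. **Photobleaching.** Each single-fluorophore event (Arp2/3, diVCA
   channels) is truncated by an independent exponential clock at rate
   `bleach_rate_per_power × laser_power` (default 0.02 s⁻¹, i.e. a 50 s
   mean bleach lifetime at unit power, the scale implied by the longest
   observed dwell components). Daughter-filament (actin-channel) events
   are exempt: filaments carry many dyes and continually incorporate
   fresh labeled monomers.
2. **Detection limit.** Events whose surviving true duration is below
   `t_min` (default 0.1 s) are dropped — this is what the 1/p0 correction
   later undoes in expectation.
3. **Frame snapping.** Appearance times are floored and disappearance
   times ceiled to the 50 ms frame grid, so a snapped duration exceeds
   the true one by one frame on average.
4. **Localization jitter.** Positions receive isotropic Gaussian noise
   (default sigma 0.05 µm).
5. **Non-specific background.** Surface binding is a spatial Poisson
   process (default 10⁻³ events s⁻¹ µm⁻², mean dwell 0.05 s, so most
   background falls below the detection limit), mirroring the transient
   non-specific binding seen off-filament.

All simulation operations take an explicit seed; a run is reproduced
byte-identically from the same seed.

## Classification and corrections

Coincident arrival uses the standard windows: a diVCA appearance within
0.27 µm (two pixels) and 0.15 s (three frames) of an Arp2/3 arrival.
Ambiguities resolve nearest-in-time, then nearest-in-space, each diVCA
event consumed at most once. Departures partition into co-release
(|Δt_off| ≤ 0.15 s), diVCA release (Arp2/3 persists > 0.15 s), and
anomalous (diVCA outlasts Arp2/3; excluded from f_V−).

Three corrections:

* **Detection efficiency.** Each arrival class (±diVCA) gets its own
  dwell fit (two-component truncated mixture by default) and
  p0 = Σ A_i exp(−t_min/tau_i); corrected counts are raw/p0. The same
  factor corrects k_A+.
* **Non-specific background.** When the filament mask (site positions) is
  supplied, events outside the mask estimate the background density and
  the expected on-mask background count is subtracted from the −diVCA
  arrival class (a background spot essentially never also draws a
  coincident diVCA).
* **Photobleaching misclassification.** A bleached diVCA dye inside a
  co-release event mimics a release (and a bleached Arp2/3 dye mimics an
  anomalous pair). The expected number of such false events,
  n_pairs · b/(b+k) · exp(−(k+b)·0.15), with k estimated from the
  co-release dwell mean and b the known or regressed bleach rate, is
  subtracted from the release and anomalous counts and returned to
  co-release. At the default bleach rate this correction is ~1% of pairs —
  without it f_V− (true value ~2.8%) would be biased upward by ~40%.

Branches are scored by a daughter-filament appearance in the actin channel
at the pair's location while the Arp2/3 spot is present. Requiring the
Arp2/3 spot to persist to the end of the record is supported as a fallback
but is only valid without photobleaching.

Counting errors are binomial, δf = √(f(1−f)/N), on corrected fractions
with corrected N. The printed errors of the reference dataset sometimes
exceed this floor (correction-propagated); both are available.

## Dwell inference

Dwell distributions are fit as mixtures of one to three exponentials with
the left truncation handled in the likelihood — the density is divided by
the mixture survival at t_min, never by shifting the data. Right-censored
dwells (spot alive at record end) contribute survival terms; the component
count is fixed by the user, not selected. Optimization is Nelder–Mead on
(log tau, amplitude logits) from quantile- and moment-based starts plus
seeded perturbations (10 by default); the single-exponential uncensored
case uses the analytic MLE (sample mean minus t_min, by memorylessness).
Components with amplitude below 10⁻³ are collapsed with a warning.
Standard errors come from a seeded nonparametric bootstrap over events
(default B = 1000), each resample warm-started at the point estimate. The
bootstrap resamples events, not sites.

First-appearance waiting times on 0.4 µm segments are exponential; the
second-order constant is (1/mean)/(c · 148 subunits) with SE k/√n.
Photobleach correction regresses observed dissociation rate on laser power
by weighted least squares (weights 1/SE²) with one intercept per construct
and a single shared slope, the photobleaching rate coefficient.

## End-to-end estimation

`pipeline.estimate_experiment` composes the above: classification with all
three corrections, tau_V\* as the mean diVCA dwell on branch-producing
nascent branches debiased for truncation (−t_min) and frame snapping
(−one frame), k_V−\* = f_V−/tau_V\* by the delta method, k_A+ from
per-site first-appearance waits corrected by the mean detection
efficiency, and k_B from the composition formula. Error propagation is
first order with independence assumed between factors.

A single record at the reference arrival count (~877 events) contains only
~6 branch events, so its tau_V\* carries a ~40% standard error; the
reference analysis pooled ~57 branch observations across its whole
dataset, and the recovery tests emulate that by estimating tau_V\* from a
~9× larger simulated pool while keeping every fraction at the ~877-event
scale. The small-sample tau SE uses the larger of the empirical standard
error and the exponential-model value tau/√n.

## Correlation significance

The association between k_B and k_V−\* across the four constructs is
scored by Pearson r on the measured values and a Gaussian-resampled
permutation test: each resample redraws every coordinate from the Gaussian
defined by its error bar, permutes the y-assignment uniformly over all n!
arrangements (identity included), and p is the fraction of resampled r at
least r_observed. Draws are not truncated at zero; r_observed is computed
once from the means. A tie tolerance of 10⁻⁹ on r keeps the ≥ boundary
well defined when the standard errors are tiny and the resampled
distribution collapses onto the n! permutation atoms; with it, the p value
converges to the exact enumeration p as errors vanish (1/24 for four
distinct collinear points). Note that p is not monotone in the error bars
in the near-collinear regime: at large errors it approaches the
permutation-null tail beyond r_observed, at vanishing errors the
enumeration value, and the minimum lies between.

## Binding equilibria

Occupancy uses the single-site isotherm L/(L+K_D); at K_D = 300 nM and
1 µM monomeric actin this gives the ~77% figure for diVCA dimers carrying
at least one actin. A two-independent-site alternative
(1 − (K_D/(K_D+L))², 94.7% at the same numbers) is exposed via
`n_sites=2` but is not the default, matching the single-site convention of
the reference estimate. Direct anisotropy titrations are fit with the
exact quadratic two-species mass balance (no excess-receptor
approximation); competition titrations solve the cubic in free receptor
for two ligands sharing one site on its physical branch (closed
trigonometric form, with a bracketed-root fallback wherever the closed
form loses precision), holding the probe K_D at its direct-fit value.
Anisotropy is a mole-fraction-weighted average of free and bound
endpoints; fits are Levenberg–Marquardt least squares.

## Bulk polymerization

Pyrene traces are normalized with the mean of the first 2% of points as
baseline and the final 5% as full polymerization (plateau averaging rather
than single-point anchors; the critical-concentration offset is ignored).
The barbed-end concentration is the linear slope of polymer vs time inside
the 42–58% polymerization window — window membership determined on a
lightly smoothed copy of the trace to avoid edge-selection bias — divided
by the elongation rate (10 subunits s⁻¹). Fold-stimulation subtracts the
actin-alone ends from both numerator and denominator. With 1% point noise
and ~1 s sampling the per-trace end estimate scatters ~6%; the estimator
is unbiased to well under 1% (checked over 400 simulated traces).

## Problem sizes in the test suite

Distributional checks run at 10⁴–10⁵ simulated events; recovery tests use
100 seeded replicates at the reference scale (~877 arrivals) with the
branch-dwell pool at ~55 events; the mixture-recovery study uses n = 2000
with a 40-resample bootstrap; solver cross-checks use 10³ random parameter
sets against bracketed-root oracles at 10⁻⁹ relative tolerance.

## Known limitations

* The simulator's nascent-branch lifetime is single-exponential by
  construction; real on-filament dwell distributions are multi-exponential
  (multiple complex conformations), so the simulated p0 (~0.87) is higher
  than the 0.5–0.6 typical of real recordings. The correction machinery is
  exercised either way.
* Daughter elongation is not simulated as length dynamics; branch
  detection in the simulator reduces to actin-channel appearance events.
  Initiation-time extrapolation is implemented and tested on synthetic
  length series instead.
* The bleach misclassification correction is first-order and assumes a
  single effective dissociation rate for co-released pairs.
* Error propagation ignores covariances between factors throughout.
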