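# Methods

## The calibration model

Observed eDNA fractions O ∈ (0, 1) from mock mixtures of known herring
weight fraction w are modelled with a mean/precision-parameterised beta
distribution,

    O_i ~ Beta(μ_i φ, (1 − μ_i) φ),    logit(μ_i) = α + β · logit(w_i),

so shape1 = μφ and shape2 = (1 − μ)φ. α is the logit-scale offset between
DNA share and weight share (α < 0: herring DNA under-represented), β the
steepness of the response, and φ the precision governing replicate scatter
(sd ≈ √(μ(1 − μ)/(1 + φ))). φ is constant across the design; there is no
variable-dispersion or mixed-effects extension, and no covariates beyond
logit(w).

**Fitting.** Maximum likelihood on (α, β, log φ), quasi-Newton (BFGS) with
the analytic gradient, started from the logit-linear least-squares solution
with a small multi-start over log φ (±1 around a moment estimate).
Convergence requires a gradient numerically at zero (tolerance 10⁻⁸ in the
line search; a stalled line search with max-norm gradient ≤ 10⁻⁵ relative
to the log-likelihood is accepted, since BFGS routinely reports precision
loss at an already-converged optimum). The covariance of (α, β, log φ) is
the inverse of a central-difference observed information (relative step
10⁻⁴). Fitting uses individual replicates, not replicate means; data with
fewer than three distinct mixture ratios, or with all observations equal,
are rejected with a diagnostic.

**Boundary observations.** Real qPCR fractions can be exactly 0 or 1 (one
species undetected). Since beta support is open, observations are shrunk by
the standard compression (O·(n − 1) + 0.5)/n before fitting whenever any
boundary value is present.

**Inversion.** The inverse model is the closed form

    w = invlogit((logit(O) − α) / β).

Writing the inverse with O left on the probability scale is dimensionally
inconsistent — α lives on the logit scale — so the logit is always applied
to O first; this is the unique choice making invert ∘ predict the identity
(verified to 10⁻¹⁰ in the tests). Inversion is refused when |β| < 10⁻⁸.

**Intervals.** Both directions use the delta method on the logit scale,
transformed through invlogit, so intervals always lie inside (0, 1). The
forward band is the confidence band of the model mean (as drawn on
calibration plots), not a prediction interval; the inverse interval
propagates only the (α, β) covariance — observation noise enters downstream
through replicate scatter. A bootstrap is deliberately not the default:
the delta method is exact enough at the calibration sample sizes used here
and keeps estimation deterministic.

## qPCR quantification

Standard curves are ordinary least squares of Cq on log₁₀(copies) over a
dilution series (≥ 3 distinct levels; the design emulated spans 3×10⁰ to
3×10⁶ copies/reaction in seven decades). Efficiency is 10^(−1/slope) − 1;
non-negative slopes are flagged invalid and refuse quantification.
Quantification inverts the curve, copies = 10^((Cq − intercept)/slope).

Technical replicates (duplicates in the emulated protocol) are aggregated
by geometric mean on copies — equivalently the arithmetic mean on the Cq
scale, which is what the instrument measures. Not-detected wells are
missing, never zero: a fraction is only computed when at least one
replicate per species is detected, and a sample with herring = sprat = 0
copies reports a missing fraction rather than 0, avoiding bias toward the
boundaries. Inhibition control (IPC) is honoured as a pass/fail filter
column; no ΔCq correction is attempted. LOD/LOQ thresholds are accepted as
configuration, not recomputed.

## Metabarcoding classification

Reads are length-filtered to [340, 380] bp, inclusive on both ends (the
bounds name the amplicon window; inclusivity keeps the printed bounds
meaningful). Each read is aligned to both reference amplicons with a
semi-global alignment (free end gaps; match +1, mismatch −1, gap −2 — the
simplest standard scheme, fixed and documented because interactive
GUI-based classification is not reproducible). Identity is matches over
aligned columns within the overlapping region, internal gaps counted;
overlap is measured in reference bases spanned and must reach 272 bp (80%
of 340). The ladder assigns species at ≥ 85% identity, genus at ≥ 82%,
family at ≥ 80%, else unassigned. Ties in best identity are conservative:
assignment falls to the deepest level at which the tied references agree
(herring vs sprat ties land on the shared family Clupeidae), never species
unless the tied references are the same species. Read fractions use
species-level assignments only; genus/family and unassigned reads are
excluded from the denominator, and zero species-level reads yield a
missing fraction.

The two bundled reference amplicons are synthetic stand-ins (360 bp,
~12% pairwise divergence, in the range of congeneric clupeid COI
divergence) — real mitogenome amplicons can be supplied by FASTA path.

## On-site model selection

Candidate seasonal calibration models are scored on test mixtures of known
composition (three 2–4 kg replicates, 30% freshwater, water sampled at
10 min, 2 h, 4 h): every observation is inverted and compared against the
pooled (weight-weighted) true fraction — per-replicate comparison is
available by flag. The score is the mean absolute error on the fraction
scale, all timepoints pooled with equal weight; MAE was chosen for
robustness at n = 9 and interpretability in fraction units. Selection is
the argmin, with ties broken by minimal circular month distance between
model season and landing month, then lexicographically — fully
deterministic. No refitting on on-site data is performed; selection is
among pre-fitted models only.

## Landing estimation

Genetic replicates are inverted individually, averaged within their sample
first, and the landing fraction is the unweighted mean over samples — the
factory stream is sampled every ~200 t and is therefore approximately
weight-proportional already. The SE is the across-sample standard
deviation (ddof = 1, the sample standard deviation) over √(number of
samples); replicate scatter within a sample does not enter it. Tonnage is
fraction × total landed weight, with the total treated as known from the
weighbridge (its uncertainty is not propagated), and the same scaling
applies to the SE. Calibration (inversion) uncertainty is not included in
the landing SE by default; the delta-method inverse intervals are available
separately. Per-tank estimates report the mean and replicate sd per tank;
when tank weights are known, the weight-weighted recombination of per-tank
means is available and coincides with the pooled estimate under equal
weights. Method differences are rounded to whole tonnes only in the
comparison report, never in intermediate arithmetic.

## The synthetic-data generators

The generators produce data with exactly the structure the analysis
assumes, which is what makes the test suite meaningful and also bounds what
it shows:

* **Calibration designs** use the experimental mixture ratios (March:
  90/10 … 10/90, nine ratios; November adds 95/5 and 5/95, eleven) with
  9 replicates per ratio, and draw observations from the beta model above.
  Defaults α = −0.4, β = 1.0, φ = 50 are assumptions — the source
  experiments report no fitted values; α < 0 encodes the observed
  under-representation of herring DNA, and φ = 50 gives replicate scatter
  (sd ≈ 0.07 at μ = 0.5) consistent with visibly tight but non-degenerate
  calibration scatter. Seasonal structure enters as intercept offsets,
  Δα ≈ 0.19 (ship) and 0.50 (factory), back-computed on the logit scale
  from fraction-scale seasonal mean differences of ≈ 0.047 and 0.121 at
  mid-range mixtures via Δfraction ≈ Δα·μ(1 − μ).
* **qPCR runs** place Cq on the log-linear curve with i.i.d. Gaussian cycle
  noise.
* **Read sets** draw species multinomially with probability ∝ weight
  fraction × primer-bias multiplier, then apply i.i.d. substitutions —
  substitutions only, no indels, so that identity arithmetic in the
  classifier tests is exact; `engineer_read` additionally spaces
  substitutions evenly and protects read ends, because a free-end-gap
  aligner would otherwise trim terminal mismatches or realign clustered
  ones and shift the identity off its engineered value.
* **Landings** are tanks with weights and true fractions; the landing truth
  is the weight-weighted tank mean.

All generators take one explicit seed per call and are bit-reproducible;
no global random state is used.

What the generators do **not** emulate: eDNA degradation over time,
temperature kinetics, allometric (size-dependent) DNA release, PCR drift,
chimeras and indel-rich nanopore error profiles, tank-emptying order, or
inhibition dynamics. Passing tests therefore demonstrate the statistical
machinery — not that real production water obeys the beta model, which is
an empirical matter for calibration experiments.

## The precision experiment

The Monte-Carlo comparison pits the eDNA estimator (8 samples × 3 genetic
replicates from well-mixed water, beta noise at φ = 200) against the
bucket estimator (15 subsamples, each landing in a tank with
weight-proportional probability and observing that tank's fraction) on
six-tank landings whose true fractions are Normal(0.25, 0.15) truncated to
(0.01, 0.99). The bucket estimator's error is dominated by between-tank
heterogeneity, which the well-mixed water integrates out; its reported SE
is accordingly several-fold larger. A per-tank eDNA mode with a tank
subset emulates ship sampling truncated before the last haul and produces
the corresponding bias. Problem sizes (200 trials, 200 fitted datasets in
the recovery study, 2000-read classification runs) were chosen to make the
Monte-Carlo standard errors comfortably smaller than the margins being
demonstrated.

## Known limitations

* Only the two-species case is implemented; fractions are binary
  (herring vs sprat).
* The landing SE reflects replicate scatter only; an option to add
  delta-method calibration variance exists at the inversion level but is
  not folded into the reported landing SE.
* The classifier is a deliberately simplified re-implementation: no
  clustering/consensus polishing, no multi-family reference database, no
  chimera or quality filtering.
* Model selection assumes candidate models share the water type of the
  test sample and at least one usable observation.
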