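# Methods

## The analysis this package implements

A single-arm neoadjuvant trial design with MPR (≤10% viable malignant
cells at resection) as the primary endpoint motivates every piece of this
package. Patients with incomplete (R1/R2) resection count as non-MPR by
rule; patients without surgery are not evaluable; pCR is 0% viable with
complete resection. The biomarker question is whether the *pre-treatment
peripheral-blood immunome* — percent abundances over all marker
combinations of a 14-tube, ≤10-markers-per-tube flow panel — predicts
MPR.

The pipeline narrows the combination space in stages: (1) enumerate
observed phenotypes; (2) drop biologically impossible combinations
(panel-file exclusion rules such as {CD3+, CD19+}); (3) drop combinations
detected in fewer than 50% of samples (inclusive boundary); (4) rank the
survivors by an information-divergence importance score estimated by
random subsampling over two extreme-response cohorts, retaining features
with positive null-centered importance; (5) split retained features at
85% detection prevalence, filter candidates per stratum (chi-squared on
the detected×outcome table for non-prevalent features, a location test on
abundance for prevalent ones, caps 17/10); (6) fit a group-sparse
penalized additive logistic model with at most one prevalent feature; (7)
evaluate by ROC on held-out samples and compare predicted probabilities
across MPR / non-MPR / radiographic-PD groups.

## Synthetic data generator

Real data of this kind are access-restricted, so the generator is a
first-class module, not a fixture. What it emulates, and how:

**Cohort.** Categorical marginals (stage IB–IIIB 18:16:55:70:22, 38%
squamous, TPS groups 69:28:49:35 including unknowns, ~9% EGFR/ALK
alterations, 12% no surgery, ~4% incomplete resection) reproduce the
enrollment table of the modeled trial. Viable tumor percent follows a
three-part mixture: an atom at 0 (mass 0.056, pCR), a uniform component
on (0, 10] (total MPR mass 0.203), and a Beta(2, 1.2) tail stretched over
(10, 100]. Survival is exponential per MPR status with independent
exponential censoring; the default monthly rates (DFS 0.0029/0.0107, OS
0.0014/0.0073, censoring 0.010) are invented, chosen to land 3-year
survival near the reported 72%/80% while keeping Kaplan–Meier and
log-rank exercisable with known truth.

**Immunome.** Each tube carries `n_populations` latent cell populations,
each with a fixed +/- signature; a patient's tube composition is a fixed
Dirichlet-drawn base proportion vector perturbed by multiplicative
log-normal noise (σ = 0.6) and renormalized, and a combination's
abundance is 100× the summed weight of matching populations. The
exhaustive signature partition of a tube therefore sums to exactly 100
per sample. Pre and post draws share the patient's noise with an extra
log-normal increment (σ = 0.25), giving realistic pre/post pairing.

**Planted effects.** `EffectSpec` maps feature ids to effect sizes on the
Cohen's-d scale. An effect is realized as a multiplicative tilt of the
generating population's weight in MPR patients, renormalized exactly so
closure is preserved, with the tilt solved by bisection so that the
feature's mean *log* abundance shifts by d of its null log-scale SD. The
log scale is deliberate: percent abundances are lognormal-like, and a
standardized multiplicative shift separates distributions consistently
regardless of skew, whereas a raw-scale mean shift rides the tail.
Because a tilt renormalizes its whole tube, planting several effects in
one tube attenuates all of them; studies that need independent effects
place one per tube.

**Zero inflation.** A configurable fraction of features (default 0.5)
receives a detection probability drawn from U(0.30, 0.95); the feature's
*detection limit* is set at the corresponding quantile of its marginal
distribution and values below it read as 0, with no renormalization
(closure is asserted pre-mask only). Thresholding rather than independent
Bernoulli dropout is a deliberate choice: it is the physically correct
model of an assay floor, and it means a feature whose abundance shifts
with outcome also has outcome-linked detection — which is precisely why a
detection-based chi-squared screen of non-prevalent features can work at
all. `EffectSpec.base_detection` pins a feature's detection probability
(e.g. to force it into the non-prevalent stratum) and
`detection_shift` adds an explicit outcome-linked detection offset.

**Mutation data.** Patients draw a latent mutation rate via a 60:10:15
stratum mixture (<10 / 10–15 / ≥16 mut/Mb, uniform within stratum),
a ~30 Mb ≥7×-covered coding footprint, and Poisson counts, so downstream
TMB recovers the planted rate in expectation.

**What the generator does not emulate:** cell-level event data,
between-feature biological correlation structure beyond tube-level
compositional coupling, batch effects, or any real distributional facts
about abundances (none are published) — so passing recovery tests shows
the pipeline recovers effects *of the planted form*, not that it would
perform identically on real cytometry data.

All randomness descends from one integer seed through named
`SeedSequence` spawn keys, so each module is independently re-runnable
and every pipeline output is byte-reproducible.

## Divergence ranking (I-index)

The published description of the importance score is "information
divergence-based"; the formula itself is in an inaccessible reference.
This package implements the divergence kernel as Jensen–Shannon
divergence between the two class histograms on shared equal-width bins
(natural log, bounded by log 2), with additive smoothing (default 1.0)
behind a named interface so another divergence can be substituted. The
default bin count of 6 matches ~√n resolution for the 13-per-arm extreme
design; rank normalization beforehand makes the estimate invariant to
monotone per-feature transforms and gives all features a common support.

Raw divergences are nonnegative, so a literal "importance > 0" retention
rule would keep everything. Importance is therefore *null-centered*: the
same B subsets are re-scored under label permutations (one fresh
permutation per subset), and a feature's importance is its observed
divergence minus its mean permuted divergence over the subsets containing
it. Under the null this statistic is near zero-mean, and about half the
features are retained (slightly under half, because a single
right-skewed divergence draw falls below the permutation mean more often
than above). Because scoring is marginal (per feature within the subset),
the observed mean over containing subsets equals one full-data
computation, which the implementation exploits; the subsampling still
determines `times_sampled` bookkeeping and the null draws. B defaults to
10,000 (library) and is a CLI flag; importance is a mean, so B controls
only Monte-Carlo variance.

The two extreme-cohort eligibility windows (viable ≤88% for regression,
≥20% for progression) overlap by construction; both thresholds are
configuration, assignment of doubly eligible patients is by distance to
the nearer extreme, disjointness is enforced, and ties break by viable
percent then patient id, making the selection deterministic without
randomness.

## The classifier

Smooths are cubic B-spline bases on each feature's observed training
range (1 internal knot at the median → 5 basis columns ≈ 4 effective df),
columns standardized, constant extrapolation outside the range,
degenerate (constant) features contributing nothing. The group-lasso
penalty λ Σ √p_g‖β_g‖₂ zeroes whole smooths; the objective is minimized
by FISTA with a spectral-norm step size, warm-started along the penalty
grid. The penalty is chosen on a log grid (8 points, 10⁻³·⁵–1) by
5-fold stratified cross-validated AUC with a parsimony rule: among
(prevalent-option, penalty) pairs within 0.01 CV-AUC of the best, the
largest penalty wins. Plain argmax-CV systematically admitted ~10 noise
smooths in development; the tolerance rule is the standard one-SE-style
remedy. The ≤1-prevalent-feature constraint is enforced exactly by
refitting over prevalent singletons (≤10 extra CV paths) rather than by
penalty weighting. Degenerate cases: an empty or fully shrunk model
predicts the training base rate exactly; separation is always penalized
(the grid has no zero).

AUC follows the Mann–Whitney convention (ties count ½), making it
identical to the normalized U statistic; the ROC curve collapses tied
thresholds. Group comparisons of predicted probabilities report the full
ANOVA decomposition plus pairwise Welch tests deliberately unadjusted for
multiplicity (flagged in the output); paired pre/post expansion tests use
Wilcoxon signed-rank (zero differences dropped; all-zero features get
p = 1) with Benjamini–Hochberg control across features.

## Endpoint conventions

* TMB strata labelled <10 / 10–15 / ≥16 are implemented as the exhaustive
  half-open partition [0, 10), [10, 16), [16, ∞), so non-integer values in
  (15, 16) are classifiable.
* Two-sided 2×2 Fisher p sums all tables with point probability at most
  the observed (10⁻¹² float-tie tolerance); r×c tables use Freeman–Halton
  by full enumeration with log-gamma arithmetic, feasible for clinical
  table sizes. All-zero rows/columns are dropped first (they do not alter
  the enumeration).
* Binomial CIs default to Clopper–Pearson with Wilson selectable; the
  method is reported alongside every interval. Percents round half away
  from zero.
* Correlations default to Spearman (pathological regression is bounded
  and non-normal), Pearson selectable; for n ≤ 9 the two-sided p is the
  exact permutation fraction over all n! permutations.
* Kaplan–Meier is the product-limit estimator with Greenwood variance
  (authored here and cross-checked against lifelines in tests); log-rank
  delegates to lifelines. Landmark survival reads the step function at
  the largest event time ≤ t.
* Design power is exact binomial: the critical value is the smallest k
  with P(X ≥ k | n, p₀) ≤ α, power is the alternative's tail there.

## Validation studies and problem sizes

The recovery study plants 5 causal features (d = 1.0, one per tube,
detection pinned at 0.70 so they land in the non-prevalent stratum, as 13
of the 14 final-model features did in the modeled analysis) in a
300-patient all-evaluable cohort with ~200 features, splits 150/150
stratified by MPR, ranks with B = 5,000 subsets over the full training
set, and fits the constrained model. Over 20 seeds the planted features
are expected in the importance top decile with held-out AUC > 0.80 in at
least 16. Ranking is scored over the full training set because the
study's question is operation-level recovery at the stated split sizes; a
13 + 13 extreme contrast is information-limited for d = 1 effects no
matter the estimator (even an oracle t-test places all five in the top
decile in well under half of replicates), which is a property of that
design, not of the ranking operation. The extreme-cohort path is
exercised by the full pipeline and its own tests. The null study repeats
everything with zero effects and checks the chance band (mean held-out
AUC in [0.4, 0.6]) and the ≈50% retained fraction.

Simulation sizes throughout (n ≤ 300 cohorts, ~200–450 features, B in
the low thousands for tests) are chosen so the whole suite runs on a
laptop in minutes; B and all thresholds scale up by configuration.

## Known limitations

* The divergence kernel is a documented stand-in for an unpublished
  score; retention counts are therefore not comparable to the published
  188-immunophenotype figure (which is data-dependent anyway).
* Marginal (per-feature) scoring within subsets means the 30-feature
  subsets affect bookkeeping and the null, not competitive interactions;
  a joint multivariate divergence is out of scope.
* The generator's marker names and base abundance distributions are
  illustrative; no claim of distributional realism is made.
* Cox proportional-hazards modeling, FCS parsing, gating and all
  sequencing-upstream processing are out of scope; variant tables are
  consumed, not produced.
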