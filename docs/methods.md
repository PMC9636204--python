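# Methods

This note records the models implemented in `remcal`, the parameter choices
that matter, what the synthetic generator does and does not emulate, and the
design decisions taken where more than one reasonable construction existed.

## Data model and preprocessing

A cohort is a complete-case table under a declared schema: every feature has
a kind (continuous / binary / categorical) and a role (predictor, target,
excluded-from-prediction, stratification). Exactly one continuous target is
allowed. Rows with any missing value are dropped at load time (logged); no
imputation is offered. An optional absolute-bounds filter on the target is
available for crude outlier removal (off by default).

Continuous predictors are z-scored with statistics fitted on the **training
split only** and reused unchanged for validation — fitting "across
participants" would leak validation information into the model, so the
training-only convention is used. The spread estimator is the population
form (divide by n); at cohort scale the two forms are indistinguishable and
the population form keeps small hand-computed test values exact. Binary
predictors enter as {0,1} unscaled; categorical predictors are one-hot
expanded **keeping every level** — the neural predictor has no collinearity
constraint and group characterisation needs each level as its own
indicator. The target is z-scored for fitting and exactly recoverable from
stored statistics; all reported metrics are computed on the raw target
scale. A mean-split helper binarises any continuous feature (value strictly
above the training-split mean → "high") for stratified reporting.

## Reference regressor

Fully connected net, hidden layers (16, 16, 8), ReLU activations, linear
scalar output; with 20 input columns this is 753 trainable parameters.
Training is mini-batch Adam (β₁ = 0.9, β₂ = 0.999), batch size 10, learning
rate 10⁻³, on mean squared error over the normalised target.
Initialisation is fan-in-scaled uniform, U(−1/√fan_in, +1/√fan_in), for
weights and biases, fully seeded; training uses a seeded shuffle so
identical configs give bit-identical weights. The networks are implemented
directly on numpy: at this size (≲10³ parameters, ≲10⁵ records) dense
CPU training takes seconds and a self-contained implementation keeps the
whole framework reproducible from a single seed with no framework
nondeterminism.

The epoch count defaults to 5 with a config override and an optional
early-stopping mode (validation MSE, patience 2, best-weights restore);
there is no single "correct" value — it should be set by validation error
for the cohort at hand. Any object exposing `fit(X, y)` / `predict(X)` can
replace the reference net everywhere (tested with a mean predictor stub).

## Representation

The autoencoder has encoder hidden layers (8, 4), a **linear** two-neuron
bottleneck, and a mirror-image decoder; hidden layers are ReLU and the
output is linear, matching the regressor's conventions. It minimises
reconstruction MSE on the prepared feature matrix. Two latent dimensions are
deliberately restrictive: the goal is a compact, segmentable, plottable
description of population structure, not lossless compression.

By default the autoencoder sees **predictor features only**: the target and
any excluded-from-prediction feature (e.g. a diabetes diagnosis) are
withheld, so the latent space cannot trivially encode the quantity whose
fidelity is being audited. A replication mode (`ae_include_withheld`)
appends the normalised target and the withheld features, yielding a latent
space organised by the outcome itself. The two modes answer different
questions: audit mode asks "where, in *observable* population structure, is
the model weak?"; replication mode concentrates outcome-defined groups and
is the configuration under which remediation visibly reshapes the fidelity
distribution (see Remediation below).

## Segmentation

A K-component Gaussian mixture with full per-component covariance
(diagonal regularisation 10⁻⁶) is fitted to the latent coordinates by EM,
seeded k-means++ initialisation, run one step at a time so the
per-iteration mean log-likelihood trace is recorded (EM guarantees it
non-decreasing; the tests assert it). K defaults to 50 — enough groups to
be diverse, few enough that groups keep workable counts. Hard labels are
the argmax posterior responsibility; full responsibilities are returned for
audit. Groups under 30 members are flagged and excluded from equity
summaries (configurable): below that, a group's NRMSE is noise.

Mean silhouette scores ((b−a)/max(a,b), Euclidean, in the latent space)
diagnose separation. On realistic cohorts the latent space is a continuum,
silhouettes are low, and they tend to fall as K grows; this is reported,
not used as a gate — segmentation here is a device for tractable auditing,
not a claim that the population is naturally clustered.

## Calibration statistics

- **NRMSE** = RMSE / √(mean y²) over the evaluated subpopulation. The
  denominator is the root-mean-square of the raw observed target, chosen
  over the standard deviation because (a) it keeps the measure in (0, 1]
  for any model better than predicting zero, and (b) on an HbA1c-like scale
  (mean ≈ 36 mmol/mol) an overall RMSE near 6 yields NRMSE near 0.17,
  matching the intended magnitude of the measure. NRMSE is scale-free but
  origin-dependent — adding a constant to target and predictions changes
  it — which is acceptable for a target with a meaningful absolute zero.
- **Gini coefficient** over the vector of included groups' NRMSE values
  (one value per group, unweighted; a count-weighted variant is available).
  Computed by the sorted (Lorenz) formula, with the O(n²) pairwise
  definition kept as a test oracle. Uniform random values give G ≈ 1/3.
- **Permutation characterisation**: for each selected group and variable,
  the statistic is |mean inside − mean outside|, the null is B = 1000
  seeded re-assignments of membership, and p = (r+1)/(B+1) with ties
  counted as exceedances — so p is a multiple of 1/1001 with floor 0.0010.
  Group selection takes the worst `worst_percentile` (default 25%) of group
  NRMSE (boundary ties included) and keeps the `top_n_groups` (default 5)
  largest by count. Benjamini-Hochberg step-up FDR control at α = 0.05 is
  applied across the full set of tests (statsmodels implementation behind
  the package surface).

## Remediation

Designation: groups with NRMSE **strictly above the median** of included
groups form the under-served stratum; the remainder is the base stratum.
Rebalancing oversamples every under-served record by a common multiplier m
(⌊m⌋ copies plus one more with probability m − ⌊m⌋, seeded), which
preserves each constituent group's share of the pool — per-group
multipliers were deliberately avoided, since they can push the smallest
groups further out. The model is retrained from the same seeded fresh
initialisation as its trial baseline, so at m = 1 the experiment reproduces
the baseline exactly and deltas are pure rebalancing effects. The latent
model and mixture are **not** refitted across the before/after comparison:
Δ metrics compare like with like on a fixed group assignment.

The experiment repeats over n_trials (default 10) independent trial seeds
and reports mean and SD of ΔNRMSE (before − after; positive = improvement)
per stratum and split, plus Gini before/after. The multiplier sweep reruns
the experiment over a list of m values sharing cached per-trial baselines;
choosing m from the sweep is left to the user — the trade-off, not an
optimum, is the deliverable.

Two facts shape what remediation can show. First, oversampling can only fix
*reducible* error: a group whose excess error is purely inflated noise
cannot improve on held-out data by any training intervention. Second,
designation can only target a group that the segmentation concentrates:
in audit mode (target withheld from the autoencoder), outcome-defined
planted groups spread across latent groups (peak per-group planted
fractions ~0.2–0.4) and stratum deltas are small; in replication mode they
concentrate, and the full directional pattern — under-served improves,
base worsens, overall worsens slightly, Gini falls — appears robustly.
The tests exercise both regimes.

## Synthetic cohort generator

The default preset (`biobank_like_spec`) emulates a mid-life population
survey: sex (46% male), age 56.5 ± 8.1 y, smoking 35%, six-level grouped
ethnicity (88% white), a Townsend-like deprivation index (−1.3 ± 3.0),
haemoglobin 14.2 ± 1.2 g/dL, BMI 27.4 ± 4.8 kg/m², weight and body-fat %
generated as linear functions of BMI (and sex), six morbidity flags (high
blood pressure logistic in age and BMI; others at fixed prevalences), and
a diabetes flag with logistic dependence on BMI, age and deprivation
(prevalence ≈ 12%) that is recorded but excluded from prediction. The
target is HbA1c-like: a linear function of predictors (intercept 24,
residual σ = 3 mmol/mol) plus planted-subgroup effects, Gaussian residuals
throughout (Gaussian noise makes RMSE-based recovery analytically
predictable). Two subgroups are planted: **diabetics** (+12 mmol/mol,
residual ×2.5 — the familiar wide glycaemic dispersion) and **deprived male
smokers** (+8, ×3) — an intersectional group defined only by a conjunction
of observable features, so single-feature stratification dilutes it. The
diabetes dependence is steep enough, and the intersectional shift large
enough, that the planted disparity has a learnable conditional-mean
component; a purely-noise disparity would make remediation untestable.
Overlapping subgroup effects combine by summing mean shifts and taking the
worst noise multiplier.

A second preset (`separable_recovery_spec`) plants a 15% marker-defined
subgroup whose feature means are shifted by 1.5–2 spreads (a BMI-like
variable most strongly) with ×3 residual spread: a genuine cluster, used
for end-to-end ground-truth recovery tests (majority-group designation
recall, FDR-significant defining variables). The realistic preset cannot
serve this purpose — there, planted conjunction members never dominate a
latent group, which is precisely the diluting phenomenon the framework
exists to overcome.

What the generator does **not** emulate: real prevalence tables or effect
sizes (magnitudes are plausible, not calibrated), non-Gaussian target
tails, missingness (cohorts are complete by construction), measurement
error structure, or correlations beyond the declared linear/logistic
dependencies. Passing tests on these cohorts therefore demonstrate the
*mechanics* of discovery, characterisation and remediation under known
ground truth — not epidemiological fidelity.

## Problem sizes and numerical choices

Synthetic studies in the tests and examples use 1 500–20 000 records
(training fraction 0.75), 2–5 epochs, and the default K = 50 (smaller K
where cohorts are small); these sizes give stable statistics for every
property being asserted while keeping any study reproducible in minutes on
one CPU. Other numerical conventions: mixture weights must sum to 1 within
10⁻⁸ and responsibilities row-normalise to the same tolerance; EM
monotonicity is asserted to 10⁻⁶; the Gini dual-route equivalence to
10⁻¹⁰; z-scored columns centre to 10⁻⁶ on the fitting split; degenerate
inputs (zero-spread features, all-zero targets, single-level strata,
single-cluster silhouettes, empty designation) raise typed errors or warn
and no-op, as documented per function.

## Known limitations

- Two latent dimensions and a fixed K are conventions, not optima; the
  segmentation is a lens, and different lenses find different groups.
- NRMSE is origin-dependent and, like any RMSE-family measure, outlier-
  sensitive.
- The above-median designation always names ~half the groups under-served,
  even when the fidelity distribution is nearly flat; the Gini coefficient
  should be read alongside it.
- Oversampling duplicates records; with aggressive multipliers and long
  training it overfits the duplicated pool (visible as worsening held-out
  under-served fidelity). Early stopping or modest epochs mitigate this.
- The equity criterion for the orchestration loop (Gini threshold) is a
  placeholder for whatever criterion a deployment actually agrees on; it is
  user-pluggable by design.
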