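# Methods

## Ranking model

The unit of analysis is the species-level genome bin (SGB). Abundances
are relative (fractions of the profiled community), stored internally on
[0, 1]; the MetaPhlAn merged-table dialect's 0–100 percentages are
converted at the I/O boundary because the arcsin√ variance-stabilizing
transform needs fractions.

**Partial Spearman.** For abundance x, marker y and covariates Z (sex,
age, BMI by default), all variables are rank-transformed with average
ties; the ranks of x and y are each residualized on an intercept plus the
ranks of Z by least squares, and ρ is the Pearson correlation of the two
residual vectors. With no covariates this is exactly plain Spearman. The
p-value uses a t reference with n − 2 − k degrees of freedom. Zeros in
abundance vectors are data (ties), never missing; rows missing y or any
covariate are dropped pairwise per marker. A correlation cell needs at
least 30 complete cases (and k + 3), otherwise the species is "not ranked
in this cohort" for that marker — the threshold bounds rank noise in
small cohorts. `correlate_all` residualizes all species against the
covariates in one pass per marker; this is algebraically identical to the
cell-wise definition and is tested against it.

**Orientation and percentiles.** Each marker carries a direction (+1
higher-is-healthier, −1 the reverse). The oriented score direction·ρ is
sorted descending and converted to percentile = average-tie rank / n, so
the species most favourably associated with health gets the smallest
percentile and the percentile multiset is {1/n, …, 1} for distinct
scores. The convention "percentile → 0 means favourable" is fixed
throughout the package.

**Aggregation.** Marker percentiles are averaged within category
(personal / fasting / postprandial / dietary), the three non-dietary
category means are averaged (unweighted) into a per-cohort health value,
and per-cohort values are averaged (unweighted) into the final
health-rank. The diet-rank averages the dietary category across cohorts.
Missing (cohort, category) combinations are simply skipped — cohorts
differ in marker availability. A species needs at least `min_cohorts`
(default 2) cohorts to receive a final rank. Prevalence filtering
(strictly greater than 20% of samples with nonzero abundance) is applied
per cohort before correlation, so the union of per-cohort species sets
determines who can be ranked.

**Agreement.** Cross-cohort consistency is summarized by ICC(2,1) —
two-way random effects, absolute agreement, single measurement — computed
from the standard mean-squares decomposition with species as targets and
cohorts as raters, and by plain Spearman concordance between rank
vectors. ICC(2,1) was chosen because cohorts are treated as a random
sample of populations and absolute agreement (not mere consistency) is
the scientifically relevant question.

## Sample scoring

`rank_sum` sums s = 1 − 2·rank over ranked species present (abundance
strictly > 0), mapping ranks in (0, 1] to [−1, 1) with favourable species
contributing positively — healthier microbiomes score *higher*. The sign
convention is recorded in the output metadata so effect signs can be
flipped consistently when comparing against conventions that orient the
score the other way. `weighted_rank_sum` multiplies each term by
arcsin(√abundance), damping the compositional dominance of highly
abundant species. Cumulative abundances of the k = 50 extreme sets are
transformed after summation (transform of the set total), and set
membership ties at the k-th position are broken lexicographically by SGB
id, making the sets deterministic.

## Effect estimation and pooling

Per-dataset effects come from OLS of the outcome on intercept + group
(0/1; control or lower-BMI arm is the reference) + covariates.
Standardization divides the group beta and its SE by the pooled
within-group outcome SD — the standard SMD construction; the choice is
isolated in `beta_to_smd` so an alternative formula is a one-line swap.

Paule–Mandel τ² solves Σ wᵢ(τ²)(yᵢ − ȳ(τ²))² = k − 1 with
wᵢ = 1/(vᵢ + τ²). The criterion is monotone decreasing in τ², so the
root is found by bisection on [0, 100·max vᵢ] to 1e-8 (≤200 iterations),
clamped to 0 when the criterion is already below k − 1 at τ² = 0. CIs
are normal-theory (±1.96·se) without Knapp–Hartung adjustment. A single
study passes through with τ² = 0 and a degenerate-meta note.

When two datasets reuse one control arm, their SMDs are correlated; the
covariance uses the standard shared-arm approximation
cov = 1/n_c + smdᵢ·smdⱼ/(2(nᵢ + nⱼ)), and pooling becomes GLS:
pooled = (1ᵀΣ⁻¹y)/(1ᵀΣ⁻¹1). With a diagonal Σ this reduces exactly to
the inverse-variance fixed-effect mean. The approximation presumes
coherent inputs (se² ≈ 1/n_case + 1/n_control + …, as produced by
`fit_group_effect` + `beta_to_smd`); a 1e-10 jitter guards borderline
positive definiteness, and genuinely inconsistent matrices are rejected.

Binomial direction-count tests are exact; the two-sided p doubles the
smaller tail (capped at 1). Published direction counts do not always
state sidedness — 34/47 reproduces its printed value (0.003) two-sided,
while some printed values match the one-sided tail — so one-sided
alternatives are exposed via a flag with two-sided as the default.

Country contrasts across datasets use a linear mixed model with a random
intercept per dataset and fixed effects for country and (standardized)
sequencing depth, falling back to OLS with a notice when only one dataset
exists per country.

## Intervention analysis

Species with prevalence ≥ 10% at *both* timepoints are tested with a
two-sided Wilcoxon signed-rank test on paired abundances. Zero
differences are dropped (standard practice); the exact null distribution
is used for ≤ 25 informative pairs without ties, otherwise the normal
approximation with tie correction. Effect size is log₂(mean endpoint /
mean baseline) on raw fractions — no pseudocount in the normal path (the
prevalence gate prevents zero means), with a 1e-8 guard for degenerate
input. P-values are BH-adjusted; significance thresholds are
configuration (Q < 0.01 and Q < 0.1 are the two cited trial
conventions; the synthetic drivers use 0.05). Enrichment compares the
health/diet ranks of significantly increasing vs decreasing species with
a two-sided Mann–Whitney U test; a side with fewer than three ranked
species yields an insufficient-data result rather than an error.

## ML association harness

The harness is the evaluation protocol, not the learner: the model is
injected via a factory (the documented reference configuration is a
1000-tree random forest with √-features; tests and drivers inject
logistic regression for speed). Features are arcsin√-transformed
abundances. Continuous targets are binarized by quartile contrasts (1v4,
123v4, 1v234) using average-tie fractional ranks with stable index order
at boundaries. Splits are stratified 80:20, repeated (100 by default),
and group-aware: members of one group (e.g. a twin pair) always land on
the same side. The splitter permutes each class block with a
per-repeat generator and orders blocks by their smallest member index —
a label-value-independent scheme, so flipping 0/1 labels reproduces
byte-identical splits and per-repeat AUC is exactly antisymmetric.
A repeat whose training fold lacks a class is redrawn (≤10 times).

## Synthetic data

The generator emulates the structure of multi-cohort SGB profiles, not
any real dataset: per-SGB Bernoulli presence (probabilities uniform on
[0.25, 0.9]) × log-normal abundance (per-SGB log-mean ~ N(−6, 1.5),
within-SGB spread 1.0), closed per sample to a random total in
[0.85, 1.0] to mimic unclassified mass. Markers are
direction-consistent linear combinations of *standardized rank-transformed*
planted-species abundances (so the planted signal is exactly what a
partial Spearman estimates) plus sex/age/BMI loadings (0.3/0.3/0.4) and
unit Gaussian noise. The standard study conditions are 3 cohorts × 500
samples × 200 SGBs with 20 favourable and 20 unfavourable planted species
at effect 0.4. An optional switch makes BMI load on the planted species
themselves, to exercise confounder removal by the partial correlation.

Case-control collections shift the planted species' presence logit and
log-mean by ∓case_shift in cases (favourable depleted, unfavourable
enriched); a `presence_shift=False` mode perturbs abundance only, the
regime where the weighted score should outperform the presence-based one.
Paired intervention designs give each subject a latent per-SGB log
abundance and a presence pattern shared by both timepoints, with
independent within-subject re-draws (sd 0.4) and the intervention shift
added at the endpoint — reproducing the strong temporal self-correlation
of real gut profiles that paired tests exploit. All generators are pure
functions of their configuration including the seed.

What the synthetic data does *not* emulate: real taxonomies and
phylogenetic correlation between species, realistic marker
co-correlation structure, batch/primer effects, and the long-tailed
prevalence distribution of rare species. Passing tests therefore
demonstrate the correctness and calibration of the statistical machinery
under the stated generative model, not effect sizes transferable to real
cohorts.

## Numerical and design notes

- Percentile and quartile ties always use average ranks; deterministic
  secondary orderings (SGB id, stable index) break boundary ties.
- Compositional closure attenuates intervention log₂ ratios when many
  species shift together (the shifted set inflates the denominator
  total); single-species recovery is unbiased up to heavy-tailed
  sampling noise, which the drivers tame by averaging replicate trials.
- Pipeline stages derive their seeds from one master seed via SHA-256
  named substreams, so adding or reordering stages never changes another
  stage's results; all artifacts are plain-text TSV/JSON and runs are
  byte-reproducible.
- Problem sizes in tests and drivers (e.g. 200 null meta-analysis
  simulations of 5 datasets × 40/arm; 50 intervention replicates at 40
  pairs) were chosen as the smallest collections at which the Monte-Carlo
  error of the calibration quantities is well below the decision bands.

## Known limitations

- The ranking is associational; no causal claims are supported.
- The shared-control covariance is an approximation for SMDs from
  *unadjusted* contrasts; with covariate-adjusted betas it is heuristic.
- ICC variant choice (absolute agreement) and binomial sidedness are
  conventions; both are documented and the latter is switchable.
- `mixed_country_effect` relies on statsmodels MixedLM convergence; near
  collinear designs may fall back with wide standard errors.
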