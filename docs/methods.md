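# Methods

`proteovary` implements a meta-analysis workflow for proteome variation
across individuals: how strongly proteins that work together co-vary in
abundance, which protein complexes hold their composition fixed and which
tolerate variable subunits, and how much of that variation sex and diet
explain. This note documents the statistical machinery, the defaults, and
the choices made where the design was open.

## Data model and pre-processing

Abundance matrices are proteins × samples, missing-aware (NaN), on linear or
log2 scale. All correlation and normalization steps operate in log2 space;
linear inputs are log2-transformed first. Identifier matching is exact
string equality — inputs are assumed pre-mapped to one identifier space
(no ortholog or multi-ID collapsing is attempted).

Each sample is screened with the Shapiro–Wilk test (values subsampled to
5,000 when larger, seeded). Quantile normalization is applied only when more
than 10% of tested samples reject normality at p < 0.01; the 10% trigger is
this package's own choice (a conditional "normalize only suspect datasets"
policy), and can be forced or suppressed. Quantile normalization replaces
the k-th smallest value in each sample by the mean of the k-th smallest
values across samples; samples with missing entries are mapped onto the mean
quantile curve by linear interpolation of their own rank grid, ties receive
the mean of the values they would have received, and missing entries stay
missing. Completeness filtering removes proteins quantified in fewer than
50% of samples (inclusive threshold).

## Module recovery (ROC/AUC)

For a module category, condition positives are protein pairs inside the same
module (interaction tables: pairs above a combined-score cutoff, default
0.7; pathways: within-complex pairs are removed from the positives so the
pathway signal is not driven by complexes). Negatives are an equally sized,
seeded uniform sample of quantified pairs belonging to no module of the
category. Pairwise Pearson correlations use jointly non-missing samples and
require ≥ 6 overlapping samples (paper-silent; 6 is the minimum at which a
correlation estimate is at all meaningful). The ROC sweeps descending
thresholds over the observed r values with all ties crossing together
(equivalent to counting tied pairs as half-concordant, which prevents
optimistic staircases); AUC is the trapezoid integral and is tested to equal
exhaustive tie-aware concordant-pair counting. The companion significance
estimate is the mean one-sided Mann–Whitney U p-value over repeated
subsamples (defaults 1000 × 1000; lists shorter than the subsample size are
resampled with replacement). Note the subsample mean p tracks the parent
comparison's p, so under a true null it is uniform across cohorts rather
than pinned at 0.5. Categories with fewer than 100 positive pairs are
reported missing.

## Complex landscape

Per dataset, a complex with ≥ 5 quantified members is summarized by the
median of all pairwise subunit correlations, ranked within the dataset
(average rank on ties, rank fraction = rank / number of qualifying
complexes, so datasets with different catalogs are comparable). The
aggregated landscape is the median rank fraction across datasets (≥ 2
required, otherwise NA); the top 25% are labelled stable and the bottom 25%
variable, with quartiles computed on the aggregated landscape rather than
per dataset. Printed cutoff anchors from any particular cohort are never
hard-coded. Two nulls are available: size-matched decoy complexes drawn from
module-free proteins, and within-protein permutation (each protein's values
shuffled independently across samples — marginals preserved, covariance
destroyed; "permuting the dataset" is not otherwise specified upstream, and
this unit is the one that exactly preserves per-protein distributions).
Cross-dataset consistency compares observed pairwise Spearman correlations
of complex rank vectors against the permutation null with a two-sided
t-test (one-sample form when only a single dataset pair exists).

## Stoichiometry decomposition

Complex normalization subtracts, per sample, the symmetric trimmed mean of
the complex's quantified subunit log2 values (sort, drop floor(0.25·k) from
each end, average — an exact "interquartile mean"); a sample needs ≥ 3
quantified subunits for a defined reference. Proteins in several complexes
get the average of their per-complex normalized values. Subtraction in log2
space corresponds to a ratio on the raw scale, so complex-level abundance
shifts cancel exactly (tested to 1e-12).

Subunit variance is computed across samples on the normalized values
(subunits present after normalization in ≥ 50% of samples; the variance uses
only samples with a defined complex reference) and standardized to z-scores
within each complex (ddof-1 sd; all-equal variances give z = 0; ≥ 3 eligible
subunits required). Within-dataset component calls use one-sided
standard-normal tail probabilities of z per direction at α = 0.05 — the
standard-normal reference is a declared choice, and |z| > 1.5 is kept only
as a display label. The cross-dataset call for a consistently variable
subunit is a one-sided Welch t-test of the protein's z-scores across
datasets against the pooled z of all sibling subunits of the same complex
across datasets (alternative: greater), BH-adjusted across all tested
(complex, protein) pairs. Welch is used because sibling and candidate
z-distributions have no reason to share a variance.

## Covariate effects

Abundance: per-complex median log2 abundance per sample (subunits quantified
in ≥ 50% of samples, ≥ 5 eligible subunits), then a two-sided two-sample
t-test per factor with Cohen's d (pooled n−1-weighted sd, sign = male−female
or high_fat−chow) and BH adjustment; q < 0.01 flags significance. Factor
tests pool across the other factor's levels.

Stoichiometry: per-subunit OLS of the complex-normalized values on an
additive intercept + sex + diet design (both factors always in the model so
each contrast controls for the other; no interaction term), casewise
deletion of missing values. Variances are moderated empirically:
e_g = log s²_g − ψ(d_g/2) + log(d_g/2) has mean log s₀² + ψ(d₀/2) − log(d₀/2)
and excess variance ψ′(d₀/2) under the scaled-F hierarchy; matching the
empirical mean and variance of e (trigamma inversion by Newton iteration)
yields (d₀, s₀²). When the excess variance is non-positive, d₀ = ∞ and s₀²
is the arithmetic mean of the variances — the pooled-variance estimate,
matching the convention of the standard Bioconductor implementation, against
which the estimator is cross-checked in the tests. The moderated t uses the
posterior variance (d₀s₀² + d·s²)/(d₀+d) on d₀ + d degrees of freedom
(normal reference at d₀ = ∞; d₀ = 0 reproduces the ordinary t exactly).
Per-complex verdicts combine the components' BH-adjusted q-values with
Fisher's method (−2Σln q on 2k df) and BH-adjust the combined p-values
across complexes. Combining adjusted q-values rather than raw p-values is
statistically unconventional but is retained as the primary mode to mirror
the upstream procedure; `use_q=False` combines raw p-values instead.

## Effect sizes (ridge regression)

Responses are module median abundance, complex-normalized subunit vectors
(stoichiometry), or single-protein profiles; predictors are 0/1 dummies for
sex, diet, or both. Ridge regression with penalty α = 1 on the slopes only
(intercept unpenalized, data centered internally) is solved in closed form —
(XcᵀXc + αI)⁻¹Xcᵀyc — which is numerically identical to the textbook
estimator and to scikit-learn's `Ridge` (asserted to 1e-9); the closed form
keeps the permutation loops fast. Cross-validation uses 10 folds stratified
by the predictor-level combination (re-drawn up to 100 times if a training
split would miss a level), and the "global R²" is 1 − SS_res/SS_tot on the
pooled out-of-fold predictions. The reported effect size is the median
global R² over 5 repeated fold assignments, and additionally over subunit
vectors for stoichiometry readouts; negative R² is reported as-is, with
max(R², 0)·100 as a "variance explained %" convenience column. Pathways
enter only if their median pairwise correlation beats a within-protein
permutation null at BH q < 0.1. Significance is an empirical FDR: predictors
reshuffled per module (default 200 times), the full ridge-CV pipeline
re-run, empirical p = (1 + #{null ≥ observed})/(1 + n_perm), BH across
modules within each readout × predictor-set stratum.

## Synthetic cohorts

The generator plants exactly the structure the pipeline is designed to
recover. Per complex, a latent per-sample abundance factor with unit
variance carries the configured fractions of sex and diet variance
(balanced two-level factors, ±½ coding); each subunit loads on the factor so
that a configured fraction ("latent strength") of its total variance
noise_sd² (default sd 0.5 log2 units, a typical between-individual spread)
is shared. Variable subunits have their loading shrunk (default to 0) and
their residual variance multiplied (default ×4). Stoichiometric covariate
effects are additive log2 shifts on one designated subunit per factor level.
Pathways repeat the construction at weaker strength (default 0.2),
background proteins are pure noise, and missingness is completely at random
(default 10%). Replicate datasets share every architectural parameter and
draw independent latent factors, noise and masks. Baseline abundances are
N(20, 2) in log2 space — the magnitude range of deep proteome surveys.

What the generator does **not** emulate: intensity-dependent dropout
(available behind a flag, off by default), shared peptides, batch
structure, heavy-tailed or skewed abundance noise, correlated missingness,
and overlap between pathway and complex membership. Passing tests therefore
demonstrate correct recovery of planted structure under Gaussian log-space
noise and MCAR missingness, not robustness to every artifact of real
MS data.

`planted_r2` evaluates the target variance fraction for effect-size recovery
numerically on a 100,000-sample virtual cohort from the noise-free
generative components; it reproduces the complex architecture draw and
ignores variable-subunit decoupling, so it should be used with cohorts
configured without variable subunits (as the recovery analyses are).
Because the median over k subunits retains a little subunit noise, the
explained fraction of the median response is slightly below the planted
fraction of the latent factor unless the latent strength is high; recovery
analyses therefore use tight complexes (strength ≥ 0.95, k = 10–20), where
the attenuation is under 2%.

## Problem sizes and determinism

Simulation-based checks use cohorts of 100–400 samples, 3–100 complexes and
up to 6 replicate datasets, with 30–200 permutations — sizes at which every
planted quantity is comfortably recoverable on a single CPU in minutes.
Every stochastic step takes an explicit seed; the CLI derives per-stage
seeds from a master seed via SHA-256, so one integer reproduces an entire
run byte-for-byte.

## Known limitations

- The landscape quartile labels are relative within the analyzed catalog;
  they are not absolute co-abundance thresholds.
- The cross-dataset variable-component test treats datasets as exchangeable
  replicates; systematic platform differences would violate that.
- Fisher combination of BH-adjusted q-values (primary mode) is conservative
  and its combined p-values are not uniformly distributed under the null.
- The ridge effect-size estimate is attenuated when the response carries
  substantial subunit-level noise (see the planted-R² discussion above).
- With heavy missingness the per-sample trimmed-mean reference can shift
  between samples, inflating apparent stoichiometric variance.
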