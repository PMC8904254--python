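# Methods

This note records the statistical conventions implemented by `immunotrack`,
in enough detail to re-derive every number the package produces.

## Repertoire metrics

Frequencies are computed over **productive** templates only: for clone *i*
with template count *nᵢ*, `pᵢ = nᵢ / Σ_productive nⱼ`.

- **Simpson clonality** is `√(Σ pᵢ²)`. For a uniform repertoire of *R*
  clones it equals `1/√R`; for a monoclonal sample it is 1.
- **Rarefied richness** at depth *d* is the mean number of unique clones in
  repeated draws of *d* templates **without replacement** (multivariate
  hypergeometric). Its analytic expectation,
  `Σᵢ [1 − C(N−nᵢ, d) / C(N, d)]` with `N = Σ nᵢ`, is implemented
  separately (`rarefied_richness_expectation`) and used as an oracle in the
  tests. At `d = N` richness equals the unique productive clone count.
- **T-cell fraction** divides total T-cell templates by total nucleated
  cells when a reference-gene-derived cell count is available.

## Differential clone abundance

For each clone present in either of two samples with productive totals
`n₁`, `n₂`: conditional on the clone total `K = k₁ + k₂`, under the null of
equal underlying frequency `k₁ ~ Binomial(K, n₁/(n₁+n₂))`. The two-sided
p-value doubles the smaller tail, including the observed outcome in the
tail, and is capped at 1 (a min-likelihood variant is available). Clones
with `K <` `min_total` (default 2) are excluded. P-values are adjusted by
Benjamini–Hochberg across all tested clones; a clone is *enriched* when its
q-value is at or below α = 0.01 and its frequency is higher in the
comparator sample.

The **vaccine-associated clone set** for a subject is the union of clones
enriched in any antigen-stimulated sorted sample versus baseline blood.
Tracking reports the set's cumulative productive frequency per
timepoint/compartment; clones absent from a sample contribute zero.

## ELISPOT positivity (DFR)

Replicate spot counts (wells too numerous to count are capped at 500) are
compared by an exact permutation test on the difference of means: all
`C(nₐ+n_c, nₐ)` assignments of the pooled counts are enumerated when that
number is at most 20,000, otherwise at least 10,000 seeded random
relabelings are drawn. The p-value is the fraction of assignments whose
statistic is at least the observed one (the observed partition counts
itself, so the exhaustive p is never below `1/C(nₐ+n_c, nₐ)`). The `2x`
variant tests antigen counts against doubled control counts. Calls:
**significant** if `p ≤ 0.05` with positive magnitude (mean antigen − mean
control); otherwise **DR** if the antigen mean is at least twice the
control mean with positive magnitude; otherwise **NS**. Cohort-level
before/after comparisons use the two-sided Wilcoxon matched-pairs
signed-rank test (≥5 pairs). ICS positivity subtracts the unstimulated
background and requires at least 0.2 percentage points.

## Binomial confidence intervals

Three 95% intervals are provided:

- **Wilson score** — inverts the score test; used for the headline response
  rates.
- **Clopper–Pearson** — exact beta-quantile interval; at `x = n` the lower
  bound is `(α/2)^(1/n)`.
- **Logit-Wald** — `expit( log(x/(n−x)) ± z·√(1/x + 1/(n−x)) )`; matches the
  intervals reported alongside logistic-model estimates. Undefined at
  `x ∈ {0, n}` (raises a degenerate-input error).

## Survival

Kaplan–Meier curves use the product-limit estimator; the reported median is
the earliest time at which the survival function is ≤ 0.5 (infinite when
never reached), with its CI read off the confidence-band columns. Median
follow-up uses the **reverse** KM estimator: event and censoring indicators
are swapped, so censored patients contribute follow-up events.

## Matched external-control comparison

Exact matching on six covariates (age group, sex, LDH, M stage, BRAF,
PD-L1). Records missing any covariate are excluded and reported. For each
covariate combination with `c` cases and `m > 0` matching controls, every
control receives weight `c/m`, so weighted control mass equals the case
count per combination — the weighted control covariate distribution equals
the case distribution exactly. Cases with no matching control are reported
as unmatched.

Effects on the matched cohort (cases weight 1, controls their weights):

- **Response**: weighted logistic regression of objective response (CR/PR)
  on the arm indicator, robust (HC0) standard errors; reports the odds
  ratio with CI and per-arm fitted rates with logit-Wald CIs. With an
  arm-only model, fitted per-arm rates equal the weighted empirical
  proportions. Complete separation returns an infinite-odds-ratio sentinel
  rather than a spurious estimate.
- **Survival**: weighted Cox proportional-hazards model (Efron ties,
  robust variance) reporting the hazard ratio with CI; fitting requires at
  least one event per arm.

## Auxiliary assays

- **Expression panel QC/normalization**: per sample, fail on binding
  density outside [0.05, 2.25] or positive-control linearity R² < 0.75;
  background threshold = mean + 2 SD of negative probes (floor to zero by
  default, or subtract); scale by the positive-control factor (reference
  over this sample's positive geometric mean, accepted in [0.3, 3]); then
  by the housekeeping factor from stable housekeeping genes (accepted in
  [0.1, 10]). Stable genes lie below the fitted mean–variance trend of
  log2 counts (minimum 3). Factor references default to across-sample
  means; fixed references make per-sample normalization exactly
  scale-free.
- **RT-qPCR**: relative expression `2^−ΔΔCt` with missing amplification
  mapped to the 40-cycle ceiling.
- **H-score**: `3·%strong + 2·%moderate + %weak`, range 0–300; the three
  percentages must not exceed 100 in total.
- **Proximity index**: percentage of CD8⁺ cells with at least one PD-L1⁺
  cell within a distance cutoff (20/40/60/80 µm conventionally), computed
  with a k-d tree and identical to the brute-force all-pairs answer.

## Synthetic data

Repertoires follow a power-law (Zipf) clone distribution (default exponent
1.0, 5,000 clones, 20,000 templates) with a configurable non-productive
fraction; defaults put baseline Simpson clonality in a realistic 0.05–0.2
band. Vaccine clones are planted with per-timepoint expansion folds, and
sorted samples mix vaccine clones at a specified purity with background.
ELISPOT wells are negative-binomial; cohorts draw covariates from melanoma
marginals, response from a logistic model with an arm effect, and survival
from response-stratified Weibull distributions with uniform censoring.
Cell maps are homogeneous Poisson or "attract" patterns in which PD-L1
cells are placed within a small radius of CD8 cells (round-robin over a
shuffled CD8 order, so enough PD-L1 cells cover every CD8 cell). All
generators draw from named, counter-based seed streams: adding a generator
does not perturb existing streams, and reruns are byte-identical.
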