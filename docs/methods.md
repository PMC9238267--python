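# Methods

## Concentration index

The index is computed as C = (2/μ)·cov(h, r) with *population* covariance
(divide by n); under that convention the covariance form is an exact
identity, and on tiny datasets the implementation agrees with a brute-force
deviation-product oracle to 1e−12 (tested exhaustively for n ≤ 6 with
integer health values).

**Fractional ranks.** r_i = i/n in the ascending living-standards order,
i = 1 for the poorest. The i/n rule is ill-defined under ties, so tied
blocks receive the mean of their positions' i/n values. This midpoint rule
changes nothing in the untied case and makes the index invariant to
permutations of tied rows. Ranking defaults to raw income; the ranking
variable is a parameter everywhere.

**Inference.** Standard errors use the convenient-regression estimator:
the OLS slope of 2σ²_r·h_i/μ on r_i equals C algebraically, and its
HC1 heteroskedasticity-robust standard error is reported with a
normal-approximation two-sided p-value. This treats μ as known — a standard
approximation; it is reported as such, not as an exact sampling variance.
With n < 3 or degenerate ranks the standard error is undefined and reported
as NaN.

**Degenerate inputs.** A zero-mean health variable makes C undefined
(division by μ) and raises rather than returning a sentinel. The [−1, 1]
bound is asserted only for nonnegative h; negative values are admissible
as long as μ ≠ 0.

## Indirect standardization

A logistic model of each binary outcome on ln income, need variables
(default: age, gender, chronic_count, srh, adl, iadl) and controls
(default: education, residence, employment, insurance_count). The need /
control split is configurable — survey analyses differ on where, e.g.,
insurance belongs — and the lists used are recorded on the model object.
Income enters as ln(max(income, floor)) with floor 1 currency unit, since
zero incomes occur in surveys. Categorical variables become indicator sets
with the first (alphabetical) level as reference; the level coding observed
at fit time is reused at prediction time.

Fitting is maximum likelihood (Newton, falling back to BFGS when Newton
stalls on a flat likelihood); a fit that still has not converged — which in
practice means separation in a sparse covariate cell, where the ML estimate
is infinite — raises an error rather than returning silent defaults. By the
logistic score equations the mean fitted probability equals the observed
outcome rate on the fitting sample; the test suite asserts this to 1e−8.

Downstream CI and decomposition use the predicted probabilities by default;
a switch (`use_standardized=False`) reruns everything on the raw outcomes
for sensitivity analysis.

## Decomposition

The outcome (binary or probability-valued) is fitted by OLS — a linear
probability model. The choice is deliberate: the adding-up identity
C = Σ η_k C_k + GC_ε/μ is an algebraic consequence of OLS residual
orthogonality and holds only for a linear model. The identity is asserted
to 1e−10 on every fixture. Per-regressor contributions are computed as
2·β_k·cov(x_k, r)/μ, which equals η_k·C_k whenever the regressor mean is
nonzero and remains well-defined when it is not (the reported C_k is NaN
for a zero-mean regressor). Indicator regressors are treated like any other
0/1 variable.

Percentage contributions 100·Q_k/C are reported unclipped — individual
shares may be negative or exceed 100% when signed contributions cancel.
When |C| < 1e−6 the shares are NaN with a warning instead of dividing by
approximately zero. Rank-deficient designs raise a collinearity error
naming the dependent columns (identified by pivoted QR).

Contributions aggregate into six reporting categories — demographic,
health, economic, insurance, medical distance, work — with a configurable
regressor→category map. The default table has no distance-to-facility
variable, so the medical-distance category exists as an empty slot and
reports zero.

## Self-organizing map

Three SES features per respondent — income, average annual expenditure, and
the household-facilities score (six facilities, 100 points each; the ×100
is affine and therefore a no-op after z-scoring, which is asserted) — are
standardized to mean 0, SD 1 within the wave (population SD). A 2×2 square
Kohonen map is trained on them: four codebook vectors, sequential updates
w ← w + η(t)·θ(t, grid distance)·(x − w) with Gaussian neighborhood.
Neurons are numbered bottom-row-left-first (1, 2 bottom; 3, 4 top).

Training schedule (our choice; no toolbox defaults are being matched):
learning rate 0.5 → 0.01 and neighborhood radius 1 → 0.01, both linear over
epochs × n steps; 500 epochs default; codebook initialized from four seeded
random data rows. The seed is mandatory. When record ids are supplied, the
presentation order is derived from the id-sorted data, so training is
invariant to row permutations of the input table.

The most mutually distant codebook pair (Euclidean, lowest-index pair on
exact ties) defines the extreme groups; the member-mean of the composite
(z_income + z_expenditure + z_facilities)/3 labels which is low- and which
high-SES. Respondents on the other two neurons belong to neither group. A
map whose maximum codebook distance is below 1e−6 is flagged degenerate and
grouping is refused.

## Pipeline

Per wave: listwise deletion on the used columns (count logged) →
standardize → rank → full-sample CI → decomposition → SOM grouping →
within-group CIs. Within-group CIs re-rank income inside each group by
default, treating the homogeneous group as its own analysis population;
full-sample ranks are available as an option. Within-group decompositions
are supported but off by default. A failed wave does not block the others:
completed waves are written and a study error listing the failures is
raised (nonzero exit from the CLI). Identical inputs and config give
byte-identical output CSVs.

## Synthetic data generator

The generator emulates a middle-aged/elderly household-survey wave.
Defaults are stylized around a 2011-like descriptive profile: lognormal
income (log-mean 8.33, log-SD 1.13 ⇒ mean ≈ 7.9k, SD ≈ 12.8k currency
units/year, right-skewed); expenditure lognormal with correlation 0.5 to
log income; facilities Binomial(6, p) with p increasing in the income
latent (mean ≈ 2.2); education 28/62/10% and residence 9/25/66% splits;
plausible health-status marginals; utilization baselines at rates
0.26 / 0.087 / 0.46 for outpatient / inpatient / prevention.

Outcomes are Bernoulli with logit p = baseline + γ·(r − r̄) + need effects
on centered need variables, where r is the *income fractional rank*. Acting
on the rank rather than raw income makes the implied ground-truth CI
insensitive to the income distribution's shape, so recovery tests compare
against a Monte-Carlo oracle (`planted_ci_oracle`, simulating the same
configuration at large n) rather than a distribution-specific closed form.
Default gradients (0.1 / 0.5 / 0.8) plant mild pro-rich inequality ordered
prevention > inpatient > outpatient.

**Blob mode.** With `cluster_separation = s > 0`, respondents split into
two latent blocks whose SES latents are offset by ±s/2. In this mode income
and expenditure are *affine* in the latent (location-shifted Gaussians)
rather than lognormal: exponentiation would warp the pooled z-score
geometry, so the planted "s SD" separation would not be the separation the
clustering features actually see. Blob mode exists only for
cluster-recovery tests; the planted block label is emitted as `ses_block`.

**What the generator does not emulate.** Longitudinal linkage of
respondents across waves, survey weights and complex sampling, realistic
joint dependence of education/residence/health on income, item
nonresponse patterns, and reporting error. Passing recovery tests therefore
demonstrates that the estimators recover what was planted under a clean
data-generating process — not that real survey estimates are unbiased.

## Problem sizes and tolerances

Exact identities (perfect-equality zero, adding-up, percentage closure,
brute-force equivalence) are asserted at 1e−6…1e−12 on hundreds to
thousands of fixtures. Monte-Carlo recoveries use n = 50,000 samples
against an oracle at n = 400,000 with a ±0.01 band; null-gradient checks on
rare outcomes use a 4-standard-deviation sampling band (the CI of a
Bernoulli(p) outcome has sampling SD ≈ (2/p)·√(p(1−p)/12n), which exceeds
0.01 for p ≈ 0.09 at n = 50,000). SOM blob recovery uses n = 400 at 6-SD
separation and 500 epochs; pipeline-level tests run the SOM at reduced
epochs since group recovery there is not the property under test.

## Known limitations

- The convenient-regression standard error ignores estimation of μ and the
  induced correlation across ranks; it matches common practice but is not
  an exact variance.
- The linear probability model can predict outside [0, 1]; it is used only
  as the decomposition's accounting device, never for prediction.
- With four neurons and two planted clusters the SOM's non-extreme neurons
  absorb a substantial share of respondents; group sizes are data-driven
  and can be small (the high-SES group in skewed-income samples
  especially), making within-group inference noisy.
- Bounded-outcome corrections of the CI (Erreygers/Wagstaff normalization)
  are intentionally out of scope; the plain index is reported.
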