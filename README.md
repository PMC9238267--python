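# healthineq

Measuring and decomposing income-related inequality in healthcare
utilization from survey microdata — with identification of socioeconomically
homogeneous subgroups for within-group inequality analysis.

## Who this is for

Health economists and epidemiologists analyzing person-level survey tables
(one row per respondent per wave: demographics, income, expenditure,
household facilities, health status, insurance, and binary utilization
indicators for outpatient, inpatient and preventive care) who want to answer
three questions: how unequal is utilization with respect to living
standards, which factors drive that inequality, and does the inequality
persist within groups of people who share a similar socioeconomic level.

## The statistics

**Concentration index.** For a health variable *h* with mean μ and
fractional rank *rᵢ = i/N* in the ascending living-standards ordering
(*i* = 1 poorest),

> C = (2/μ) · cov(h, r)

C ∈ [−1, 1] for nonnegative *h*; 0 means perfect equality, C > 0 pro-rich
concentration, C < 0 pro-poor. Ties in living standards receive midpoint
ranks, making the index permutation-invariant. Standard errors come from
the convenient regression (the OLS slope of 2σ²ᵣ·hᵢ/μ on rᵢ equals C; its
HC1-robust standard error is reported).

**Indirect standardization.** Each binary outcome is first modelled by
logistic regression,

> logit(pᵢ) = α + β ln incomeᵢ + Σₖ γₖ xₖᵢ + Σₚ δₚ zₚᵢ

on need variables *xₖ* (age, gender, chronic conditions, self-reported
health, ADL/IADL) and controls *zₚ* (education, residence, employment,
insurance). The fitted probabilities replace the raw 0/1 outcome downstream,
so inequality comparisons are net of composition differences in need.

**Wagstaff decomposition.** Fitting the (standardized) outcome by a linear
additive model *y = α + Σₖ βₖxₖ + ε* gives the exact identity

> C = Σₖ (βₖ·x̄ₖ/μ)·Cₖ + GC_ε/μ

where Cₖ is the regressor's own concentration index, ηₖ = βₖx̄ₖ/μ its
elasticity, and GC_ε = 2·cov(ε, r) the generalized concentration index of
the residual. Percentage contributions 100·Qₖ/C (plus the residual's share)
sum to 100%; individual shares may be negative or exceed 100%.

**Homogeneous groups.** Income, expenditure and the household-facilities
score (100 points per facility) are z-scored and clustered with a 2×2
Kohonen self-organizing map; the two most mutually distant codebook vectors
define the low- and high-SES groups, and the concentration index is
recomputed within each group (re-ranking members internally).

A synthetic survey generator with a *plantable* rank gradient
(logit pᵢ = baseline + γ·rᵢ + need effects) supplies ground truth for every
stage, including a Monte-Carlo oracle for the planted CI and planted SES
blobs for cluster-recovery checks.

## Worked example

```python
from healthineq import (SyntheticConfig, generate_population,
                        StandardizationModel, fractional_rank,
                        concentration_index, decompose_ci,
                        build_ses_features, SESSelfOrganizingMap)

wave = generate_population(SyntheticConfig(n=5000, seed=1))

std = StandardizationModel(wave, "prevention").fit()
h = std.predict()                                  # standardized utilization
ranked = fractional_rank(wave["income"].to_numpy())
print(concentration_index(h, ranked).summary())

dec = decompose_ci(h, std.model.exog.drop(columns="const"), ranked)
print(dec.category_summary().round(4))
```

prints

```
Concentration Index
===================
outcome:   h
n:         5000
mean:      0.467200
CI:        0.063827
Std.Err:   0.001507
p-value:   0.0000
95% CI:    [0.060873, 0.066781]

                  contribution   percent
category
demographic             0.0001    0.0855
health                 -0.0010   -1.6235
economic                0.0647  101.4259
insurance              -0.0001   -0.1058
medical_distance        0.0000    0.0000
work                    0.0000    0.0484
```

The CI of 0.064 (p < 10⁻⁴) says preventive-care use in this simulated wave
is concentrated among the rich — as planted (the generator's default
prevention gradient is pro-rich). The decomposition attributes essentially
all of it to the economic category (income itself drives the planted
gradient), with small offsetting shares elsewhere; shares sum to 100%.

Grouping the same wave with the SOM and recomputing within groups:

```python
features = build_ses_features(wave)
som = SESSelfOrganizingMap(features, epochs=100, seed=7,
                           record_ids=wave["id"].to_numpy()).fit()
labels = som.group_labels()    # 'low' / 'high' / 'none'
```

selects extreme pair (2, 3) with a low-SES group of n=2879 (CI 0.056) and a
small high-SES group of n=44 (CI 0.009, not significant) — within-group
inequality is attenuated relative to the full sample, as the restriction of
the rank range implies.

The same steps are available from the shell:

```sh
healthineq simulate --seed 1 --n 5000 --out pop.csv
healthineq ci --in pop.csv --outcome prevention --rank-by income --out ci.csv
healthineq standardize --in pop.csv --outcome prevention --out std.csv
healthineq cluster --in pop.csv --seed 7 --epochs 100 --out groups.csv
```

and a multi-wave study runs end-to-end via `healthineq run --config
study.yaml`, writing `ci_by_scope.csv`, `decomposition.csv`, `groups.csv`
and a run log.

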