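"""Synthetic survey microdata with a plantable income-related gradient.

Emulates a cross-sectional wave of a middle-aged/elderly household survey:
one row per respondent with demographics, socioeconomic status (income,
expenditure, a 0-6 household-facilities count), health-need variables,
insurance coverage and three binary healthcare-utilization outcomes
(outpatient, inpatient, preventive care).

The key design point is that each utilization outcome is drawn Bernoulli
with ``logit(p_i) = baseline + gamma * r_i + need_effects . needs_i`` where
``r_i`` is the respondent's income fractional rank.  Because the gradient
acts on the rank rather than on raw income, the implied ground-truth
concentration index depends only on ``gamma`` (and the need terms), not on
the shape of the income distribution — which makes planted inequality
recoverable by construction.

Default parameter values are stylized around the descriptive statistics of a
2011 Chinese middle-aged/elderly survey wave: right-skewed lognormal income
(mean ~7.9k, SD ~12.8k currency units/year), expenditure positively
correlated with income, facilities averaging ~2.2 of 6, and utilization
rates of roughly 0.26 (outpatient), 0.09 (inpatient) and 0.46 (prevention).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .ranking import _ci_value, fractional_rank

OUTCOMES = ("outpatient", "inpatient", "prevention")

EDUCATION_LEVELS = ("illiterate", "middle_or_lower", "high_or_above")
RESIDENCE_LEVELS = ("urban", "combination", "rural")

# Generation-time means of the need variables; need effects apply to the
# centered values so baseline_logit stays interpretable as the marginal rate.
_NEED_CENTERS = {"chronic_count": 1.6, "srh": 3.15, "adl": 0.22, "iadl": 0.25}


class ConfigurationError(ValueError):
    """Invalid synthetic-data configuration; the message names the field."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic survey wave.

    gradient
        Per-outcome coefficient on the income fractional rank in the
        utilization log-odds; positive plants pro-rich inequality.
    cluster_separation
        Standardized distance between two planted SES blobs (low/high);
        0 disables planting.  When > 0 the output carries a ``ses_block``
        column with the planted labels.
    """

    n: int = 2000
    seed: int = 0
    wave: str = "2011"
    income_log_mean: float = 8.33
    income_log_sd: float = 1.13
    expenditure_log_mean: float = 7.94
    expenditure_log_sd: float = 1.16
    expenditure_income_corr: float = 0.5
    facility_baseline: float = -0.55
    facility_slope: float = 0.8
    gradient: Mapping[str, float] = field(
        default_factory=lambda: {"outpatient": 0.1, "inpatient": 0.5, "prevention": 0.8}
    )
    baseline_logit: Mapping[str, float] = field(
        default_factory=lambda: {
            "outpatient": -1.05,
            "inpatient": -2.35,
            "prevention": -0.16,
        }
    )
    need_effects: Mapping[str, float] = field(
        default_factory=lambda: {
            "chronic_count": 0.15,
            "srh": 0.25,
            "adl": 0.3,
            "iadl": 0.2,
        }
    )
    cluster_separation: float = 0.0
    education_probs: tuple[float, float, float] = (0.28, 0.62, 0.10)
    residence_probs: tuple[float, float, float] = (0.09, 0.25, 0.66)
    employment_rate: float = 0.96
    chronic_mean: float = 1.6
    adl_rate: float = 0.22
    iadl_rate: float = 0.25

    def validate(self) -> None:
        if self.n < 1:
            raise ConfigurationError(f"n must be >= 1, got {self.n}")
        if self.income_log_sd <= 0:
            raise ConfigurationError(
                f"income_log_sd must be > 0, got {self.income_log_sd}"
            )
        if self.expenditure_log_sd <= 0:
            raise ConfigurationError(
                f"expenditure_log_sd must be > 0, got {self.expenditure_log_sd}"
            )
        if not abs(self.expenditure_income_corr) < 1:
            raise ConfigurationError(
                "expenditure_income_corr must satisfy |rho| < 1, got "
                f"{self.expenditure_income_corr}"
            )
        if self.cluster_separation < 0:
            raise ConfigurationError(
                f"cluster_separation must be >= 0, got {self.cluster_separation}"
            )
        for name, probs in (
            ("education_probs", self.education_probs),
            ("residence_probs", self.residence_probs),
        ):
            if len(probs) != 3 or abs(sum(probs) - 1.0) > 1e-8 or min(probs) < 0:
                raise ConfigurationError(f"{name} must be 3 nonnegative probs summing to 1")
        for mapping_name, mapping in (
            ("gradient", self.gradient),
            ("baseline_logit", self.baseline_logit),
        ):
            unknown = set(mapping) - set(OUTCOMES)
            if unknown:
                raise ConfigurationError(
                    f"{mapping_name} refers to unknown outcomes {sorted(unknown)}"
                )
        unknown_needs = set(self.need_effects) - set(_NEED_CENTERS)
        if unknown_needs:
            raise ConfigurationError(
                f"need_effects refers to unknown need variables {sorted(unknown_needs)}"
            )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def generate_population(config: SyntheticConfig) -> pd.DataFrame:
    """Draw one synthetic survey wave.

    Deterministic: the same config (including seed) yields a byte-identical
    table.  Column order and dtypes are fixed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n

    if config.cluster_separation > 0:
        block = rng.integers(0, 2, size=n)
        offset = (block - 0.5) * config.cluster_separation
    else:
        block = None
        offset = np.zeros(n)

    z_inc_noise = rng.standard_normal(n)
    z_inc = offset + z_inc_noise

    rho = config.expenditure_income_corr
    z_exp = offset + rho * z_inc_noise + np.sqrt(1 - rho**2) * rng.standard_normal(n)

    if block is None:
        income = np.exp(config.income_log_mean + config.income_log_sd * z_inc)
        expenditure = np.exp(
            config.expenditure_log_mean + config.expenditure_log_sd * z_exp
        )
    else:
        # Blob mode: currency variables are affine in the latent so the
        # planted standardized blob distance survives z-scoring untouched
        # (a lognormal's heavy tail would warp the standardized geometry).
        shift = 2.0 + config.cluster_separation
        income = np.maximum(np.exp(config.income_log_mean) / shift * (shift + z_inc), 1e-6)
        expenditure = np.maximum(
            np.exp(config.expenditure_log_mean) / shift * (shift + z_exp), 1e-6
        )

    p_fac = _sigmoid(config.facility_baseline + config.facility_slope * z_inc)
    facilities = rng.binomial(6, p_fac)

    gender = rng.integers(0, 2, size=n)
    age = np.clip(np.round(rng.normal(60.0, 9.5, size=n)), 45, 100).astype(int)
    education = rng.choice(EDUCATION_LEVELS, size=n, p=config.education_probs)
    residence = rng.choice(RESIDENCE_LEVELS, size=n, p=config.residence_probs)
    employment = (rng.random(n) < config.employment_rate).astype(int)

    chronic = rng.poisson(config.chronic_mean, size=n)
    srh = rng.choice([1, 2, 3, 4, 5], size=n, p=[0.04, 0.18, 0.42, 0.28, 0.08])
    adl = (rng.random(n) < config.adl_rate).astype(int)
    iadl = (rng.random(n) < config.iadl_rate).astype(int)
    insurance = rng.choice([0, 1, 2], size=n, p=[0.05, 0.90, 0.05])

    ranks = fractional_rank(income).ranks
    needs = {"chronic_count": chronic, "srh": srh, "adl": adl, "iadl": iadl}
    need_term = np.zeros(n)
    for name, coef in config.need_effects.items():
        need_term += coef * (needs[name] - _NEED_CENTERS[name])

    outcomes = {}
    for outcome in OUTCOMES:
        gamma = config.gradient.get(outcome, 0.0)
        base = config.baseline_logit.get(outcome, 0.0)
        # Center the rank term so gamma does not shift the marginal rate.
        logit = base + gamma * (ranks - ranks.mean()) + need_term
        outcomes[outcome] = (rng.random(n) < _sigmoid(logit)).astype(int)

    table = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "wave": config.wave,
            "gender": gender,
            "age": age,
            "education": education,
            "residence": residence,
            "income": income,
            "employment": employment,
            "facilities_count": facilities,
            "expenditure": expenditure,
            "chronic_count": chronic,
            "srh": srh,
            "adl": adl,
            "iadl": iadl,
            "insurance_count": insurance,
            "outpatient": outcomes["outpatient"],
            "inpatient": outcomes["inpatient"],
            "prevention": outcomes["prevention"],
        }
    )
    if block is not None:
        table["ses_block"] = block
    return table


def facilities_level(table: pd.DataFrame) -> pd.Series:
    """Facilities scored 100 points per owned facility (0-600 scale)."""
    return table["facilities_count"] * 100


def planted_ci_oracle(
    config: SyntheticConfig, outcome: str, n_large: int = 100_000
) -> float:
    """Monte-Carlo ground-truth CI of ``outcome`` under ``config``.

    Simulates ``n_large`` records from the same generative model (with a seed
    derived from the config's) and applies the covariance formula directly.
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}; expected one of {OUTCOMES}")
    if n_large < 10_000:
        raise ValueError(f"n_large must be >= 10,000 for a stable oracle, got {n_large}")
    oracle_seed = int(np.random.SeedSequence([config.seed, 0xC1]).generate_state(1)[0] % (2**31))
    big = replace(config, n=n_large, seed=oracle_seed)
    table = generate_population(big)
    h = table[outcome].to_numpy(dtype=float)
    r = fractional_rank(table["income"].to_numpy()).ranks
    return _ci_value(h, r)
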