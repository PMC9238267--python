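"""Fractional ranks and the concentration index.

The concentration index (CI) measures income-related inequality in a health
variable ``h``: ``C = (2/mu) * cov(h, r)`` where ``mu`` is the mean of ``h``
and ``r`` is the fractional rank of each individual in the living-standards
distribution (``r_i = i/N``, i = 1 for the poorest).  ``C`` lies in [-1, 1]
for nonnegative ``h``; 0 means perfect equality, positive values mean the
variable is concentrated among the rich (pro-rich), negative among the poor.

Covariances here are population covariances (divide by ``n``), the convention
under which the identity ``C = (2/mu) cov(h, r)`` is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.stats import rankdata


class UndefinedIndexError(ValueError):
    """Raised when the CI is undefined (health variable has zero mean)."""


@dataclass(frozen=True)
class RankedVariable:
    """A living-standards variable with fractional ranks in (0, 1].

    Ranks are returned in the original row order.  Tied values share the mean
    of the fractional ranks their sorted positions would receive, which makes
    every downstream index invariant to permutations of tied rows.
    """

    values: np.ndarray
    ranks: np.ndarray

    @property
    def n(self) -> int:
        return self.values.size

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "ranks", np.asarray(self.ranks, dtype=float))


def fractional_rank(values) -> RankedVariable:
    """Fractional ranks r_i = i/n of a living-standards measure.

    The poorest record gets 1/n, the richest 1.  Tied blocks share the mean
    of their positions' i/n values (midpoint rule).

    Raises
    ------
    ValueError
        If the input is empty or contains non-finite values (the offending
        row indices are named).
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        arr = arr.ravel()
    if arr.size == 0:
        raise ValueError("cannot rank an empty living-standards vector")
    bad = np.flatnonzero(~np.isfinite(arr))
    if bad.size:
        raise ValueError(
            f"non-finite living-standards values at rows {bad[:10].tolist()}"
        )
    ranks = rankdata(arr, method="average") / arr.size
    return RankedVariable(values=arr, ranks=ranks)


@dataclass
class CIResult:
    """Concentration-index estimate with its convenient-regression inference.

    Attributes
    ----------
    estimate : CI point estimate, dimensionless, in [-1, 1] for h >= 0.
    mean_h : mean of the health variable.
    se : heteroskedasticity-robust standard error from the convenient
        regression (an approximation that treats ``mu`` as known).
    p_value : two-sided p-value from the normal approximation.
    n : number of records.
    """

    estimate: float
    mean_h: float
    se: float
    p_value: float
    n: int
    outcome: str = field(default="h")

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        return (self.estimate - z * self.se, self.estimate + z * self.se)

    def summary(self) -> str:
        lo, hi = self.conf_int()
        lines = [
            "Concentration Index",
            "===================",
            f"outcome:   {self.outcome}",
            f"n:         {self.n}",
            f"mean:      {self.mean_h:.6f}",
            f"CI:        {self.estimate:.6f}",
            f"Std.Err:   {self.se:.6f}",
            f"p-value:   {self.p_value:.4f}",
            f"95% CI:    [{lo:.6f}, {hi:.6f}]",
        ]
        return "\n".join(lines)


def _ci_value(h: np.ndarray, r: np.ndarray) -> float:
    """Fast point estimate (2/mu)*cov_pop(h, r); no validation, no inference."""
    mu = h.mean()
    cov = ((h - mu) * (r - r.mean())).mean()
    return 2.0 * cov / mu


def concentration_index(h, ranked: RankedVariable, outcome: str = "h") -> CIResult:
    """Concentration index of ``h`` against the fractional ranks of ``ranked``.

    The point estimate is ``(2/mu) cov_pop(h, r)``.  The standard error comes
    from the convenient regression of ``2*var_pop(r)*h_i/mu`` on ``r_i``,
    whose OLS slope equals the CI exactly; its HC1-robust standard error and
    a normal-approximation two-sided p-value are reported.
    """
    h = np.asarray(h, dtype=float).ravel()
    r = ranked.ranks
    if h.size != r.size:
        raise ValueError(
            f"health variable has {h.size} records but ranks have {r.size}"
        )
    if not np.all(np.isfinite(h)):
        bad = np.flatnonzero(~np.isfinite(h))
        raise ValueError(f"non-finite health values at rows {bad[:10].tolist()}")
    mu = h.mean()
    if mu == 0.0:
        raise UndefinedIndexError(
            "concentration index undefined: health variable has zero mean"
        )
    estimate = _ci_value(h, r)
    if h.size < 3 or np.ptp(r) == 0.0:
        # No residual degrees of freedom (or degenerate ranks): inference
        # is meaningless; report the estimate with undefined uncertainty.
        return CIResult(estimate, mu, np.nan, np.nan, int(h.size), outcome)
    var_r = r.var()
    lhs = 2.0 * var_r * h / mu
    exog = sm.add_constant(r)
    fit = sm.OLS(lhs, exog).fit(cov_type="HC1")
    se = float(fit.bse[1])
    p = float(fit.pvalues[1])
    return CIResult(float(estimate), float(mu), se, p, int(h.size), outcome)


def generalized_concentration_index(x, ranked: RankedVariable) -> float:
    """Unnormalized index ``2*cov_pop(x, r)``.

    Unlike the CI this does not divide by the variable's mean, so zero-mean
    variables such as regression residuals are admissible.
    """
    x = np.asarray(x, dtype=float).ravel()
    r = ranked.ranks
    if x.size != r.size:
        raise ValueError(f"variable has {x.size} records but ranks have {r.size}")
    return float(2.0 * ((x - x.mean()) * (r - r.mean())).mean())


class ConcentrationIndexModel:
    """Model object computing the CI of an outcome ranked by living standards.

    Parameters
    ----------
    h : array-like
        Health / utilization variable (binary, count or probability-valued).
    rank_values : array-like
        Living-standards measure used for ranking (e.g. income).
    """

    def __init__(self, h, rank_values, outcome: str = "h"):
        self.h = np.asarray(h, dtype=float).ravel()
        self.ranked = fractional_rank(rank_values)
        self.outcome = outcome

    @classmethod
    def from_dataframe(cls, data, outcome: str, rank_by: str = "income"):
        for col in (outcome, rank_by):
            if col not in data.columns:
                raise KeyError(f"column {col!r} not found in data")
        return cls(data[outcome].to_numpy(), data[rank_by].to_numpy(), outcome)

    def fit(self) -> CIResult:
        return concentration_index(self.h, self.ranked, outcome=self.outcome)
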