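"""Decomposition of the concentration index into factor contributions.

For a linear additive model ``y = alpha + sum_k beta_k x_k + eps`` the CI of
``y`` decomposes exactly as

    C = sum_k (beta_k * xbar_k / mu) * C_k  +  GC_eps / mu

where ``mu = mean(y)``, ``C_k`` is the CI of regressor ``x_k`` (same ranks),
``eta_k = beta_k * xbar_k / mu`` is the elasticity of y with respect to x_k
at the means, and ``GC_eps`` is the generalized (unnormalized) concentration
index of the OLS residual.  Because OLS residuals are exactly orthogonal to
the regressors the adding-up holds to floating precision, which the fitted
results assert.  Percentage contributions 100*Q_k/C sum to 100% (including
the residual's share); individual percentages may be negative or exceed 100
when contributions of opposite sign cancel — they are reported unclipped.

The outcome may be binary or probability-valued; the linear probability
model is used deliberately, as exact adding-up requires a linear model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.linalg import qr

from .ranking import (
    RankedVariable,
    UndefinedIndexError,
    _ci_value,
    generalized_concentration_index,
)
from .standardization import DUMMY_SEP

#: the six contribution categories used for reporting; "medical_distance"
#: has no associated variable in the default survey table and stays empty.
DEFAULT_CATEGORIES: dict[str, str] = {
    "gender": "demographic",
    "age": "demographic",
    "education": "demographic",
    "residence": "demographic",
    "chronic_count": "health",
    "srh": "health",
    "adl": "health",
    "iadl": "health",
    "ln_income": "economic",
    "income": "economic",
    "expenditure": "economic",
    "facilities_count": "economic",
    "insurance_count": "insurance",
    "employment": "work",
}

CATEGORY_ORDER = (
    "demographic",
    "health",
    "economic",
    "insurance",
    "medical_distance",
    "work",
)


class CollinearityError(ValueError):
    """Design matrix is rank deficient; message names dependent columns."""


class CategoryMapError(KeyError):
    """A regressor has no entry in the category map."""


def fit_linear_additive_model(y, X: pd.DataFrame):
    """OLS fit of ``y = alpha + sum_k beta_k x_k``; returns (alpha, betas).

    Raises :class:`CollinearityError` naming the dependent columns when the
    intercept-augmented design is rank deficient.
    """
    y = np.asarray(y, dtype=float).ravel()
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
        X.columns = [f"x{j}" for j in range(X.shape[1])]
    design = sm.add_constant(X, has_constant="add")
    mat = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        _, _, piv = qr(mat, mode="economic", pivoting=True)
        dependent = sorted(design.columns[j] for j in piv[rank:])
        raise CollinearityError(
            f"design matrix is rank deficient; dependent columns: {dependent}"
        )
    fit = sm.OLS(y, design).fit()
    alpha = float(fit.params.iloc[0])
    betas = fit.params.iloc[1:]
    betas.index = X.columns
    return alpha, betas


@dataclass
class DecompositionResult:
    """Wagstaff decomposition of a concentration index.

    ``table`` holds one row per regressor with columns beta, mean,
    elasticity, ck, contribution, percent; ``residual`` is GC_eps/mu.
    """

    total_ci: float
    mean_y: float
    n: int
    table: pd.DataFrame
    residual: float
    residual_percent: float
    categories: Mapping[str, str] = field(default_factory=dict)

    @property
    def explained(self) -> float:
        return float(self.table["contribution"].sum())

    def category_summary(self) -> pd.DataFrame:
        """Contributions summed within the six reporting categories."""
        rows = []
        for cat in CATEGORY_ORDER:
            mask = self.table["category"] == cat
            contrib = float(self.table.loc[mask, "contribution"].sum())
            pct = (
                100.0 * contrib / self.total_ci
                if abs(self.total_ci) > 1e-6
                else np.nan
            )
            rows.append({"category": cat, "contribution": contrib, "percent": pct})
        extra = sorted(set(self.table["category"]) - set(CATEGORY_ORDER))
        for cat in extra:
            mask = self.table["category"] == cat
            contrib = float(self.table.loc[mask, "contribution"].sum())
            pct = (
                100.0 * contrib / self.total_ci
                if abs(self.total_ci) > 1e-6
                else np.nan
            )
            rows.append({"category": cat, "contribution": contrib, "percent": pct})
        return pd.DataFrame(rows).set_index("category")

    def summary(self) -> str:
        lines = [
            "Concentration Index Decomposition",
            "=================================",
            f"n: {self.n}    mean(y): {self.mean_y:.6f}    total CI: {self.total_ci:.6f}",
            "",
            self.table.round(6).to_string(),
            "",
            f"residual (GC_eps/mu): {self.residual:.6f}"
            + (
                f"  ({self.residual_percent:.2f}%)"
                if np.isfinite(self.residual_percent)
                else ""
            ),
        ]
        return "\n".join(lines)


def _category_for(name: str, categories: Mapping[str, str]) -> str:
    if name in categories:
        return categories[name]
    base = name.split(DUMMY_SEP)[0]
    if base in categories:
        return categories[base]
    raise CategoryMapError(
        f"regressor {name!r} has no entry in the category map"
    )


def decompose_ci(
    y,
    X: pd.DataFrame,
    ranked: RankedVariable,
    categories: Mapping[str, str] | None = None,
) -> DecompositionResult:
    """Decompose the CI of ``y`` into elasticity-weighted regressor shares.

    ``C_k`` for each regressor uses the same fractional ranks (and tie rule)
    as the outcome CI; indicator regressors are treated like any other 0/1
    variable.  When ``|C| < 1e-6`` percentage contributions are reported as
    NaN with a warning instead of dividing by approximately zero.
    """
    y = np.asarray(y, dtype=float).ravel()
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
        X.columns = [f"x{j}" for j in range(X.shape[1])]
    if categories is None:
        categories = DEFAULT_CATEGORIES
    r = ranked.ranks
    if y.size != r.size or len(X) != r.size:
        raise ValueError("y, X and ranks must have the same number of records")
    mu = y.mean()
    if mu == 0.0:
        raise UndefinedIndexError("decomposition undefined: mean(y) is zero")

    cats = {name: _category_for(name, categories) for name in X.columns}

    alpha, betas = fit_linear_additive_model(y, X)
    fitted = alpha + X.to_numpy(dtype=float) @ betas.to_numpy()
    eps = y - fitted

    total_ci = _ci_value(y, r)
    tiny = abs(total_ci) < 1e-6
    if tiny:
        warnings.warn(
            "total CI is below 1e-6; percentage contributions are undefined "
            "and reported as NaN",
            RuntimeWarning,
            stacklevel=2,
        )

    rows = []
    rc = r - r.mean()
    for name in X.columns:
        x = X[name].to_numpy(dtype=float)
        beta = float(betas[name])
        xbar = float(x.mean())
        cov_xr = float(((x - xbar) * rc).mean())
        # eta_k * C_k reduces to 2*beta*cov(x,r)/mu, well-defined even when
        # xbar (and hence C_k itself) degenerates.
        contribution = 2.0 * beta * cov_xr / mu
        ck = 2.0 * cov_xr / xbar if xbar != 0.0 else np.nan
        elasticity = beta * xbar / mu
        percent = np.nan if tiny else 100.0 * contribution / total_ci
        rows.append(
            {
                "regressor": name,
                "category": cats[name],
                "beta": beta,
                "mean": xbar,
                "elasticity": elasticity,
                "ck": ck,
                "contribution": contribution,
                "percent": percent,
            }
        )
    table = pd.DataFrame(rows).set_index("regressor")

    residual = generalized_concentration_index(eps, ranked) / mu
    residual_percent = np.nan if tiny else 100.0 * residual / total_ci

    return DecompositionResult(
        total_ci=float(total_ci),
        mean_y=float(mu),
        n=int(y.size),
        table=table,
        residual=float(residual),
        residual_percent=float(residual_percent),
        categories=dict(cats),
    )


def category_summary(result: DecompositionResult) -> pd.DataFrame:
    """Functional form of :meth:`DecompositionResult.category_summary`."""
    return result.category_summary()


class WagstaffDecomposition:
    """Model object for the CI decomposition of an outcome on regressors.

    Parameters mirror :func:`decompose_ci`; ``fit`` returns the
    :class:`DecompositionResult`.
    """

    def __init__(self, y, X: pd.DataFrame, ranked: RankedVariable, categories=None):
        self.y = y
        self.X = X
        self.ranked = ranked
        self.categories = categories

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        outcome: str,
        regressors: list[str],
        rank_by: str = "income",
        categories=None,
    ):
        from .ranking import fractional_rank

        missing = [c for c in [outcome, rank_by, *regressors] if c not in data.columns]
        if missing:
            raise KeyError(f"columns not found in data: {missing}")
        ranked = fractional_rank(data[rank_by].to_numpy())
        return cls(data[outcome].to_numpy(), data[regressors], ranked, categories)

    def fit(self) -> DecompositionResult:
        return decompose_ci(self.y, self.X, self.ranked, self.categories)
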