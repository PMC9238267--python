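"""Indirect standardization of utilization via logistic regression.

Each binary utilization outcome is modelled as

    logit(p_i) = alpha + beta * ln(income_i) + sum_k gamma_k x_ki
                 + sum_p delta_p z_pi

where the x_k are healthcare-need variables (age, gender, morbidity and
functional-status measures by default) and the z_p are other controls
(education, residence, employment, insurance).  The fitted probabilities are
the indirectly standardized utilization: they replace the raw 0/1 outcome in
downstream inequality analysis so that comparisons are net of composition
differences in need.

By the logistic score equations the mean predicted probability on the
fitting sample equals the observed outcome rate, so standardization never
shifts the overall utilization level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

DEFAULT_NEED_VARS = ("age", "gender", "chronic_count", "srh", "adl", "iadl")
DEFAULT_CONTROL_VARS = ("education", "residence", "employment", "insurance_count")

#: separator between a categorical variable and its level in dummy names
DUMMY_SEP = "::"


class DegenerateOutcomeError(ValueError):
    """Outcome is all-0 or all-1; the logistic model cannot be fitted."""


class FittingError(RuntimeError):
    """Logistic ML failed to converge (e.g. separation)."""


def _build_design(
    records: pd.DataFrame,
    variables: tuple[str, ...],
    income_floor: float,
    categories: dict[str, list] | None = None,
) -> tuple[pd.DataFrame, dict[str, list]]:
    """Expand variables into a numeric design matrix (no intercept).

    Categorical columns become indicator sets with the first level as
    reference, named ``var::level``.  ``ln_income`` is derived from income
    with the configured floor.  Returns the matrix and the category levels
    used (so prediction on new data uses the same coding).
    """
    cols: dict[str, np.ndarray] = {}
    seen_categories: dict[str, list] = {}
    for var in variables:
        if var == "ln_income":
            if "income" not in records.columns:
                raise KeyError("column 'income' not found in records")
            cols["ln_income"] = np.log(
                np.maximum(records["income"].to_numpy(dtype=float), income_floor)
            )
            continue
        if var not in records.columns:
            raise KeyError(f"column {var!r} not found in records")
        series = records[var]
        if series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype):
            if categories is not None and var in categories:
                levels = categories[var]
            else:
                levels = sorted(series.dropna().unique().tolist())
            seen_categories[var] = levels
            for level in levels[1:]:
                cols[f"{var}{DUMMY_SEP}{level}"] = (
                    (series == level).to_numpy().astype(float)
                )
        else:
            cols[var] = series.to_numpy(dtype=float)
    return pd.DataFrame(cols, index=records.index), seen_categories


class StandardizationModel:
    """Logistic model of one utilization outcome on need and control variables.

    Parameters
    ----------
    records : DataFrame
        Survey table; must contain ``outcome``, ``income`` and all need and
        control variables.
    outcome : str
        Binary 0/1 utilization column.
    need_vars, control_vars : sequences of column names
        Healthcare-need variables x_k and other controls z_p.  Categorical
        columns are expanded to indicators with the first level as reference.
    income_floor : float
        Income enters as ``ln(max(income, income_floor))`` so zero incomes
        survive the log transform.
    """

    def __init__(
        self,
        records: pd.DataFrame,
        outcome: str,
        need_vars=DEFAULT_NEED_VARS,
        control_vars=DEFAULT_CONTROL_VARS,
        income_floor: float = 1.0,
    ):
        if outcome not in records.columns:
            raise KeyError(f"column {outcome!r} not found in records")
        self.outcome = outcome
        self.need_vars = tuple(need_vars)
        self.control_vars = tuple(control_vars)
        self.income_floor = float(income_floor)
        self.records = records

        y = records[outcome].to_numpy(dtype=float)
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValueError(f"outcome {outcome!r} must be binary 0/1")
        if y.min() == y.max():
            raise DegenerateOutcomeError(
                f"outcome {outcome!r} is constant ({int(y[0])}); cannot fit"
            )
        self.endog = y
        design, cats = _build_design(
            records,
            ("ln_income",) + self.need_vars + self.control_vars,
            self.income_floor,
        )
        self.categories = cats
        self.exog = sm.add_constant(design, has_constant="add")

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, outcome: str, **kwargs):
        return cls(data, outcome, **kwargs)

    def fit(self, maxiter: int = 200) -> "StandardizationResults":
        model = sm.Logit(self.endog, self.exog)
        try:
            res = model.fit(disp=0, maxiter=maxiter)
            if not res.mle_retvals.get("converged", False):
                # Newton can stall on flat likelihoods; give BFGS one try
                # before declaring failure (quasi-separation still fails).
                res = model.fit(disp=0, maxiter=5 * maxiter, method="bfgs")
        except Exception as exc:  # statsmodels raises on perfect separation
            raise FittingError(
                f"logistic fit failed for outcome {self.outcome!r}: {exc}"
            ) from exc
        if not res.mle_retvals.get("converged", False):
            raise FittingError(
                f"logistic fit did not converge for outcome {self.outcome!r} "
                "(possible separation in a sparse covariate cell)"
            )
        return StandardizationResults(self, res)


@dataclass
class StandardizationResults:
    """Fitted standardization model: coefficients plus prediction machinery."""

    model: StandardizationModel
    _fit: object

    @property
    def params(self) -> pd.Series:
        return self._fit.params

    @property
    def bse(self) -> pd.Series:
        return self._fit.bse

    @property
    def converged(self) -> bool:
        return bool(self._fit.mle_retvals.get("converged", False))

    @property
    def n_used(self) -> int:
        return int(self.model.endog.size)

    @property
    def exog_names(self) -> list[str]:
        return list(self.model.exog.columns)

    def design_matrix(self, records: pd.DataFrame) -> pd.DataFrame:
        """Design matrix (with intercept) for new records, same coding as fit."""
        design, _ = _build_design(
            records,
            ("ln_income",) + self.model.need_vars + self.model.control_vars,
            self.model.income_floor,
            categories=self.model.categories,
        )
        return sm.add_constant(design, has_constant="add")

    def predict(self, records: pd.DataFrame | None = None) -> np.ndarray:
        """Standardized utilization: inverse-logit of the linear predictor.

        Values lie strictly in (0, 1).  On the fitting sample the mean
        prediction equals the observed outcome rate.
        """
        if records is None:
            exog = self.model.exog
        else:
            exog = self.design_matrix(records)
        eta = exog.to_numpy(dtype=float) @ self.params.to_numpy()
        return 1.0 / (1.0 + np.exp(-eta))

    def summary(self):
        return self._fit.summary()


def fit_standardization_model(
    records: pd.DataFrame,
    outcome: str,
    need_vars=DEFAULT_NEED_VARS,
    control_vars=DEFAULT_CONTROL_VARS,
    income_floor: float = 1.0,
) -> StandardizationResults:
    """Fit the logistic standardization model; functional convenience form."""
    return StandardizationModel(
        records, outcome, need_vars, control_vars, income_floor
    ).fit()


def predict_standardized_utilization(
    results: StandardizationResults, records: pd.DataFrame
) -> np.ndarray:
    """Per-record standardized utilization probabilities for ``records``."""
    return results.predict(records)
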