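"""Study orchestration: per wave and per outcome, standardize, measure the
concentration index, decompose it, identify homogeneous SES groups with the
2x2 SOM, and measure within-group concentration indices.

The study design treats each wave cross-sectionally.  Within each wave and
outcome the stages run in a fixed order:

  standardize -> rank -> CI -> decompose -> cluster -> group CIs

All randomness is driven by the configured SOM seed, so identical inputs
and config give byte-identical output tables.  Within-group CIs re-rank
records inside each group by default, treating the homogeneous group as its
own analysis population; full-sample ranks can be kept instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .decomposition import DEFAULT_CATEGORIES, WagstaffDecomposition, decompose_ci
from .ranking import concentration_index, fractional_rank
from .som import (
    DegenerateSOMError,
    SESSelfOrganizingMap,
    build_ses_features,
)
from .standardization import (
    DEFAULT_CONTROL_VARS,
    DEFAULT_NEED_VARS,
    StandardizationModel,
)

DEFAULT_OUTCOMES = ("outpatient", "inpatient", "prevention")


class StudyConfigError(ValueError):
    """Invalid study configuration."""


class StudyError(RuntimeError):
    """One or more waves failed; completed waves were still written."""

    def __init__(self, failures: dict):
        self.failures = failures
        msgs = "; ".join(f"{k}: {v}" for k, v in failures.items())
        super().__init__(f"study failed for {len(failures)} wave(s): {msgs}")


@dataclass
class StudyConfig:
    """Configuration of a full multi-wave inequality study.

    waves
        Mapping from wave label to an input table (DataFrame or CSV path).
    use_standardized
        If True (default) the CI and decomposition use the logistic model's
        predicted utilization; if False, the raw 0/1 outcomes.
    within_group_rank
        Re-rank living standards within each SES group (default) instead of
        keeping full-sample ranks.
    """

    waves: Mapping[str, object]
    outcomes: Sequence[str] = DEFAULT_OUTCOMES
    rank_by: str = "income"
    need_vars: Sequence[str] = DEFAULT_NEED_VARS
    control_vars: Sequence[str] = DEFAULT_CONTROL_VARS
    categories: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_CATEGORIES))
    som_seed: int = 0
    som_epochs: int = 100
    use_standardized: bool = True
    within_group_rank: bool = True
    within_group_decomposition: bool = False
    income_floor: float = 1.0
    output_dir: str | Path | None = None

    def validate(self) -> None:
        if not self.waves:
            raise StudyConfigError("at least one wave is required")
        if not self.outcomes:
            raise StudyConfigError("at least one outcome is required")


@dataclass
class WaveResult:
    """All per-wave outputs: CI rows, decompositions, grouping, log lines."""

    wave: str
    ci_rows: pd.DataFrame
    decompositions: dict[str, object]
    som: object
    group_info: dict
    log: list[str]


@dataclass
class StudyResult:
    """Concatenated per-wave results plus the tables written to disk."""

    ci_by_scope: pd.DataFrame
    decomposition: pd.DataFrame
    groups: pd.DataFrame
    waves: dict[str, WaveResult]
    log: list[str]


def _load_wave(source) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        return source.copy()
    return pd.read_csv(source)


class InequalityStudy:
    """Driver running the full design over configured waves and outcomes."""

    def __init__(self, config: StudyConfig):
        config.validate()
        self.config = config

    # -- single wave ------------------------------------------------------

    def run_wave(self, wave: str, records: pd.DataFrame) -> WaveResult:
        cfg = self.config
        log: list[str] = []

        used_cols = {
            "income",
            cfg.rank_by,
            *cfg.outcomes,
            *cfg.need_vars,
            *cfg.control_vars,
            "expenditure",
            "facilities_count",
        }
        missing = sorted(c for c in used_cols if c not in records.columns)
        if missing:
            raise StudyConfigError(
                f"wave {wave!r}: missing required column(s) {missing}"
            )
        n_raw = len(records)
        records = records.dropna(subset=sorted(used_cols)).reset_index(drop=True)
        dropped = n_raw - len(records)
        if dropped:
            log.append(f"wave {wave}: dropped {dropped} record(s) with missing values")

        ranked_full = fractional_rank(records[cfg.rank_by].to_numpy())

        ci_rows = []
        decomps: dict[str, object] = {}
        h_by_outcome: dict[str, np.ndarray] = {}
        for outcome in cfg.outcomes:
            try:
                if cfg.use_standardized:
                    std = StandardizationModel(
                        records,
                        outcome,
                        need_vars=cfg.need_vars,
                        control_vars=cfg.control_vars,
                        income_floor=cfg.income_floor,
                    ).fit()
                    h = std.predict()
                    regressors = std.model.exog.drop(columns=["const"])
                else:
                    std = None
                    h = records[outcome].to_numpy(dtype=float)
                    from .standardization import _build_design

                    regressors, _ = _build_design(
                        records,
                        ("ln_income",) + tuple(cfg.need_vars) + tuple(cfg.control_vars),
                        cfg.income_floor,
                    )
                h_by_outcome[outcome] = h

                res = concentration_index(h, ranked_full, outcome=outcome)
                ci_rows.append(
                    {
                        "wave": wave,
                        "outcome": outcome,
                        "scope": "full",
                        "n": res.n,
                        "mean": res.mean_h,
                        "ci": res.estimate,
                        "se": res.se,
                        "p": res.p_value,
                    }
                )
                decomps[outcome] = decompose_ci(
                    h, regressors, ranked_full, categories=cfg.categories
                )
            except Exception as exc:
                raise type(exc)(
                    f"wave {wave!r}, outcome {outcome!r}: {exc}"
                ) from exc

        features = build_ses_features(records)
        som = SESSelfOrganizingMap(
            features,
            epochs=cfg.som_epochs,
            seed=cfg.som_seed,
            record_ids=records["id"].to_numpy() if "id" in records.columns else None,
        ).fit()

        group_info = {
            "wave": wave,
            "n_total": len(records),
            "degenerate": som.degenerate,
            "extreme_pair": som.extreme_pair,
            "low_neuron": som.low_neuron,
            "high_neuron": som.high_neuron,
            "n_low": 0,
            "n_high": 0,
        }
        if som.degenerate:
            log.append(f"wave {wave}: SOM degenerate; group CIs skipped")
            for outcome in cfg.outcomes:
                for scope in ("low-SES", "high-SES"):
                    ci_rows.append(
                        {
                            "wave": wave,
                            "outcome": outcome,
                            "scope": scope,
                            "n": 0,
                            "mean": np.nan,
                            "ci": np.nan,
                            "se": np.nan,
                            "p": np.nan,
                        }
                    )
        else:
            labels = som.group_labels()
            masks = {"low-SES": labels == "low", "high-SES": labels == "high"}
            group_info["n_low"] = int(masks["low-SES"].sum())
            group_info["n_high"] = int(masks["high-SES"].sum())
            for outcome in cfg.outcomes:
                h = h_by_outcome[outcome]
                for scope, mask in masks.items():
                    sub_h = h[mask]
                    if cfg.within_group_rank:
                        sub_ranked = fractional_rank(
                            records.loc[mask, cfg.rank_by].to_numpy()
                        )
                    else:
                        from .ranking import RankedVariable

                        sub_ranked = RankedVariable(
                            values=ranked_full.values[mask],
                            ranks=ranked_full.ranks[mask],
                        )
                    if sub_h.size == 0 or sub_h.mean() == 0.0:
                        ci_rows.append(
                            {
                                "wave": wave,
                                "outcome": outcome,
                                "scope": scope,
                                "n": int(sub_h.size),
                                "mean": float(sub_h.mean()) if sub_h.size else np.nan,
                                "ci": np.nan,
                                "se": np.nan,
                                "p": np.nan,
                            }
                        )
                        log.append(
                            f"wave {wave}: {outcome} CI undefined in {scope} group"
                        )
                        continue
                    res = concentration_index(sub_h, sub_ranked, outcome=outcome)
                    ci_rows.append(
                        {
                            "wave": wave,
                            "outcome": outcome,
                            "scope": scope,
                            "n": res.n,
                            "mean": res.mean_h,
                            "ci": res.estimate,
                            "se": res.se,
                            "p": res.p_value,
                        }
                    )
                    if cfg.within_group_decomposition:
                        sub_records = records.loc[mask].reset_index(drop=True)
                        decomps[f"{outcome}@{scope}"] = WagstaffDecomposition.from_dataframe(
                            sub_records,
                            outcome,
                            [
                                c
                                for c in sub_records.columns
                                if c
                                in {"chronic_count", "srh", "adl", "iadl", "age", "gender"}
                            ],
                            rank_by=cfg.rank_by,
                            categories=cfg.categories,
                        ).fit()

        return WaveResult(
            wave=wave,
            ci_rows=pd.DataFrame(ci_rows),
            decompositions=decomps,
            som=som,
            group_info=group_info,
            log=log,
        )

    # -- full study -------------------------------------------------------

    def run(self) -> StudyResult:
        cfg = self.config
        wave_results: dict[str, WaveResult] = {}
        failures: dict[str, str] = {}
        log: list[str] = [
            f"outcomes={list(cfg.outcomes)} rank_by={cfg.rank_by} "
            f"use_standardized={cfg.use_standardized} "
            f"within_group_rank={cfg.within_group_rank} "
            f"som_seed={cfg.som_seed} som_epochs={cfg.som_epochs}"
        ]
        for wave, source in cfg.waves.items():
            try:
                records = _load_wave(source)
                wave_results[wave] = self.run_wave(wave, records)
                log.extend(wave_results[wave].log)
            except Exception as exc:
                failures[wave] = str(exc)
                log.append(f"wave {wave}: FAILED ({exc})")

        ci_by_scope = (
            pd.concat([w.ci_rows for w in wave_results.values()], ignore_index=True)
            if wave_results
            else pd.DataFrame(
                columns=["wave", "outcome", "scope", "n", "mean", "ci", "se", "p"]
            )
        )
        decomp_rows = []
        for wave, wres in wave_results.items():
            for outcome, dec in wres.decompositions.items():
                tab = dec.table.reset_index()
                tab.insert(0, "wave", wave)
                tab.insert(1, "outcome", outcome)
                decomp_rows.append(tab)
                decomp_rows.append(
                    pd.DataFrame(
                        [
                            {
                                "wave": wave,
                                "outcome": outcome,
                                "regressor": "residual",
                                "category": "",
                                "contribution": dec.residual,
                                "percent": dec.residual_percent,
                            },
                            {
                                "wave": wave,
                                "outcome": outcome,
                                "regressor": "total",
                                "category": "",
                                "contribution": dec.total_ci,
                                "percent": 100.0 if abs(dec.total_ci) > 1e-6 else np.nan,
                            },
                        ]
                    )
                )
        decomposition = (
            pd.concat(decomp_rows, ignore_index=True)
            if decomp_rows
            else pd.DataFrame()
        )
        groups = pd.DataFrame([w.group_info for w in wave_results.values()])

        if cfg.output_dir is not None:
            outdir = Path(cfg.output_dir)
            outdir.mkdir(parents=True, exist_ok=True)
            ci_by_scope.to_csv(outdir / "ci_by_scope.csv", index=False)
            decomposition.to_csv(outdir / "decomposition.csv", index=False)
            groups.to_csv(outdir / "groups.csv", index=False)
            (outdir / "run_log.txt").write_text("\n".join(log) + "\n")

        result = StudyResult(
            ci_by_scope=ci_by_scope,
            decomposition=decomposition,
            groups=groups,
            waves=wave_results,
            log=log,
        )
        if failures:
            raise StudyError(failures)
        return result


def run_study(config: StudyConfig) -> StudyResult:
    """Run the whole study; functional convenience form."""
    return InequalityStudy(config).run()
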