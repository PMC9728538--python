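"""Attribution of central-SBP calibration error to clinical predictors.

Models the signed difference (estimated central SBP − invasive aortic
SBP) — Type I (C1) or Type II (C2) — as a linear function of
pre-specified clinical and pulse-wave predictors, reporting for each
predictor its effect on the mean difference (beta, mmHg per unit), its
two-sided p-value, and its partial R².

Partial R² uses the classical sum-of-squares ratio

    partial_R²_j = (SSE(without j) − SSE(full)) / SSE(without j)

i.e. the share of residual variance attributable to predictor j given
all others; it is computed from the full fit's t statistic via the
identity ``t² / (t² + df_resid)``, which equals the refit-based ratio
exactly for a single dropped column.  Multicollinearity is screened
with variance inflation factors, ``VIF_j = 1 / (1 − R²_j)`` from
regressing predictor j on the remaining predictors (with intercept);
an exactly collinear predictor reports ``inf`` rather than raising.

Binary covariates enter as 0/1 and sex as the female=1 indicator.
p-values are reported raw, without multiplicity adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .synthetic_cohort import CohortTable, female_indicator

__all__ = [
    "DEFAULT_DIFFERENCE_PREDICTORS",
    "PredictorEffect",
    "DifferenceModelFit",
    "design_matrix",
    "fit_difference_model",
    "vif",
]

#: Default pre-specified predictor set: demographics, anthropometrics,
#: comorbidities, medications and pulse-wave indices.
DEFAULT_DIFFERENCE_PREDICTORS = [
    "age",
    "sex",
    "heart_rate",
    "amplification",
    "epwv",
    "aix75",
    "reflection_magnitude",
    "height",
    "weight",
    "egfr",
    "active_smoking",
    "diabetes",
    "antihypertensive_any",
    "statin",
    "aspirin",
]


@dataclass(frozen=True)
class PredictorEffect:
    name: str
    beta: float  # mmHg per unit (per-category for binaries)
    se: float  # standard error of beta
    p_value: float
    partial_r2: float  # %
    vif: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.partial_r2 <= 100.0 + 1e-9):
            raise ValueError(f"partial_r2 out of [0, 100]: {self.partial_r2}")
        if self.vif < 1.0 - 1e-9:
            raise ValueError(f"vif must be >= 1, got {self.vif}")


@dataclass(frozen=True)
class DifferenceModelFit:
    target: str  # "c1" | "c2"
    effects: tuple[PredictorEffect, ...]
    intercept: float
    global_r2: float  # %
    n: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.global_r2 <= 100.0 + 1e-9):
            raise ValueError(f"global_r2 out of [0, 100]: {self.global_r2}")

    def effect(self, name: str) -> PredictorEffect:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        """One row per predictor plus a footer row (intercept, global R², n)."""
        rows = [
            {
                "predictor": e.name,
                "beta": e.beta,
                "se": e.se,
                "p_value": e.p_value,
                "partial_r2_pct": e.partial_r2,
                "vif": e.vif,
            }
            for e in self.effects
        ]
        rows.append(
            {
                "predictor": "(model)",
                "beta": self.intercept,
                "p_value": np.nan,
                "partial_r2_pct": self.global_r2,
                "vif": np.nan,
            }
        )
        return pd.DataFrame(rows)


def design_matrix(cohort: CohortTable, predictors: list[str]) -> pd.DataFrame:
    """Numeric design matrix (no intercept column) for the named predictors.

    ``sex`` becomes the female=1/male=0 indicator; binary flags are cast
    to float.  Unknown names raise KeyError.
    """
    df = cohort.df
    cols = {}
    for name in predictors:
        if name == "sex":
            cols["sex"] = female_indicator(df)
        elif name in df.columns:
            cols[name] = df[name].astype(float)
        else:
            raise KeyError(f"predictor '{name}' not present in cohort")
    return pd.DataFrame(cols, index=df.index)


def _check_rank(X: pd.DataFrame) -> None:
    Xc = sm.add_constant(X.to_numpy(), has_constant="add")
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        # name the columns involved in a dependency, for the error message
        corr = X.corr().abs()
        np.fill_diagonal(corr.to_numpy(), 0.0)
        pairs = [
            f"{a}~{b}"
            for a in corr.index
            for b in corr.columns
            if a < b and corr.loc[a, b] > 1 - 1e-10
        ]
        raise ValueError(
            "design matrix is rank deficient"
            + (f" (exactly dependent: {pairs})" if pairs else "")
        )


def vif(cohort: CohortTable, predictors: list[str]) -> dict[str, float]:
    """Variance inflation factor per predictor: ``1 / (1 − R²_j)``.

    ``R²_j`` comes from regressing predictor j on the other predictors
    (with intercept).  Exact collinearity yields ``inf``, not an error.
    """
    if len(predictors) < 2:
        raise ValueError("VIF needs at least 2 predictors")
    X = design_matrix(cohort, predictors)
    if len(X) <= len(predictors):
        raise ValueError(f"n={len(X)} too small for {len(predictors)} predictors")
    out: dict[str, float] = {}
    for name in predictors:
        y = X[name].to_numpy()
        others = sm.add_constant(X.drop(columns=[name]).to_numpy())
        r2 = sm.OLS(y, others).fit().rsquared
        out[name] = float("inf") if r2 >= 1.0 - 1e-12 else float(1.0 / (1.0 - r2))
    return out


def fit_difference_model(
    cohort: CohortTable,
    target: str,
    predictors: list[str] | None = None,
) -> DifferenceModelFit:
    """Least-squares model of (C1SBP or C2SBP − AoSBP) on clinical predictors.

    Parameters
    ----------
    cohort
        Validated patient table.
    target
        ``"c1"`` or ``"c2"`` — which calibration's difference to model.
    predictors
        Column names (default :data:`DEFAULT_DIFFERENCE_PREDICTORS`).

    Returns per-predictor beta / p-value / partial R² / VIF plus the
    intercept and global R² (both R² on the percent scale).
    """
    if target not in ("c1", "c2"):
        raise ValueError(f"target must be 'c1' or 'c2', got {target!r}")
    predictors = list(predictors) if predictors is not None else list(
        DEFAULT_DIFFERENCE_PREDICTORS
    )
    X = design_matrix(cohort, predictors)
    n = len(X)
    if n <= len(predictors) + 1:
        raise ValueError(
            f"n={n} too small to fit {len(predictors)} predictors with intercept"
        )
    _check_rank(X)
    y = (cohort.df[f"{target}sbp"] - cohort.df["aosbp_invasive"]).to_numpy()
    fit = sm.OLS(y, sm.add_constant(X.to_numpy())).fit()
    vifs = vif(cohort, predictors) if len(predictors) >= 2 else {predictors[0]: 1.0}
    df_resid = fit.df_resid
    effects = []
    for j, name in enumerate(predictors, start=1):
        t2 = float(fit.tvalues[j]) ** 2
        partial = 100.0 * t2 / (t2 + df_resid)
        effects.append(
            PredictorEffect(
                name=name,
                beta=float(fit.params[j]),
                se=float(fit.bse[j]),
                p_value=float(fit.pvalues[j]),
                partial_r2=partial,
                vif=vifs[name],
            )
        )
    return DifferenceModelFit(
        target=target,
        effects=tuple(effects),
        intercept=float(fit.params[0]),
        global_r2=float(100.0 * fit.rsquared),
        n=n,
    )
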