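"""Adjusted prediction models for invasive aortic SBP.

The model ladder adds clinical and pulse-wave information to the two
calibrated central-SBP estimates:

========== ==============================================================
name       predictors
========== ==============================================================
c1_only    C1SBP
c2_only    C2SBP
c1_c2      C1SBP + C2SBP
demographics  c1_c2 + age + sex
pwa        demographics + heart rate, SBP amplification, ePWV, AIx@75,
           reflection magnitude
full       pwa + height, weight, eGFR, smoking, diabetes,
           antihypertensives, statin, aspirin
lasso      data-driven subset of the full set (default: age, sex, C1SBP,
           C2SBP, amplification, AIx@75, height)
full_bmi   full with height and weight replaced by BMI (sensitivity)
========== ==============================================================

All models are ordinary least squares with an intercept, so their
in-sample mean residual (accuracy) is zero by construction; the
interesting outputs are precision (residual SD), R² and the ±10 mmHg
capture rate.

Internal validation resamples patients with replacement, refits the
model on each resample and evaluates it on the *original* cohort,
averaging the four agreement metrics over replications (the apparent
performance of a raw, unmodelled measure is therefore unchanged by this
procedure).  A Harrell-style optimism-corrected variant is available via
``scheme="optimism"``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold
from sklearn.preprocessing import StandardScaler

from .agreement import AgreementSummary, agreement
from .attribution import design_matrix
from .synthetic_cohort import CohortTable

logger = logging.getLogger(__name__)

__all__ = [
    "AdjustedModelSpec",
    "FittedModel",
    "BootstrapResult",
    "ADJUSTED_SPECS",
    "RAW_MEASURES",
    "model_spec",
    "fit_adjusted_model",
    "lasso_select",
    "bootstrap_validate",
    "run_table3",
]


@dataclass(frozen=True)
class AdjustedModelSpec:
    name: str
    predictors: tuple[str, ...]


_DEMOGRAPHICS = ("age", "sex", "c1sbp", "c2sbp")
_PWA = _DEMOGRAPHICS + (
    "heart_rate",
    "amplification",
    "epwv",
    "aix75",
    "reflection_magnitude",
)
_FULL = _PWA + (
    "height",
    "weight",
    "egfr",
    "active_smoking",
    "diabetes",
    "antihypertensive_any",
    "statin",
    "aspirin",
)

#: The named model ladder.
ADJUSTED_SPECS: dict[str, AdjustedModelSpec] = {
    "c1_only": AdjustedModelSpec("c1_only", ("c1sbp",)),
    "c2_only": AdjustedModelSpec("c2_only", ("c2sbp",)),
    "c1_c2": AdjustedModelSpec("c1_c2", ("c1sbp", "c2sbp")),
    "demographics": AdjustedModelSpec("demographics", _DEMOGRAPHICS),
    "pwa": AdjustedModelSpec("pwa", _PWA),
    "full": AdjustedModelSpec("full", _FULL),
    "lasso": AdjustedModelSpec(
        "lasso", ("age", "sex", "c1sbp", "c2sbp", "amplification", "aix75", "height")
    ),
    "full_bmi": AdjustedModelSpec(
        "full_bmi",
        tuple(p for p in _FULL if p not in ("height", "weight")) + ("bmi",),
    ),
}

#: Raw (unadjusted) measures reported alongside the models.
RAW_MEASURES = {"brachial": "brachial_sbp", "c1": "c1sbp", "c2": "c2sbp"}


def model_spec(name: str) -> AdjustedModelSpec:
    try:
        return ADJUSTED_SPECS[name]
    except KeyError:
        raise KeyError(
            f"unknown model '{name}'; choose from {sorted(ADJUSTED_SPECS)}"
        ) from None


@dataclass(frozen=True)
class FittedModel:
    spec: AdjustedModelSpec
    intercept: float
    coefficients: dict[str, float]
    training: AgreementSummary
    fitted_values: np.ndarray = field(repr=False)

    def predict(self, cohort: CohortTable) -> np.ndarray:
        X = design_matrix(cohort, list(self.spec.predictors)).to_numpy()
        beta = np.array([self.coefficients[p] for p in self.spec.predictors])
        return self.intercept + X @ beta


@dataclass(frozen=True)
class BootstrapResult:
    spec_name: str
    B: int
    seed: int
    accuracy: float
    precision: float
    r_squared: float
    pct_within_10: float
    skipped: int = 0


def _ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least squares with intercept; returns [intercept, betas...]."""
    Xc = np.column_stack([np.ones(len(X)), X])
    beta, _, rank, _ = np.linalg.lstsq(Xc, y, rcond=None)
    if rank < Xc.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design")
    return beta


def fit_adjusted_model(
    cohort: CohortTable, spec: AdjustedModelSpec | str
) -> FittedModel:
    """Fit a model of AoSBP by least squares and summarise its training fit.

    The returned :class:`AgreementSummary` compares in-sample predictions
    with invasive AoSBP; its accuracy is 0 to numerical tolerance because
    OLS residuals with an intercept sum to zero.
    """
    if isinstance(spec, str):
        spec = model_spec(spec)
    X = design_matrix(cohort, list(spec.predictors)).to_numpy()
    y = cohort.df["aosbp_invasive"].to_numpy()
    if len(y) <= X.shape[1] + 1:
        raise ValueError(
            f"n={len(y)} too small for model '{spec.name}' with {X.shape[1]} predictors"
        )
    beta = _ols(X, y)
    fitted = beta[0] + X @ beta[1:]
    return FittedModel(
        spec=spec,
        intercept=float(beta[0]),
        coefficients={p: float(b) for p, b in zip(spec.predictors, beta[1:])},
        training=agreement(fitted, y),
        fitted_values=fitted,
    )


def lasso_select(
    cohort: CohortTable,
    candidates: list[str] | None = None,
    seed: int = 0,
    alpha: float | None = None,
    cv_folds: int = 10,
    rule: str = "1se",
) -> list[str]:
    """L1-penalised predictor selection for the AoSBP model.

    Candidates (default: the full-model set) are standardised to unit
    variance; the outcome stays on its native scale.  The penalty comes
    from ``cv_folds``-fold cross-validation with a seed-determined fold
    assignment: ``rule="1se"`` (default) takes the largest penalty whose
    mean CV error is within one standard error of the minimum — the
    glmnet parsimony rule, which keeps false selections rare — while
    ``rule="min"`` takes the error-minimising penalty.  ``alpha`` pins
    the penalty instead (``alpha=0`` is the unpenalised limit and retains
    every candidate of a full-rank design).  Returns the names with
    nonzero coefficients, in candidate order.
    """
    candidates = list(candidates) if candidates is not None else list(_FULL)
    X = design_matrix(cohort, candidates).to_numpy()
    y = cohort.df["aosbp_invasive"].to_numpy()
    if len(y) <= 20:
        raise ValueError(f"n={len(y)} too small for cross-validated selection")
    if np.std(y) == 0.0:
        raise ValueError("outcome has zero variance; selection undefined")
    if rule not in ("1se", "min"):
        raise ValueError(f"rule must be '1se' or 'min', got {rule!r}")
    Xs = StandardScaler().fit_transform(X)
    if alpha is not None and alpha == 0.0:
        beta = _ols(Xs, y)[1:]
        return [c for c, b in zip(candidates, beta) if b != 0.0]
    if alpha is not None:
        coefs = Lasso(alpha=alpha, max_iter=50_000).fit(Xs, y).coef_
    else:
        cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        model = LassoCV(cv=cv, max_iter=50_000).fit(Xs, y)
        if rule == "min":
            coefs = model.coef_
        else:
            mean_mse = model.mse_path_.mean(axis=1)
            se_mse = model.mse_path_.std(axis=1, ddof=1) / np.sqrt(
                model.mse_path_.shape[1]
            )
            i_min = int(np.argmin(mean_mse))
            threshold = mean_mse[i_min] + se_mse[i_min]
            # alphas_ are descending; the first index within threshold is the
            # largest (most parsimonious) admissible penalty
            i_1se = int(np.nonzero(mean_mse <= threshold)[0][0])
            coefs = Lasso(alpha=float(model.alphas_[i_1se]), max_iter=50_000).fit(
                Xs, y
            ).coef_
    return [c for c, b in zip(candidates, coefs) if b != 0.0]


def bootstrap_validate(
    cohort: CohortTable,
    spec: AdjustedModelSpec | str,
    B: int = 1000,
    seed: int = 0,
    scheme: str = "evaluate_original",
) -> BootstrapResult:
    """Bootstrap internal validation of an adjusted model.

    ``scheme="evaluate_original"`` (default): for each of B replications,
    resample n patients with replacement, refit on the resample, evaluate
    accuracy / precision / R² / ±10 mmHg on the original cohort, and
    average over replications.  ``scheme="optimism"`` instead subtracts
    the mean (resample-apparent − original-evaluated) optimism from the
    apparent metrics.  Rank-deficient resamples are skipped with a
    warning and counted.
    """
    if isinstance(spec, str):
        spec = model_spec(spec)
    if B < 1:
        raise ValueError(f"B must be >= 1, got {B}")
    if cohort.n < 20:
        raise ValueError(f"n={cohort.n} too small for bootstrap validation")
    if scheme not in ("evaluate_original", "optimism"):
        raise ValueError(f"unknown bootstrap scheme {scheme!r}")
    X = design_matrix(cohort, list(spec.predictors)).to_numpy()
    y = cohort.df["aosbp_invasive"].to_numpy()
    apparent = fit_adjusted_model(cohort, spec).training
    rng = np.random.default_rng(seed)
    n = len(y)
    rows, optimism_rows, skipped = [], [], 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            beta = _ols(X[idx], y[idx])
        except np.linalg.LinAlgError:
            skipped += 1
            continue
        pred = beta[0] + X @ beta[1:]
        s = agreement(pred, y)
        rows.append([s.accuracy, s.precision, s.r_squared, s.pct_within_10])
        if scheme == "optimism":
            pred_in = beta[0] + X[idx] @ beta[1:]
            a = agreement(pred_in, y[idx])
            optimism_rows.append(
                [
                    a.accuracy - s.accuracy,
                    a.precision - s.precision,
                    a.r_squared - s.r_squared,
                    a.pct_within_10 - s.pct_within_10,
                ]
            )
    if skipped:
        warnings.warn(
            f"skipped {skipped}/{B} rank-deficient bootstrap resamples",
            RuntimeWarning,
            stacklevel=2,
        )
    if not rows:
        raise ValueError("every bootstrap resample was rank deficient")
    if scheme == "optimism":
        opt = np.mean(optimism_rows, axis=0)
        vals = [
            apparent.accuracy - opt[0],
            apparent.precision - opt[1],
            apparent.r_squared - opt[2],
            apparent.pct_within_10 - opt[3],
        ]
    else:
        vals = list(np.mean(rows, axis=0))
    return BootstrapResult(
        spec_name=spec.name,
        B=B,
        seed=seed,
        accuracy=float(vals[0]),
        precision=float(vals[1]),
        r_squared=float(vals[2]),
        pct_within_10=float(vals[3]),
        skipped=skipped,
    )


def run_table3(
    cohort: CohortTable,
    B: int = 1000,
    seed: int = 0,
    model_names: list[str] | None = None,
    scheme: str = "evaluate_original",
) -> pd.DataFrame:
    """Performance ladder: raw measures, then adjusted models, apparent and bootstrap.

    Rows: brachial SBP, C1SBP and C2SBP taken at face value (their raw
    agreement with AoSBP, which the bootstrap leaves unchanged), then one
    row per adjusted model with apparent and bootstrap-validated
    accuracy / precision / R² / ±10 mmHg columns.
    """
    model_names = model_names or ["c1_c2", "demographics", "pwa", "full", "lasso"]
    ref = cohort.df["aosbp_invasive"].to_numpy()
    rows = []
    for label, col in RAW_MEASURES.items():
        s = agreement(cohort.df[col].to_numpy(), ref)
        rows.append(
            {
                "model": label,
                "kind": "raw",
                "accuracy": s.accuracy,
                "precision": s.precision,
                "r_squared": s.r_squared,
                "pct_within_10": s.pct_within_10,
                "boot_accuracy": s.accuracy,
                "boot_precision": s.precision,
                "boot_r_squared": s.r_squared,
                "boot_pct_within_10": s.pct_within_10,
            }
        )
    for k, name in enumerate(model_names):
        fit = fit_adjusted_model(cohort, name)
        boot = bootstrap_validate(cohort, name, B=B, seed=seed + k, scheme=scheme)
        s = fit.training
        rows.append(
            {
                "model": name,
                "kind": "adjusted",
                "accuracy": s.accuracy,
                "precision": s.precision,
                "r_squared": s.r_squared,
                "pct_within_10": s.pct_within_10,
                "boot_accuracy": boot.accuracy,
                "boot_precision": boot.precision,
                "boot_r_squared": boot.r_squared,
                "boot_pct_within_10": boot.pct_within_10,
            }
        )
    return pd.DataFrame(rows)
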