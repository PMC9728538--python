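"""Agreement statistics for device-validation comparisons.

Implements the validation vocabulary used for central blood-pressure
devices: *accuracy* is the mean of (estimated − reference) differences,
*precision* the sample SD of those differences, plus the share of
patients within ±10 mmHg of the reference, consensus pass/fail
thresholds (accuracy within 5 mmHg and precision within 8 mmHg, both
inclusive), age/sex-stratified comparisons, and the *modified*
Bland–Altman analysis in which the reference measurement — not the pair
mean — sits on the X axis.

Conventions fixed here and used package-wide:

* SDs use the n−1 (sample) denominator;
* the ±10 mmHg band is inclusive (|diff| = 10 counts as within);
* age strata are left-closed, right-open: [40, 60), [60, 80), [80, ∞);
* the sex comparison is a pooled-variance (Student) t-test, the age
  comparison a one-way ANOVA, both on signed differences;
* limits of agreement are bias ± 2·SD (exactly 2, not 1.96).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .synthetic_cohort import CohortTable

__all__ = [
    "AgreementSummary",
    "ArteryCheck",
    "StrataComparison",
    "BlandAltmanResult",
    "AGE_BINS",
    "agreement",
    "artery_check",
    "stratified_agreement",
    "bland_altman",
]

#: Age strata: label -> [low, high) in years.
AGE_BINS = {"40-60": (40.0, 60.0), "60-80": (60.0, 80.0), ">=80": (80.0, np.inf)}

ARTERY_ACCURACY_LIMIT = 5.0  # mmHg, |mean difference|
ARTERY_PRECISION_LIMIT = 8.0  # mmHg, SD of differences


@dataclass(frozen=True)
class AgreementSummary:
    """One row of a device-validation table."""

    n: int
    accuracy: float  # mmHg, mean(estimate - reference)
    precision: float  # mmHg, sample SD of differences
    r_squared: Optional[float]  # %, reference variance explained
    pct_within_10: float  # % of |diff| <= 10 mmHg

    def __post_init__(self) -> None:
        if self.precision < 0:
            raise ValueError(f"precision must be >= 0, got {self.precision}")
        if not (0.0 <= self.pct_within_10 <= 100.0):
            raise ValueError(f"pct_within_10 out of [0, 100]: {self.pct_within_10}")


@dataclass(frozen=True)
class ArteryCheck:
    passed: bool
    reasons: tuple[str, ...]  # empty when passed


@dataclass(frozen=True)
class StrataComparison:
    by: str  # "age" | "sex"
    strata: dict[str, AgreementSummary]
    p_value: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value out of [0, 1]: {self.p_value}")


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    loa_low: float  # bias - 2*SD
    loa_high: float  # bias + 2*SD
    slope: float  # OLS slope of (est - ref) on ref
    slope_ci_low: float
    slope_ci_high: float


def _paired(estimates, reference) -> tuple[np.ndarray, np.ndarray]:
    est = np.asarray(estimates, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if est.shape != ref.shape or est.ndim != 1:
        raise ValueError(
            f"estimates and reference must be equal-length 1-d series, "
            f"got shapes {est.shape} and {ref.shape}"
        )
    return est, ref


def agreement(estimates, reference) -> AgreementSummary:
    """Accuracy / precision / R² / within-±10 summary of paired series.

    R² is the squared Pearson correlation between estimate and reference
    (×100): for a univariate least-squares fit, and for in-sample
    predictions of any least-squares model, this equals the model R².
    It is omitted (None) when either series is constant.
    """
    est, ref = _paired(estimates, reference)
    n = est.size
    if n < 2:
        raise ValueError(f"need at least 2 pairs for an SD, got {n}")
    diff = est - ref
    accuracy = float(np.mean(diff))
    precision = float(np.std(diff, ddof=1))
    if np.std(est) == 0.0 or np.std(ref) == 0.0:
        r2 = None
    else:
        r2 = float(100.0 * np.corrcoef(est, ref)[0, 1] ** 2)
    pct = float(100.0 * np.mean(np.abs(diff) <= 10.0))
    return AgreementSummary(
        n=n, accuracy=accuracy, precision=precision, r_squared=r2, pct_within_10=pct
    )


def artery_check(s: AgreementSummary) -> ArteryCheck:
    """Consensus pass/fail: |accuracy| ≤ 5 mmHg and precision ≤ 8 mmHg (inclusive)."""
    reasons = []
    if abs(s.accuracy) > ARTERY_ACCURACY_LIMIT:
        reasons.append(
            f"accuracy {s.accuracy:+.1f} mmHg exceeds ±{ARTERY_ACCURACY_LIMIT:g} mmHg"
        )
    if s.precision > ARTERY_PRECISION_LIMIT:
        reasons.append(
            f"precision {s.precision:.1f} mmHg exceeds {ARTERY_PRECISION_LIMIT:g} mmHg"
        )
    return ArteryCheck(passed=not reasons, reasons=tuple(reasons))


def _group_pvalue(groups: Sequence[np.ndarray], by: str) -> float:
    """ANOVA across age bins, pooled-variance t-test between sexes.

    Degenerate inputs (all groups constant) give p = 1 when the group
    means coincide — no evidence of a difference — and p = 0 when they
    differ with zero within-group variance; both emit a warning.
    """
    pooled_var = sum(((len(g) - 1) * np.var(g, ddof=1) if len(g) > 1 else 0.0) for g in groups)
    if pooled_var == 0.0:
        means = [float(np.mean(g)) for g in groups]
        same = np.allclose(means, means[0])
        warnings.warn(
            "zero within-stratum variance; p-value set to "
            f"{1.0 if same else 0.0} by convention",
            RuntimeWarning,
            stacklevel=3,
        )
        return 1.0 if same else 0.0
    if by == "sex":
        t = stats.ttest_ind(groups[0], groups[1], equal_var=True)
        return float(t.pvalue)
    f = stats.f_oneway(*groups)
    return float(f.pvalue)


def stratified_agreement(
    cohort: CohortTable, estimates, by: str = "age"
) -> StrataComparison:
    """Per-stratum agreement with a between-stratum test on the differences.

    ``by='age'`` uses the [40,60) / [60,80) / [80,∞) bins and a one-way
    ANOVA; ``by='sex'`` uses a pooled-variance two-sample t-test.
    Patients outside every age bin (< 40 y) are dropped from the age
    comparison.
    """
    est = np.asarray(estimates, dtype=float)
    if est.shape != (cohort.n,):
        raise ValueError(
            f"estimates must have one value per patient ({cohort.n}), got {est.shape}"
        )
    ref = cohort.df["aosbp_invasive"].to_numpy()
    diff = est - ref

    if by == "age":
        age = cohort.df["age"].to_numpy()
        masks = {
            label: (age >= lo) & (age < hi) for label, (lo, hi) in AGE_BINS.items()
        }
        nonempty = {k: m for k, m in masks.items() if m.sum() >= 2}
        if len(nonempty) < 2:
            empty = [k for k, m in masks.items() if m.sum() < 2]
            raise ValueError(
                f"age stratification needs >= 2 populated bins; too few patients in {empty}"
            )
        masks = nonempty
    elif by == "sex":
        sex = cohort.df["sex"].to_numpy()
        masks = {"men": sex == "male", "women": sex == "female"}
        for label, m in masks.items():
            if m.sum() < 2:
                raise ValueError(f"sex stratification requires >= 2 {label}")
    else:
        raise ValueError(f"by must be 'age' or 'sex', got {by!r}")

    strata = {
        label: agreement(est[m], ref[m]) for label, m in masks.items()
    }
    p = _group_pvalue([diff[m] for m in masks.values()], by)
    return StrataComparison(by=by, strata=strata, p_value=p)


def bland_altman(estimates, reference) -> BlandAltmanResult:
    """Modified Bland–Altman analysis: differences against the *reference*.

    Returns the bias, limits of agreement (bias ± 2·SD) and the OLS slope
    (with 95% CI) of (estimate − reference) on the reference.  For
    in-sample least-squares predictions the slope equals R² − 1 exactly,
    so a model explaining 70% of reference variance shows a −0.30 trend.
    """
    est, ref = _paired(estimates, reference)
    if est.size < 3:
        raise ValueError(f"need at least 3 pairs, got {est.size}")
    if np.std(ref) == 0.0:
        raise ValueError("reference series is constant; slope undefined")
    diff = est - ref
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    fit = sm.OLS(diff, sm.add_constant(ref)).fit()
    ci = fit.conf_int(alpha=0.05)
    return BlandAltmanResult(
        bias=bias,
        loa_low=bias - 2.0 * sd,
        loa_high=bias + 2.0 * sd,
        slope=float(fit.params[1]),
        slope_ci_low=float(ci[1, 0]),
        slope_ci_high=float(ci[1, 1]),
    )
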