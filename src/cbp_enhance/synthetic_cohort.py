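"""Synthetic catheterization-cohort generator.

Emulates a cohort of patients with simultaneous invasive aortic SBP
(AoSBP) and brachial-cuff based non-invasive measurements, with the bias
structure the downstream analysis is built to detect:

* Type I calibrated central SBP (C1SBP) **underestimates** AoSBP, the
  more so with higher SBP amplification, higher age and female sex;
* Type II calibrated central SBP (C2SBP) **overestimates** AoSBP, the
  more so at lower heart rates (default +4.7 mmHg per 10 bpm decrease),
  with smaller age and augmentation-index contributions.

Generative chain (per patient):

1. draw clinical covariates; age is coupled to amplification (−),
   ePWV (+) and AIx@75 (+) through a Gaussian copula;
2. draw AoSBP;
3. ``brachial_sbp = mean + attenuation*(AoSBP − mean) + bias(age, sex)
   + shared_cuff_error + e_brachial`` — the attenuation (< 1) is the
   regression-dilution that makes underestimation grow with AoSBP, as raw
   modified Bland–Altman plots of cuff-based estimates show; cuff DBP is
   drawn correlated with cuff SBP;
4. draw SBP amplification (log-normal matched to a median/IQR) and set
   ``c1sbp = brachial_sbp − amplification`` (the amplification column is
   then re-derived as ``brachial_sbp − c1sbp`` so the defining identity
   holds bit-exactly);
5. ``c2sbp = mean + attenuation*(AoSBP − mean)
   + overestimation(heart_rate, age, AIx75) + shared_cuff_error + e_c2``.

The shared cuff-error component appears in both the brachial and the C2
noise: both measurements descend from the same oscillometric cuff
reading, and the component bounds how much of AoSBP any model built on
the non-invasive channels can recover.  Its default standard deviation
is calibrated so the fully adjusted prediction model attains an
in-sample R² of about 0.70 on a default cohort.

Physiologically absurd draws (any pressure <= 40 mmHg, heart rate
<= 30 bpm, SBP <= DBP, non-positive anthropometrics) are redrawn whole-row
rather than truncated, so configured means are not distorted; the redraw
count is logged at DEBUG.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as dc_fields, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "GeneratorConfig",
    "CohortTable",
    "ParameterError",
    "SchemaError",
    "CohortValidationError",
    "generate_cohort",
    "read_cohort",
    "write_cohort",
    "COHORT_COLUMNS",
    "female_indicator",
]


class ParameterError(ValueError):
    """Invalid generator configuration."""


class SchemaError(ValueError):
    """Cohort file missing a required column or carrying a bad value."""


class CohortValidationError(ValueError):
    """A cohort row violates a physiological/definitional invariant."""


#: Column order of a cohort table / CSV (one row per patient).
COHORT_COLUMNS = [
    "age",
    "sex",
    "height",
    "weight",
    "bmi",
    "egfr",
    "active_smoking",
    "diabetes",
    "antihypertensive_any",
    "statin",
    "aspirin",
    "heart_rate",
    "aosbp_invasive",
    "brachial_sbp",
    "brachial_dbp",
    "c1sbp",
    "c2sbp",
    "amplification",
    "aix75",
    "reflection_magnitude",
    "epwv",
]

_BINARY_COLUMNS = ["active_smoking", "diabetes", "antihypertensive_any", "statin", "aspirin"]
_PRESSURE_COLUMNS = ["aosbp_invasive", "brachial_sbp", "brachial_dbp", "c1sbp", "c2sbp"]
_NUMERIC_COLUMNS = [c for c in COHORT_COLUMNS if c != "sex"]


def _lognormal_sigma(median: float, q1: float, q3: float) -> float:
    """Log-normal sigma matched to a printed median and interquartile range.

    Averages the sigma implied by each quartile (0.6745 is the standard
    normal upper quartile), which splits the difference when the printed
    IQR is not exactly log-symmetric.
    """
    z = 0.6744897501960817
    return 0.5 * (np.log(q3 / median) + np.log(median / q1)) / z


def _lognormal_mean(median: float, sigma: float) -> float:
    return median * float(np.exp(0.5 * sigma**2))


@dataclass(frozen=True)
class GeneratorConfig:
    """Marginals, covariate coupling and bias structure of the simulated cohort.

    Marginal defaults reproduce a catheterization cohort of mostly older,
    mostly male patients; bias defaults encode Type-I underestimation that
    deepens with age and female sex and Type-II overestimation that grows
    as heart rate falls.
    """

    n: int = 500
    seed: int = 0

    # --- marginals (mean/SD unless noted) ---
    age_mean: float = 65.7
    age_sd: float = 10.0
    male_fraction: float = 0.71
    height_mean: float = 170.0
    height_sd: float = 9.8
    weight_mean: float = 82.7
    weight_sd: float = 18.7
    egfr_mean: float = 80.2
    egfr_sd: float = 17.4
    smoking_prevalence: float = 0.248
    diabetes_prevalence: float = 0.282
    antihypertensive_prevalence: float = 0.798
    statin_prevalence: float = 0.696
    aspirin_prevalence: float = 0.708
    heart_rate_mean: float = 67.6
    heart_rate_sd: float = 12.1
    aosbp_mean: float = 126.5
    aosbp_sd: float = 21.7
    brachial_dbp_mean: float = 76.6
    brachial_dbp_sd: float = 10.8
    # correlation of cuff DBP with cuff SBP; keeps SBP > DBP essentially
    # automatic so redraws stay rare and marginals unbiased
    dbp_sbp_corr: float = 0.7
    epwv_mean: float = 9.39
    epwv_sd: float = 1.80
    reflection_mean: float = 66.9
    reflection_sd: float = 9.1
    # log-normal marginals given as median + quartiles
    amplification_median: float = 8.0
    amplification_q1: float = 5.0
    amplification_q3: float = 12.0
    aix75_median: float = 20.3
    aix75_q1: float = 10.6
    aix75_q3: float = 28.1

    # --- covariate coupling (Gaussian-copula correlations with age) ---
    # kept weaker than the other couplings: at -0.3 the implied fall of
    # amplification with age (~0.21 mmHg/y) would cancel the direct age bias
    # (-0.17 mmHg/y) and invert the Type-I age-stratum ordering
    age_amplification_corr: float = -0.15
    age_epwv_corr: float = 0.3
    age_aix75_corr: float = 0.3

    # --- brachial-vs-aortic bias: b0 + slope*(age-age_mean) + female_shift*female ---
    brachial_bias_male: float = -0.3       # mmHg, men at mean age
    brachial_bias_female_shift: float = -6.2  # mmHg added for women
    brachial_bias_age_slope: float = -0.17    # mmHg per year

    # --- C2 overestimation: mean_bias + slopes on centred covariates ---
    c2_bias_mean: float = 6.2              # mmHg, cohort-mean overestimation
    c2_heart_rate_slope: float = -0.47     # mmHg per bpm (+4.7 per 10 bpm decrease)
    c2_age_slope: float = -0.10            # mmHg per year
    c2_aix75_slope: float = -0.05          # mmHg per AIx75 unit

    # --- measurement-error structure of the non-invasive channels ---
    # attenuation < 1 gives the regression-dilution seen in raw
    # modified Bland-Altman plots (underestimation grows with AoSBP);
    # the shared cuff error appears in both channels and bounds how much
    # aortic variance any adjusted model can recover
    brachial_attenuation: float = 0.644  # slope of brachial SBP on AoSBP
    c2_attenuation: float = 0.628        # slope of C2SBP on AoSBP
    shared_noise_sd: float = 9.3    # cuff error common to brachial and C2 channels
    brachial_noise_sd: float = 2.0  # brachial-specific
    c2_noise_sd: float = 4.8        # C2-specific

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ParameterError(f"n must be >= 0, got {self.n}")
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if f.name.endswith("_sd") and v <= 0:
                raise ParameterError(f"{f.name} must be > 0, got {v}")
            if (f.name.endswith("_prevalence") or f.name == "male_fraction") and not (
                0.0 <= v <= 1.0
            ):
                raise ParameterError(f"{f.name} must be in [0, 1], got {v}")
            if f.name.endswith("_corr") and not (-1.0 < v < 1.0):
                raise ParameterError(f"{f.name} must be in (-1, 1), got {v}")
        for name in ("brachial_attenuation", "c2_attenuation"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ParameterError(f"{name} must be in (0, 1], got {v}")
        for name in ("amplification", "aix75"):
            q1 = getattr(self, f"{name}_q1")
            med = getattr(self, f"{name}_median")
            q3 = getattr(self, f"{name}_q3")
            if not (0 < q1 < med < q3):
                raise ParameterError(
                    f"{name} quartiles must satisfy 0 < q1 < median < q3, "
                    f"got ({q1}, {med}, {q3})"
                )

    # log-normal shape parameters and analytic means, derived once
    @property
    def amplification_sigma(self) -> float:
        return _lognormal_sigma(
            self.amplification_median, self.amplification_q1, self.amplification_q3
        )

    @property
    def amplification_mean(self) -> float:
        return _lognormal_mean(self.amplification_median, self.amplification_sigma)

    @property
    def aix75_sigma(self) -> float:
        return _lognormal_sigma(self.aix75_median, self.aix75_q1, self.aix75_q3)

    @property
    def aix75_mean(self) -> float:
        return _lognormal_mean(self.aix75_median, self.aix75_sigma)

    @classmethod
    def from_file(cls, path: str | Path) -> "GeneratorConfig":
        """Load a flat YAML/JSON key-value config; unknown keys are rejected."""
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dc_fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown generator config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class CohortTable:
    """Validated per-patient table consumed by every pipeline stage.

    ``df`` holds one row per patient with columns :data:`COHORT_COLUMNS`
    (``sex`` as the strings male/female, binary flags as 0/1 integers).
    """

    df: pd.DataFrame
    provenance: str = "synthetic"  # "synthetic" | "file"
    seed: Optional[int] = None

    @property
    def n(self) -> int:
        return len(self.df)

    def validate(self) -> "CohortTable":
        """Raise if any row violates the record invariants; return self."""
        df = self.df
        missing = [c for c in COHORT_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"cohort is missing required column(s): {missing}")
        if self.n == 0:
            return self
        na_rows = df[COHORT_COLUMNS].isna().any(axis=1)
        if na_rows.any():
            raise CohortValidationError(
                f"missing values in rows {list(df.index[na_rows][:10])}"
            )
        bad_sex = ~df["sex"].isin(["male", "female"])
        if bad_sex.any():
            raise CohortValidationError(
                f"sex must be 'male' or 'female'; bad rows {list(df.index[bad_sex][:10])}"
            )
        for col in _PRESSURE_COLUMNS:
            bad = df[col] <= 0
            if bad.any():
                raise CohortValidationError(
                    f"non-positive {col} in rows {list(df.index[bad][:10])}"
                )
        bad = df["brachial_sbp"] <= df["brachial_dbp"]
        if bad.any():
            raise CohortValidationError(
                "brachial_sbp must exceed brachial_dbp; "
                f"bad rows {list(df.index[bad][:10])}"
            )
        bad = df["heart_rate"] <= 0
        if bad.any():
            raise CohortValidationError(
                f"non-positive heart_rate in rows {list(df.index[bad][:10])}"
            )
        # definitional identities (amplification exact, BMI to rounding)
        amp_err = (df["amplification"] - (df["brachial_sbp"] - df["c1sbp"])).abs()
        bad = amp_err > 1e-8
        if bad.any():
            raise CohortValidationError(
                "amplification must equal brachial_sbp - c1sbp; "
                f"bad rows {list(df.index[bad][:10])}"
            )
        bmi_err = (df["bmi"] - df["weight"] / (df["height"] / 100.0) ** 2).abs()
        bad = bmi_err > 1e-6
        if bad.any():
            raise CohortValidationError(
                f"bmi inconsistent with weight/height in rows {list(df.index[bad][:10])}"
            )
        return self


def female_indicator(cohort: CohortTable | pd.DataFrame) -> pd.Series:
    """Sex as the 0/1 indicator used in every model: female=1, male=0."""
    df = cohort.df if isinstance(cohort, CohortTable) else cohort
    return (df["sex"] == "female").astype(float)


def _copula_cholesky(cfg: GeneratorConfig) -> np.ndarray:
    # latent order: age, amplification, epwv, aix75
    r = np.eye(4)
    r[0, 1] = r[1, 0] = cfg.age_amplification_corr
    r[0, 2] = r[2, 0] = cfg.age_epwv_corr
    r[0, 3] = r[3, 0] = cfg.age_aix75_corr
    try:
        return np.linalg.cholesky(r)
    except np.linalg.LinAlgError as exc:
        raise ParameterError(
            "copula correlation matrix is not positive definite"
        ) from exc


def _draw_block(rng: np.random.Generator, m: int, cfg: GeneratorConfig, chol: np.ndarray) -> pd.DataFrame:
    z = rng.standard_normal((m, 4)) @ chol.T
    age = cfg.age_mean + cfg.age_sd * z[:, 0]
    amplification = np.exp(
        np.log(cfg.amplification_median) + cfg.amplification_sigma * z[:, 1]
    )
    epwv = cfg.epwv_mean + cfg.epwv_sd * z[:, 2]
    aix = np.exp(np.log(cfg.aix75_median) + cfg.aix75_sigma * z[:, 3])

    female = rng.random(m) >= cfg.male_fraction
    height = rng.normal(cfg.height_mean, cfg.height_sd, m)
    weight = rng.normal(cfg.weight_mean, cfg.weight_sd, m)
    egfr = rng.normal(cfg.egfr_mean, cfg.egfr_sd, m)
    heart_rate = rng.normal(cfg.heart_rate_mean, cfg.heart_rate_sd, m)
    reflection = rng.normal(cfg.reflection_mean, cfg.reflection_sd, m)
    smoking = rng.random(m) < cfg.smoking_prevalence
    diabetes = rng.random(m) < cfg.diabetes_prevalence
    antihyp = rng.random(m) < cfg.antihypertensive_prevalence
    statin = rng.random(m) < cfg.statin_prevalence
    aspirin = rng.random(m) < cfg.aspirin_prevalence

    aosbp = rng.normal(cfg.aosbp_mean, cfg.aosbp_sd, m)

    shared = rng.normal(0.0, cfg.shared_noise_sd, m)
    e_brach = rng.normal(0.0, cfg.brachial_noise_sd, m)
    e_c2 = rng.normal(0.0, cfg.c2_noise_sd, m)

    brachial_bias = (
        cfg.brachial_bias_male
        + cfg.brachial_bias_age_slope * (age - cfg.age_mean)
        + cfg.brachial_bias_female_shift * female
    )
    aosbp_centred = aosbp - cfg.aosbp_mean
    brachial_sbp = (
        cfg.aosbp_mean
        + cfg.brachial_attenuation * aosbp_centred
        + brachial_bias
        + shared
        + e_brach
    )
    c1sbp = brachial_sbp - amplification
    # re-derive so amplification == brachial_sbp - c1sbp holds bit-exactly
    amplification = brachial_sbp - c1sbp

    # DBP correlated with cuff SBP around the theoretical SBP moments; only
    # DBP is redrawn on the rare SBP<=DBP conflict so SBP marginals stay clean
    p_f = 1.0 - cfg.male_fraction
    sbp_mean_theory = (
        cfg.aosbp_mean + cfg.brachial_bias_male + cfg.brachial_bias_female_shift * p_f
    )
    sbp_sd_theory = float(
        np.sqrt(
            (cfg.brachial_attenuation * cfg.aosbp_sd) ** 2
            + (cfg.brachial_bias_age_slope * cfg.age_sd) ** 2
            + cfg.brachial_bias_female_shift**2 * p_f * (1 - p_f)
            + cfg.shared_noise_sd**2
            + cfg.brachial_noise_sd**2
        )
    )
    rho = cfg.dbp_sbp_corr
    dbp_cond_mean = cfg.brachial_dbp_mean + rho * (
        cfg.brachial_dbp_sd / sbp_sd_theory
    ) * (brachial_sbp - sbp_mean_theory)
    dbp_cond_sd = cfg.brachial_dbp_sd * float(np.sqrt(1.0 - rho**2))
    brachial_dbp = dbp_cond_mean + dbp_cond_sd * rng.standard_normal(m)
    for _ in range(1000):
        bad_dbp = (brachial_dbp >= brachial_sbp) | (brachial_dbp <= 40.0)
        if not bad_dbp.any():
            break
        brachial_dbp[bad_dbp] = dbp_cond_mean[bad_dbp] + dbp_cond_sd * rng.standard_normal(
            int(bad_dbp.sum())
        )

    c2_bias = (
        cfg.c2_bias_mean
        + cfg.c2_heart_rate_slope * (heart_rate - cfg.heart_rate_mean)
        + cfg.c2_age_slope * (age - cfg.age_mean)
        + cfg.c2_aix75_slope * (aix - cfg.aix75_mean)
    )
    c2sbp = (
        cfg.aosbp_mean + cfg.c2_attenuation * aosbp_centred + c2_bias + shared + e_c2
    )

    return pd.DataFrame(
        {
            "age": age,
            "sex": np.where(female, "female", "male"),
            "height": height,
            "weight": weight,
            "bmi": weight / (height / 100.0) ** 2,
            "egfr": egfr,
            "active_smoking": smoking.astype(int),
            "diabetes": diabetes.astype(int),
            "antihypertensive_any": antihyp.astype(int),
            "statin": statin.astype(int),
            "aspirin": aspirin.astype(int),
            "heart_rate": heart_rate,
            "aosbp_invasive": aosbp,
            "brachial_sbp": brachial_sbp,
            "brachial_dbp": brachial_dbp,
            "c1sbp": c1sbp,
            "c2sbp": c2sbp,
            "amplification": amplification,
            "aix75": aix,
            "reflection_magnitude": reflection,
            "epwv": epwv,
        }
    )


def _invalid_rows(df: pd.DataFrame) -> np.ndarray:
    bad = np.zeros(len(df), dtype=bool)
    for col in _PRESSURE_COLUMNS:
        bad |= (df[col] <= 40.0).to_numpy()
    bad |= (df["heart_rate"] <= 30.0).to_numpy()
    bad |= (df["brachial_sbp"] <= df["brachial_dbp"]).to_numpy()
    for col in ("height", "weight", "egfr", "epwv", "reflection_magnitude"):
        bad |= (df[col] <= 0.0).to_numpy()
    bad |= (df["age"] <= 18.0).to_numpy()
    return bad


def generate_cohort(config: GeneratorConfig) -> CohortTable:
    """Draw a synthetic cohort of ``config.n`` patients.

    Deterministic: identical configs (including ``seed``) give identical
    tables.  Rows failing plausibility screens are redrawn whole.
    """
    rng = np.random.default_rng(config.seed)
    chol = _copula_cholesky(config)
    if config.n == 0:
        df = pd.DataFrame({c: pd.Series(dtype=float) for c in COHORT_COLUMNS})
        df["sex"] = df["sex"].astype(str)
        return CohortTable(df=df, provenance="synthetic", seed=config.seed)

    df = _draw_block(rng, config.n, config, chol)
    redraws = 0
    for _ in range(1000):
        bad = _invalid_rows(df)
        if not bad.any():
            break
        redraws += int(bad.sum())
        df.loc[bad, :] = _draw_block(rng, int(bad.sum()), config, chol).to_numpy()
        # restore dtypes clobbered by the block assignment
        for col in _NUMERIC_COLUMNS:
            df[col] = df[col].astype(float)
    else:
        raise ParameterError(
            "could not draw a plausible cohort; configuration places too much "
            "mass on physiologically impossible values"
        )
    if redraws:
        logger.debug("redrew %d implausible row draws for n=%d", redraws, config.n)
    for col in _BINARY_COLUMNS:
        df[col] = df[col].astype(int)
    df = df[COHORT_COLUMNS].reset_index(drop=True)
    return CohortTable(df=df, provenance="synthetic", seed=config.seed).validate()


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write a cohort as UTF-8 CSV (header = the record field names).

    Floats are written with ``repr`` precision so a write→read round trip
    reproduces every numeric field bit-exactly.
    """
    cohort.df[COHORT_COLUMNS].to_csv(path, index=False)


def read_cohort(path: str | Path) -> CohortTable:
    """Read and validate a cohort CSV.

    Raises
    ------
    SchemaError
        If a required column is missing or a numeric field fails to parse
        (the offending rows are named).
    CohortValidationError
        If a row violates a physiological or definitional invariant.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort file {path} is missing column(s): {missing}")
    for col in _NUMERIC_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            raise SchemaError(
                f"non-numeric value in column '{col}' at row(s) "
                f"{list(df.index[bad][:10])} of {path}"
            )
        df[col] = coerced.astype(float)
    for col in _BINARY_COLUMNS:
        if not df[col].isin([0, 1]).all():
            bad = ~df[col].isin([0, 1])
            raise SchemaError(
                f"column '{col}' must be 0/1; bad row(s) {list(df.index[bad][:10])}"
            )
        df[col] = df[col].astype(int)
    return CohortTable(df=df, provenance="file", seed=None).validate()
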