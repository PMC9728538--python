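"""End-to-end orchestration: simulate/load → attribute → fit → validate → report.

A run consumes either a generator config (synthetic cohort) or a cohort
CSV, and writes a fixed set of outputs to the output directory:

* ``cohort.csv`` — the analysed cohort;
* ``table2.csv`` — accuracy/precision by age and sex strata for brachial
  SBP, C1SBP, C2SBP and the fully adjusted model, with between-stratum
  p-values;
* ``table3.csv`` — the model-ladder performance table (apparent and
  bootstrap columns);
* ``ds1_c1.csv`` / ``ds1_c2.csv`` — difference-model attributions
  (beta, p, partial R², VIF per predictor);
* ``bland_altman.csv`` — modified Bland–Altman bias, limits of agreement
  and slope for each raw measure and the full model;
* ``manifest.json`` — seed, config hash, package version, row counts and
  the file list.

Reproducibility: a single run seed fans out to per-stage child seeds by
fixed offsets (generator +0, LASSO folds +1, bootstrap +2; all kept
below 2³¹), so any stage can be re-run in isolation. Identical config
and seed give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .agreement import bland_altman, stratified_agreement
from .attribution import fit_difference_model
from .models import fit_adjusted_model, lasso_select, run_table3
from .synthetic_cohort import (
    CohortTable,
    GeneratorConfig,
    generate_cohort,
    read_cohort,
    write_cohort,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "child_seed"]

_SEED_MOD = 2**31
_STAGE_OFFSETS = {"generator": 0, "lasso": 1, "bootstrap": 2}


def child_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed: (seed + fixed stage offset) mod 2³¹."""
    return (seed + _STAGE_OFFSETS[stage]) % _SEED_MOD


@dataclass(frozen=True)
class RunConfig:
    """Exactly one of ``generator`` / ``cohort_csv`` selects the input."""

    out_dir: str | Path
    generator: Optional[GeneratorConfig] = None
    cohort_csv: Optional[str | Path] = None
    models: tuple[str, ...] = ("c1_c2", "demographics", "pwa", "full", "lasso")
    B: int = 1000
    seed: int = 0
    run_lasso_selection: bool = True
    bootstrap_scheme: str = "evaluate_original"

    def __post_init__(self) -> None:
        if (self.generator is None) == (self.cohort_csv is None):
            raise ValueError(
                "provide exactly one of a generator config or a cohort CSV path"
            )


def _config_hash(cfg: RunConfig) -> str:
    d = dataclasses.asdict(cfg)
    d["out_dir"] = str(d["out_dir"])
    if d.get("cohort_csv") is not None:
        d["cohort_csv"] = str(d["cohort_csv"])
    return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _table2(cohort: CohortTable, full_fit) -> pd.DataFrame:
    measures = {
        "brachial": cohort.df["brachial_sbp"].to_numpy(),
        "c1": cohort.df["c1sbp"].to_numpy(),
        "c2": cohort.df["c2sbp"].to_numpy(),
        "adjusted_full": full_fit.fitted_values,
    }
    rows = []
    for name, est in measures.items():
        for by in ("age", "sex"):
            comp = stratified_agreement(cohort, est, by=by)
            for label, s in comp.strata.items():
                rows.append(
                    {
                        "measure": name,
                        "stratified_by": by,
                        "stratum": label,
                        "n": s.n,
                        "accuracy": s.accuracy,
                        "precision": s.precision,
                        "p_value": comp.p_value,
                    }
                )
    return pd.DataFrame(rows)


def _bland_altman_table(cohort: CohortTable, full_fit) -> pd.DataFrame:
    ref = cohort.df["aosbp_invasive"].to_numpy()
    measures = {
        "brachial": cohort.df["brachial_sbp"].to_numpy(),
        "c1": cohort.df["c1sbp"].to_numpy(),
        "c2": cohort.df["c2sbp"].to_numpy(),
        "adjusted_full": full_fit.fitted_values,
    }
    rows = []
    for name, est in measures.items():
        ba = bland_altman(est, ref)
        rows.append(
            {
                "measure": name,
                "bias": ba.bias,
                "loa_low": ba.loa_low,
                "loa_high": ba.loa_high,
                "slope": ba.slope,
                "slope_ci_low": ba.slope_ci_low,
                "slope_ci_high": ba.slope_ci_high,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every analysis stage; return (and write) the run manifest.

    Aborts on the first stage error, naming the stage; files written
    before the failure are removed so a failed run leaves no partial
    outputs.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"
    t0 = time.perf_counter()
    try:
        stage = "cohort"
        if cfg.generator is not None:
            gen = dataclasses.replace(
                cfg.generator, seed=child_seed(cfg.seed, "generator")
            )
            cohort = generate_cohort(gen)
        else:
            cohort = read_cohort(cfg.cohort_csv)
        _log_stage(stage, t0, n=cohort.n)

        path = out / "cohort.csv"
        write_cohort(cohort, path)
        written.append(path)

        stage = "attribute"
        ds1 = {t: fit_difference_model(cohort, t) for t in ("c1", "c2")}
        for t, fit in ds1.items():
            path = out / f"ds1_{t}.csv"
            fit.to_frame().to_csv(path, index=False)
            written.append(path)
        _log_stage(stage, t0)

        stage = "fit"
        full_fit = fit_adjusted_model(cohort, "full")
        selected = (
            lasso_select(cohort, seed=child_seed(cfg.seed, "lasso"))
            if cfg.run_lasso_selection
            else None
        )
        _log_stage(stage, t0)

        stage = "validate"
        table3 = run_table3(
            cohort,
            B=cfg.B,
            seed=child_seed(cfg.seed, "bootstrap"),
            model_names=list(cfg.models),
            scheme=cfg.bootstrap_scheme,
        )
        path = out / "table3.csv"
        table3.to_csv(path, index=False)
        written.append(path)
        _log_stage(stage, t0)

        stage = "report"
        path = out / "table2.csv"
        _table2(cohort, full_fit).to_csv(path, index=False)
        written.append(path)
        path = out / "bland_altman.csv"
        _bland_altman_table(cohort, full_fit).to_csv(path, index=False)
        written.append(path)
        _log_stage(stage, t0)
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed in stage '{stage}': {exc}") from exc

    manifest = {
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "version": __version__,
        "n_patients": cohort.n,
        "provenance": cohort.provenance,
        "B": cfg.B,
        "models": list(cfg.models),
        "lasso_selected": selected,
        "stage_seeds": {s: child_seed(cfg.seed, s) for s in _STAGE_OFFSETS},
        "files": [p.name for p in written],
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _log_stage(stage: str, t0: float, **extra) -> None:
    logger.info(
        "stage %-9s done at %.2fs%s",
        stage,
        time.perf_counter() - t0,
        "".join(f" {k}={v}" for k, v in extra.items()),
    )
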