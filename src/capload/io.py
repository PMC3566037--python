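"""Cohort table I/O, the exclusion ledger, and the end-to-end pipeline.

Cohort CSV column dictionary (one record per child):

    id          unique identifier
    sex         "male" | "female"
    gest_age_wk gestational age at birth, weeks
    bw_kg       birth weight, kg
    blen_cm     crown-heel length at birth, cm
    wt7_kg, ht7_cm, age7_mo      mid-childhood visit (weight kg, height cm,
                                 age months)
    wt9_kg, ht9_cm, lm9_kg, fm9_kg, age9_mo
                outcome visit: weight, height, DXA lean and fat mass (kg),
                age (months)
    sbp, dbp    systolic / diastolic blood pressure, mmHg

Malformed numeric cells ("NA", "", ".", text) are read as missing and
counted; physically impossible values (non-positive quantities, SBP <= DBP)
are logged and left to the outlier screens rather than silently dropped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import SEXES
from .exceptions import SchemaError
from .models import render_suite, run_suite
from .references import ReferenceSet, read_reference_csv
from .residuals import ALL_PREDICTORS, build_predictor_set

logger = logging.getLogger("capload")

__all__ = ["COHORT_COLUMNS", "ExclusionLedger", "read_cohort", "write_cohort",
           "run_pipeline"]

MANDATORY_COLUMNS = ["id", "sex", "ht9_cm", "lm9_kg", "fm9_kg", "age9_mo", "sbp", "dbp"]
COHORT_COLUMNS = [
    "id", "sex", "gest_age_wk", "bw_kg", "blen_cm",
    "wt7_kg", "ht7_cm", "age7_mo",
    "wt9_kg", "ht9_cm", "lm9_kg", "fm9_kg", "age9_mo",
    "sbp", "dbp",
]
NA_VALUES = ["NA", "", ".", "NaN", "nan"]


@dataclass
class ExclusionLedger:
    """Per-step record of excluded children, mirroring per-step outlier counts."""

    steps: list[dict] = field(default_factory=list)

    def record(self, step: str, ids, reason: str = "") -> None:
        ids = list(ids)
        for existing in self.steps:
            if existing["step"] == step and set(existing["ids"]) & set(ids):
                raise SchemaError(f"ids recorded twice for step {step!r}")
        self.steps.append({"step": step, "ids": ids, "n": len(ids), "reason": reason})

    @property
    def total(self) -> int:
        """Size of the union of all removals."""
        return len(self.all_ids())

    def all_ids(self) -> set:
        out: set = set()
        for s in self.steps:
            out |= set(s["ids"])
        return out

    def per_step_counts(self) -> dict[str, int]:
        return {s["step"]: s["n"] for s in self.steps}

    def to_dict(self) -> dict:
        return {"steps": self.steps, "total": self.total}

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, default=str))


def read_cohort(path, mandatory: list[str] = MANDATORY_COLUMNS) -> pd.DataFrame:
    """Read and validate a cohort CSV (order-insensitive header)."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"cohort file not found: {path}")
    try:
        df = pd.read_csv(path, na_values=NA_VALUES, keep_default_na=True, dtype=str,
                         skipinitialspace=True)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"cohort file is empty: {path}")
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort CSV missing mandatory columns: {missing}")
    if df.empty:
        raise SchemaError(f"cohort file has a header but no records: {path}")

    out = pd.DataFrame(index=df.index)
    out["id"] = df["id"]
    if out["id"].duplicated().any():
        dup = out["id"][out["id"].duplicated()].head(5).tolist()
        raise SchemaError(f"duplicate ids: {dup}")
    sex = df["sex"].str.strip().str.lower()
    bad_sex = ~sex.isin(SEXES) & sex.notna()
    if bad_sex.any():
        raise SchemaError(f"sex must be in {SEXES}; offending rows "
                          f"{df.index[bad_sex][:5].tolist()}")
    out["sex"] = sex
    n_malformed = 0
    for col in COHORT_COLUMNS:
        if col in ("id", "sex") or col not in df.columns:
            continue
        raw = df[col]
        num = pd.to_numeric(raw, errors="coerce")
        newly_bad = num.isna() & raw.notna()
        if newly_bad.any():
            n_malformed += int(newly_bad.sum())
            for line in (df.index[newly_bad] + 2)[:10]:
                logger.warning("malformed cell in %s, line %d: parsed as missing", col, line)
        out[col] = num
    # extra (derived or planted) numeric columns pass through
    for col in df.columns:
        if col not in out.columns:
            out[col] = pd.to_numeric(df[col], errors="coerce")
    out.attrs["n_malformed_cells"] = n_malformed

    # physical-plausibility logging; violations go to the outlier screens
    for col in ("gest_age_wk", "bw_kg", "blen_cm", "wt7_kg", "ht7_cm",
                "wt9_kg", "ht9_cm", "lm9_kg", "fm9_kg", "sbp", "dbp"):
        if col in out.columns:
            bad = (out[col] <= 0).fillna(False)
            if bad.any():
                logger.warning("%d non-positive values in %s", int(bad.sum()), col)
    both = out["sbp"].notna() & out["dbp"].notna()
    inverted = both & (out["sbp"] <= out["dbp"])
    if inverted.any():
        logger.warning("%d records with SBP <= DBP (kept for outlier screening)",
                       int(inverted.sum()))
    return out


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def run_pipeline(
    cohort,
    refs,
    out_dir=None,
    predictors: tuple[str, ...] = ALL_PREDICTORS,
    alpha_outlier: float = 0.05,
    higher_bp_centile: float = 0.95,
    seed: int | None = None,
) -> dict:
    """End-to-end analysis: z-scoring -> outlier screens -> derived
    predictors -> linear and logistic model suites -> reports.

    ``cohort`` and ``refs`` may be paths or in-memory objects.  Returns a
    bundle with the derived table, exclusion ledger, suite report and
    machine-readable results; writes JSON/TSV artifacts when ``out_dir``
    is given.
    """
    if not isinstance(refs, ReferenceSet):
        refs = read_reference_csv(refs)
    if not isinstance(cohort, pd.DataFrame):
        cohort = read_cohort(cohort)
    n_input = len(cohort)
    if n_input < 50:
        logger.warning("only %d records: confidence intervals will be wide", n_input)

    ledger = ExclusionLedger()
    derived, resvars = build_predictor_set(
        cohort, refs, predictors=predictors, alpha_outlier=alpha_outlier,
        ledger=ledger)
    report = run_suite(derived, higher_bp_centile=higher_bp_centile)

    bundle = {
        "seed": seed,
        "n_input": n_input,
        "n_excluded": ledger.total,
        "n_analysed": n_input - ledger.total,
        "derived": derived,
        "residual_variables": resvars,
        "ledger": ledger,
        "report": report,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_cohort(derived, out_dir / "derived_cohort.csv")
        ledger.to_json(out_dir / "exclusions.json")
        (out_dir / "results.json").write_text(
            json.dumps(_jsonable_report(report) | {
                "seed": seed, "n_input": n_input,
                "n_excluded": ledger.total,
                "n_analysed": n_input - ledger.total,
            }, indent=2))
        (out_dir / "tables.txt").write_text(render_suite(report))
    return bundle


def _jsonable_report(report: dict) -> dict:
    def conv(obj):
        if hasattr(obj, "strata"):  # ModelResult
            return {"outcome": obj.spec.outcome,
                    "predictors": list(obj.spec.predictors),
                    "family": obj.spec.family,
                    "strata": obj.strata}
        if isinstance(obj, dict):
            return {k: conv(v) for k, v in obj.items()}
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj
    return conv(report)
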