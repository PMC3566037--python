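"""Standardised unexplained-residual predictors and conditional velocities.

A standardised regression residual (SRR) takes the part of one variable not
linearly explained by another, within sex, and scales it to unit SD:
within each stratum the (regressor, outcome) scatter is screened for
outliers with Hadi's method, a least-squares line is fitted to the retained
records, and the residuals (observed - predicted) are divided by their SD.
By construction an SRR has stratum mean 0, SD 1, and zero sample
correlation with its regressor.

The pipeline's named predictors:

=========  ===========================================  ==========
name       outcome ~ regressor                          scale
=========  ===========================================  ==========
Wr/H       weight at 9 y  ~ height at 9 y               raw (kg, cm)
LMr/H      lean mass      ~ height at 9 y               raw
FMr/H      fat mass       ~ height at 9 y               raw
FMr/LM     fat mass       ~ lean mass                   raw
CWV        weight-at-7 SDS ~ birth-weight SDS           z-scores
CHV        height-at-7 SDS ~ birth-length SDS           z-scores
=========  ===========================================  ==========

CWV/CHV (conditional weight/height velocity) measure growth faster or
slower than predicted from birth size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DegenerateFitError, DegenerateGeometryError, SchemaError, StratumError
from .outliers import hadi_outliers
from .references import ReferenceSet, lms_zscore

__all__ = [
    "ResidualVariable",
    "standardized_residual",
    "conditional_velocity",
    "add_zscores",
    "build_predictor_set",
    "ALL_PREDICTORS",
]

logger = logging.getLogger("capload")

MIN_STRATUM_N = 10


@dataclass
class ResidualVariable:
    """An SRR column with its defining regression metadata."""

    name: str
    values: pd.Series           # aligned to the source table index; NaN if missing/flagged
    outcome: str
    regressor: str
    sex_stratified: bool
    fit_meta: dict = field(default_factory=dict)  # per stratum: slope, intercept, resid sd, n, outliers

    @property
    def n_outliers(self) -> int:
        return sum(m["n_outliers"] for m in self.fit_meta.values())


def _fit_stratum(x: np.ndarray, y: np.ndarray):
    """Least-squares line by the normal equations; returns slope, intercept."""
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx == 0.0:
        raise DegenerateFitError("regressor has zero variance in stratum")
    slope = float(((x - xm) * (y - ym)).sum()) / sxx
    return slope, ym - slope * xm


def standardized_residual(
    table: pd.DataFrame,
    outcome: str,
    regressor: str,
    stratify_by_sex: bool = True,
    alpha_outlier: float = 0.05,
    name: str | None = None,
    ddof: int = 1,
    pooled_sd: bool = False,
    ledger=None,
    screen_outliers: bool = True,
) -> ResidualVariable:
    """Compute the SRR of ``outcome`` on ``regressor``.

    Per stratum: Hadi screen on the (regressor, outcome) pairs, OLS line on
    retained records, residuals divided by the residual SD (denominator
    ``n - ddof``).  ``pooled_sd=True`` divides every stratum's residuals by
    the SD pooled across strata instead of the within-stratum SD.
    Flagged and incomplete records carry NaN.
    """
    name = name or f"{outcome}_r_{regressor}"
    for col in (outcome, regressor):
        if col not in table.columns:
            raise SchemaError(f"column {col!r} absent from table")
    if stratify_by_sex and "sex" not in table.columns:
        raise SchemaError("stratify_by_sex requires a 'sex' column")

    strata = table.groupby("sex", sort=True).groups if stratify_by_sex else {"all": table.index}
    values = pd.Series(np.nan, index=table.index, name=name)
    raw_resid: dict[str, tuple[pd.Index, np.ndarray]] = {}
    fit_meta: dict[str, dict] = {}

    for stratum, idx in strata.items():
        sub = table.loc[idx, [regressor, outcome]].dropna()
        if len(sub) == 0:
            raise StratumError(f"{name}: stratum {stratum!r} is empty")
        if len(sub) < MIN_STRATUM_N:
            raise StratumError(
                f"{name}: stratum {stratum!r} has {len(sub)} complete records "
                f"(minimum {MIN_STRATUM_N})"
            )
        n_flagged = 0
        if screen_outliers:
            ids = (table.loc[sub.index, "id"].to_numpy()
                   if "id" in table.columns else sub.index.to_numpy())
            try:
                report = hadi_outliers(sub.to_numpy(float), alpha=alpha_outlier,
                                       step=f"{name}/{stratum}", record_ids=ids)
            except DegenerateGeometryError:
                # exact collinearity of outcome and regressor: zero residual
                # variance, surfaced as a degenerate fit
                raise DegenerateFitError(
                    f"{name}: zero-variance residuals in stratum {stratum!r} "
                    f"({outcome} is an affine function of {regressor})"
                )
            n_flagged = report.n_flagged
            if ledger is not None:
                ledger.record(f"{name}/{stratum}", report.flagged_ids(),
                              reason=f"Hadi screen on ({regressor}, {outcome}) "
                                     f"at alpha={alpha_outlier}")
            sub = sub.loc[~report.flags]
        x = sub[regressor].to_numpy(float)
        y = sub[outcome].to_numpy(float)
        slope, intercept = _fit_stratum(x, y)
        resid = y - (intercept + slope * x)
        sd = float(np.sqrt((resid**2).sum() / (len(resid) - ddof)))
        if sd == 0.0 or not np.isfinite(sd):
            raise DegenerateFitError(f"{name}: zero-variance residuals in stratum {stratum!r}")
        raw_resid[stratum] = (sub.index, resid)
        fit_meta[stratum] = {
            "slope": slope,
            "intercept": intercept,
            "resid_sd": sd,
            "n": int(len(sub)),
            "n_outliers": int(n_flagged),
        }

    if pooled_sd:
        allr = np.concatenate([r for _, r in raw_resid.values()])
        pooled = float(np.sqrt((allr**2).sum() / (allr.size - ddof)))
        for stratum in fit_meta:
            fit_meta[stratum]["pooled_sd"] = pooled

    for stratum, (idx, resid) in raw_resid.items():
        sd = fit_meta[stratum]["pooled_sd"] if pooled_sd else fit_meta[stratum]["resid_sd"]
        values.loc[idx] = resid / sd

    return ResidualVariable(
        name=name,
        values=values,
        outcome=outcome,
        regressor=regressor,
        sex_stratified=stratify_by_sex,
        fit_meta=fit_meta,
    )


def conditional_velocity(
    table: pd.DataFrame,
    z_later: str,
    z_birth: str,
    stratify_by_sex: bool = True,
    alpha_outlier: float = 0.05,
    name: str | None = None,
    **kwargs,
) -> ResidualVariable:
    """Conditional growth velocity: the SRR of a later z-score on the birth
    z-score.  Positive values mean growth faster than predicted from birth
    size; uncorrelated with the birth measure by construction."""
    return standardized_residual(
        table, outcome=z_later, regressor=z_birth,
        stratify_by_sex=stratify_by_sex, alpha_outlier=alpha_outlier,
        name=name or f"cv_{z_later}", **kwargs,
    )


# ---------------------------------------------------------------------------
# full predictor set
# ---------------------------------------------------------------------------

#: derived column -> (kind, outcome, regressor)
_SRR_DEFS = {
    "wr_h": ("raw", "wt9_kg", "ht9_cm"),
    "lmr_h": ("raw", "lm9_kg", "ht9_cm"),
    "fmr_h": ("raw", "fm9_kg", "ht9_cm"),
    "fmr_lm": ("raw", "fm9_kg", "lm9_kg"),
    "cwv": ("z", "wz7", "bwz"),
    "chv": ("z", "hz7", "blz"),
}

ALL_PREDICTORS = tuple(_SRR_DEFS)

_ZSCORE_DEFS = [
    # new column, measurement, value column, age column
    ("bwz", "weight_birth", "bw_kg", "gest_age_wk"),
    ("blz", "length_birth", "blen_cm", "gest_age_wk"),
    ("wz7", "weight", "wt7_kg", "age7_mo"),
    ("hz7", "height", "ht7_cm", "age7_mo"),
    ("height_z", "height", "ht9_cm", "age9_mo"),
    ("sbp_z", "sbp", "sbp", "age9_mo"),
    ("dbp_z", "dbp", "dbp", "age9_mo"),
    ("pp_z", "pp", "pp", "age9_mo"),
]


def add_zscores(table: pd.DataFrame, refs: ReferenceSet,
                gestation_adjust_birth: bool = True) -> pd.DataFrame:
    """Add reference SDS columns (and raw pulse pressure) to the cohort.

    Birth measurements are scored at the child's gestational age when
    present; with ``gestation_adjust_birth=False``, or when gestational age
    is missing, they are scored at term (40 weeks).
    """
    out = table.copy()
    out["pp"] = out["sbp"] - out["dbp"]
    for sex, idx in out.groupby("sex", sort=True).groups.items():
        sub = out.loc[idx]
        for col, meas, val_col, age_col in _ZSCORE_DEFS:
            if val_col not in sub.columns or age_col not in sub.columns:
                continue
            ref = refs.get(meas, str(sex))
            ages = sub[age_col].to_numpy(float)
            if age_col == "gest_age_wk":
                if gestation_adjust_birth:
                    ages = np.where(np.isnan(ages), 40.0, ages)
                else:
                    ages = np.full_like(ages, 40.0)
            else:
                # a missing visit age makes the visit's z-scores missing
                bad_age = np.isnan(ages)
                ages = np.where(bad_age, ref.ages[0], ages)
            vals = sub[val_col].to_numpy(float)
            if age_col != "gest_age_wk":
                vals = np.where(bad_age, np.nan, vals)
            # non-positive raw values (e.g. PP <= 0 from inverted readings)
            # cannot be z-scored: carried as missing, not an abort
            nonpos = np.nan_to_num(vals, nan=1.0) <= 0
            if nonpos.any():
                logger.warning("%d non-positive %s values set missing for %s",
                               int(nonpos.sum()), val_col, col)
                vals = np.where(nonpos, np.nan, vals)
            out.loc[idx, col] = lms_zscore(vals, ages, str(sex), ref)
    return out


def build_predictor_set(
    table: pd.DataFrame,
    refs: ReferenceSet,
    predictors: tuple[str, ...] = ALL_PREDICTORS,
    alpha_outlier: float = 0.05,
    gestation_adjust_birth: bool = True,
    ledger=None,
    drop_outliers: bool = True,
) -> tuple[pd.DataFrame, dict[str, ResidualVariable]]:
    """Derive the full predictor set used by the model suites.

    Adds reference z-scores, per-record pulse pressure, and the requested
    SRR columns; children flagged by any Hadi screen are excluded from the
    returned table (sequentially, raw-scale body-composition residuals
    first, then the conditional velocities), mirroring a per-step exclusion
    ledger.  Returns the extended table and the ResidualVariable objects.
    """
    required = {"id", "sex", "sbp", "dbp", "ht9_cm", "age9_mo"}
    _Z_SOURCES = {
        "cwv": {"bw_kg", "gest_age_wk", "wt7_kg", "age7_mo"},
        "chv": {"blen_cm", "gest_age_wk", "ht7_cm", "age7_mo"},
    }
    for name in predictors:
        kind, outcome, regressor = _SRR_DEFS[name]
        if kind == "raw":
            required |= {outcome, regressor}
        else:
            required |= _Z_SOURCES[name]
    missing = sorted(required - set(table.columns))
    if missing:
        raise SchemaError(f"cohort table missing required columns: {missing}")

    work = add_zscores(table, refs, gestation_adjust_birth=gestation_adjust_birth)
    resvars: dict[str, ResidualVariable] = {}
    # raw-scale body-composition residuals first, then conditional velocities,
    # matching the order in which the screens are described
    order = [p for p in ("wr_h", "lmr_h", "fmr_h", "fmr_lm", "cwv", "chv") if p in predictors]
    for name in order:
        kind, outcome, regressor = _SRR_DEFS[name]
        rv = standardized_residual(
            work, outcome=outcome, regressor=regressor, stratify_by_sex=True,
            alpha_outlier=alpha_outlier, name=name, ledger=ledger,
        )
        work[name] = rv.values
        resvars[name] = rv
        if drop_outliers and rv.n_outliers:
            flagged = work[outcome].notna() & work[regressor].notna() & work[name].isna()
            work = work.loc[~flagged]
    return work, resvars
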