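"""Linear and logistic model suites for the capacity-load analysis.

Three nested linear specifications are fitted per sex for each BP outcome
(systolic, diastolic and pulse-pressure z-scores):

* load suite  — Model 1: height z; Model 2: height z + Wr/H;
  Model 3: height z + LMr/H + FMr/LM (current metabolic load).
* growth suite — Model 1: height z + LMr/H + FMr/LM;
  Model 2: birth-weight z + CWV (capacity and early load);
  Model 3: all five jointly.

The logistic suite models the odds of "higher BP" (at or above the
reference 95th centile on a single occasion — not a clinical hypertension
diagnosis) with the sexes pooled and a male-sex indicator.

Coefficients are reported with normal-based Wald 95% CIs
(beta +/- 1.959964 * SE); odds ratios exponentiate the log-odds scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import (ClassError, CollinearityError, DomainError,
                         InsufficientDataError, SchemaError, SeparationError)

__all__ = [
    "ModelSpec",
    "ModelResult",
    "fit_linear",
    "fit_logistic",
    "classify_higher_bp",
    "run_suite",
    "LINEAR_MODEL_SETS",
]

Z95 = 1.959963984540054  # normal 97.5% quantile


@dataclass(frozen=True)
class ModelSpec:
    outcome: str
    predictors: tuple[str, ...]
    family: str = "linear"                 # "linear" | "logistic"
    stratify_by_sex: bool = True
    higher_bp_centile: float | None = None  # logistic only

    def __post_init__(self):
        if not self.predictors:
            raise SchemaError("predictors must be nonempty")
        if len(set(self.predictors)) != len(self.predictors):
            raise SchemaError("duplicate predictors")
        if self.family not in ("linear", "logistic"):
            raise SchemaError(f"unknown family {self.family!r}")
        if self.family == "logistic" and self.higher_bp_centile is not None:
            if not 0 < self.higher_bp_centile < 1:
                raise DomainError("higher_bp_centile must be in (0, 1)")


@dataclass
class ModelResult:
    """Per-stratum fit results for one specification."""

    spec: ModelSpec
    strata: dict[str, dict] = field(default_factory=dict)
    # each stratum dict: n, coef: {name: {beta|or_, se, ci_low, ci_high}},
    # r2 (linear) or counts (logistic)

    def coef(self, name: str, stratum: str = "all"):
        return self.strata[stratum]["coef"][name]

    def to_frame(self, digits: int | None = None) -> pd.DataFrame:
        rows = []
        point = "or" if self.spec.family == "logistic" else "beta"
        for stratum, res in self.strata.items():
            for name, c in res["coef"].items():
                rows.append({
                    "stratum": stratum, "term": name, point: c[point],
                    "ci_low": c["ci_low"], "ci_high": c["ci_high"],
                    "se": c["se"], "n": res["n"],
                    **({"r2": res["r2"]} if "r2" in res else {}),
                })
        df = pd.DataFrame(rows)
        if digits is not None:
            for col in (point, "ci_low", "ci_high"):
                df[col] = df[col].round(digits)
            if "r2" in df:
                df["r2"] = df["r2"].round(2)
        return df


def _design(df: pd.DataFrame, predictors) -> np.ndarray:
    X = df[list(predictors)].to_numpy(float)
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        # name the columns involved in the dependency
        dep = []
        for j, name in enumerate(predictors):
            others = np.delete(Xc, j + 1, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                dep.append(name)
        raise CollinearityError(f"rank-deficient design; dependent columns: {dep or list(predictors)}")
    return Xc


def fit_linear(table: pd.DataFrame, spec: ModelSpec) -> ModelResult:
    """Ordinary least squares per stratum with Wald 95% CIs and r^2."""
    cols = [spec.outcome, *spec.predictors]
    for c in cols:
        if c not in table.columns:
            raise SchemaError(f"column {c!r} absent from table")
    strata = (table.groupby("sex", sort=True).groups if spec.stratify_by_sex
              else {"all": table.index})
    result = ModelResult(spec=spec)
    for stratum, idx in strata.items():
        sub = table.loc[idx, cols].dropna()
        n = len(sub)
        if n <= len(spec.predictors) + 2:
            raise InsufficientDataError(
                f"stratum {stratum!r}: n={n} too small for {len(spec.predictors)} predictors")
        Xc = _design(sub, spec.predictors)
        y = sub[spec.outcome].to_numpy(float)
        fit = sm.OLS(y, Xc).fit()
        coef = {}
        for j, name in enumerate(spec.predictors):
            b, se = float(fit.params[j + 1]), float(fit.bse[j + 1])
            coef[name] = {"beta": b, "se": se,
                          "ci_low": b - Z95 * se, "ci_high": b + Z95 * se}
        result.strata[str(stratum)] = {"n": n, "coef": coef, "r2": float(fit.rsquared)}
    return result


def classify_higher_bp(table: pd.DataFrame, bp_column_z: str,
                       centile: float = 0.95) -> tuple[pd.Series, dict]:
    """Dichotomise a BP z-score column at a reference centile.

    A record is "higher BP" when its SDS is at or above the standard-normal
    quantile of the centile (>= is inclusive); the threshold is the external
    reference's centile, not the sample's own percentile.
    """
    if not 0.0 < centile < 1.0:
        raise DomainError(f"centile must be in (0, 1), got {centile}")
    zcut = stats.norm.ppf(centile)
    z = table[bp_column_z]
    flag = (z >= zcut).astype(float).where(z.notna())
    counts = {
        "threshold_z": float(zcut),
        "n": int(z.notna().sum()),
        "n_high": int((flag == 1).sum()),
        "n_normal": int((flag == 0).sum()),
    }
    return flag.rename(f"{bp_column_z}_high"), counts


def fit_logistic(table: pd.DataFrame, spec: ModelSpec,
                 add_male_indicator: bool = True) -> ModelResult:
    """Maximum-likelihood logit fit, sexes pooled with a male-sex indicator.

    Reports odds ratios (exp of the log-odds coefficients) with Wald CIs
    computed on the log-odds scale and exponentiated.
    """
    cols = [spec.outcome, *spec.predictors]
    for c in cols:
        if c not in table.columns:
            raise SchemaError(f"column {c!r} absent from table")
    work = table[cols + (["sex"] if add_male_indicator else [])].dropna()
    predictors = list(spec.predictors)
    if add_male_indicator:
        work = work.assign(male_sex=(work["sex"] == "male").astype(float))
        predictors.append("male_sex")
    y = work[spec.outcome].to_numpy(float)
    classes = np.unique(y)
    if classes.size < 2:
        raise ClassError(f"outcome {spec.outcome!r} has a single class present")
    Xc = _design(work, predictors)
    try:
        fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels PerfectSeparationError and kin
        if "separation" in str(exc).lower() or "Singular" in str(exc):
            raise SeparationError(f"separation in logistic fit: {exc}")
        raise
    if not fit.mle_retvals.get("converged", True):
        raise SeparationError("logistic fit failed to converge (possible separation)")
    coef = {}
    for j, name in enumerate(predictors):
        b, se = float(fit.params[j + 1]), float(fit.bse[j + 1])
        coef[name] = {"or": float(np.exp(b)), "beta": b, "se": se,
                      "ci_low": float(np.exp(b - Z95 * se)),
                      "ci_high": float(np.exp(b + Z95 * se))}
    result = ModelResult(spec=spec)
    result.strata["pooled"] = {
        "n": int(len(work)), "coef": coef,
        "n_high": int(y.sum()), "n_normal": int(len(y) - y.sum()),
    }
    return result


# ---------------------------------------------------------------------------
# suites
# ---------------------------------------------------------------------------

LINEAR_MODEL_SETS = {
    "load": {
        "model1": ("height_z",),
        "model2": ("height_z", "wr_h"),
        "model3": ("height_z", "lmr_h", "fmr_lm"),
    },
    "growth": {
        "model1": ("height_z", "lmr_h", "fmr_lm"),
        "model2": ("bwz", "cwv"),
        "model3": ("height_z", "lmr_h", "fmr_lm", "bwz", "cwv"),
    },
    "growth_length": {
        "model1": ("height_z", "lmr_h", "fmr_lm"),
        "model2": ("blz", "chv"),
        "model3": ("height_z", "lmr_h", "fmr_lm", "blz", "chv"),
    },
}

LOGISTIC_MODEL_SET = {
    "model1": ("height_z", "lmr_h", "fmr_lm"),
    "model2": ("bwz", "cwv"),
    "model3": ("height_z", "lmr_h", "fmr_lm", "bwz", "cwv"),
}


def sex_interaction_pvalue(table: pd.DataFrame, outcome: str = "sbp_z",
                           term: str = "lmr_h",
                           covariates: tuple[str, ...] = ("height_z", "fmr_lm")) -> float:
    """Wald p-value for a sex-by-predictor interaction in the pooled sample."""
    cols = [outcome, term, *covariates, "sex"]
    work = table[cols].dropna()
    work = work.assign(male_sex=(work["sex"] == "male").astype(float))
    work["interaction"] = work["male_sex"] * work[term]
    predictors = [term, *covariates, "male_sex", "interaction"]
    Xc = _design(work, predictors)
    fit = sm.OLS(work[outcome].to_numpy(float), Xc).fit()
    j = predictors.index("interaction") + 1
    zstat = fit.params[j] / fit.bse[j]
    return float(2 * stats.norm.sf(abs(zstat)))


def run_suite(
    table: pd.DataFrame,
    outcomes: tuple[str, ...] = ("sbp_z", "dbp_z", "pp_z"),
    suites: tuple[str, ...] = ("load", "growth"),
    logistic_outcomes: tuple[str, ...] = ("sbp_z", "dbp_z"),
    higher_bp_centile: float = 0.95,
    interaction_check: bool = True,
) -> dict:
    """Fit the full linear and logistic model suites on a derived table.

    Returns a nested report: linear results per (suite, outcome, model),
    logistic results per (outcome, model) with higher-BP counts, and the
    optional pooled sex-by-LMr/H interaction p-value.
    """
    report: dict = {"linear": {}, "logistic": {}, "interaction": None}
    for suite in suites:
        report["linear"][suite] = {}
        for outcome in outcomes:
            models = {}
            for mname, preds in LINEAR_MODEL_SETS[suite].items():
                if not all(p in table.columns for p in preds):
                    continue
                spec = ModelSpec(outcome=outcome, predictors=preds, family="linear")
                models[mname] = fit_linear(table, spec)
            report["linear"][suite][outcome] = models
    for outcome in logistic_outcomes:
        flag, counts = classify_higher_bp(table, outcome, centile=higher_bp_centile)
        work = table.assign(**{flag.name: flag})
        models = {"counts": counts}
        for mname, preds in LOGISTIC_MODEL_SET.items():
            if not all(p in table.columns for p in preds):
                continue
            spec = ModelSpec(outcome=flag.name, predictors=preds, family="logistic",
                             higher_bp_centile=higher_bp_centile)
            models[mname] = fit_logistic(work, spec)
        report["logistic"][outcome] = models
    if interaction_check and all(c in table.columns for c in ("lmr_h", "height_z", "fmr_lm")):
        report["interaction"] = {
            "term": "sex * lmr_h",
            "p_value": sex_interaction_pvalue(table),
        }
    return report


def render_suite(report: dict, digits: int = 2) -> str:
    """Human-readable markdown tables mirroring the published layout."""
    lines = []
    for suite, by_outcome in report["linear"].items():
        for outcome, models in by_outcome.items():
            lines.append(f"\n## Linear ({suite} suite) — {outcome}\n")
            frames = []
            for mname, res in models.items():
                f = res.to_frame(digits=digits)
                f.insert(0, "model", mname)
                frames.append(f)
            if frames:
                lines.append(pd.concat(frames).to_string(index=False))
    for outcome, models in report["logistic"].items():
        lines.append(f"\n## Logistic (higher BP) — {outcome}\n")
        counts = models.get("counts", {})
        if counts:
            lines.append(f"records >= cutoff: {counts['n_high']} of {counts['n']}\n")
        frames = []
        for mname, res in models.items():
            if mname == "counts":
                continue
            f = res.to_frame(digits=digits)
            f.insert(0, "model", mname)
            frames.append(f)
        if frames:
            lines.append(pd.concat(frames).to_string(index=False))
    if report.get("interaction"):
        inter = report["interaction"]
        lines.append(f"\nSex interaction check ({inter['term']}): p = {inter['p_value']:.2f}")
    return "\n".join(lines)
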