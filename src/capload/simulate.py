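"""Structural synthetic-cohort generator and its analytic oracle.

The generator draws children from an explicit capacity-load DAG.  Per sex,
with all structural variables on the z/SRR scale (unit variance):

    BWz  ~ N(0, 1)                               metabolic capacity
    CWV  ~ N(0, 1), independent of BWz           postnatal growth
    Hz   = b_H*BWz + a_H*CWV + e_H               height (load)
    LMr  = b_L*BWz + a_L*CWV + e_L               relative lean mass (load)
    FMr  = T(g_F*CWV + e_F)                      relative fat mass (load;
                                                 no capacity loading)
    BPz  = beta_H*Hz + beta_L*LMr + beta_F*FMr + beta_C*BWz
           + beta_CWV_direct*CWV + e_BP

Noise SDs are solved so every structural variable has unit variance.
Relative fat mass is right-skewed and bounded below, as childhood adiposity
is: T is a standardised lognormal transform, T(G) =
(exp(sigma*G) - exp(sigma^2/2)) / sqrt(exp(sigma^2)(exp(sigma^2)-1)) for
unit-Gaussian G, which has mean 0 and variance 1, and the Gaussian loading
g_F is solved so the covariance loading cov(FMr, CWV) equals the configured
a_F exactly (cov(exp(sigma*G), CWV) = sigma*exp(sigma^2/2)*cov(G, CWV)), so
the DAG covariance algebra is unchanged by the skew.
Systolic and diastolic BP get separate coefficient vectors whose residuals
are correlated so the pulse-pressure SD matches the calibration table.

Raw-scale columns are back-constructed by inverting the pipeline's own
derived-variable definitions (z-scores inverted through the reference
tables; lean mass = its height regression plus residual*SD; fat mass
likewise on lean mass; weight = lean + fat + a constant residual-mass
offset), so that running the full pipeline on a synthetic cohort recovers
the planted structure.  Gross outliers and item-level missingness are
injected last.

``implied_coefficients`` is the closed-form oracle: for the jointly
specified covariance structure the expected large-n OLS coefficients of any
predictor subset follow from the DAG's covariance algebra.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import ANALYTIC_N, SEXES, TABLE1_MOMENTS, implied_bp_correlation
from .exceptions import CalibrationError, SchemaError
from .references import ReferenceSet, synthetic_reference_set

__all__ = [
    "StructuralParams",
    "GeneratorConfig",
    "generate_cohort",
    "implied_coefficients",
    "calibrate_default_config",
    "logistic_plant_config",
]

#: order of structural variables in covariance computations
STRUCTURAL_VARS = ("height_z", "lmr_h", "fmr_lm", "bwz", "cwv")


@dataclass
class StructuralParams:
    """Per-sex loadings and BP coefficients of the capacity-load DAG."""

    a_h: float          # CWV -> height z
    a_l: float          # CWV -> LMr/H
    a_f: float          # CWV -> FMr/LM
    b_h: float          # BWz -> height z
    b_l: float          # BWz -> LMr/H
    beta_h: float       # height z -> systolic BP z
    beta_l: float       # LMr/H -> systolic BP z
    beta_f: float       # FMr/LM -> systolic BP z
    beta_c: float       # BWz -> systolic BP z (direct capacity effect)
    beta_cwv_direct: float = 0.0   # unmediated CWV -> BP path (0 = full mediation)
    # diastolic coefficient vector (same load/capacity structure)
    beta_h_dia: float = 0.12
    beta_l_dia: float = 0.02
    beta_f_dia: float = 0.13
    beta_c_dia: float = -0.04
    beta_cwv_direct_dia: float = 0.0

    def betas(self, outcome: str = "systolic") -> np.ndarray:
        """(beta_H, beta_L, beta_F, beta_C, beta_CWV_direct) for an outcome."""
        if outcome == "systolic":
            return np.array([self.beta_h, self.beta_l, self.beta_f,
                             self.beta_c, self.beta_cwv_direct])
        if outcome == "diastolic":
            return np.array([self.beta_h_dia, self.beta_l_dia, self.beta_f_dia,
                             self.beta_c_dia, self.beta_cwv_direct_dia])
        raise SchemaError(f"unknown outcome {outcome!r}")

    def noise_sds(self) -> dict[str, float]:
        """Residual SDs making each structural variable unit-variance."""
        out = {}
        for name, expl in (
            ("height_z", self.b_h**2 + self.a_h**2),
            ("lmr_h", self.b_l**2 + self.a_l**2),
            ("fmr_lm", self.a_f**2),
        ):
            if expl >= 1.0:
                raise CalibrationError(
                    f"loadings give {name} explained variance {expl:.3f} >= 1; "
                    "unit-variance decomposition infeasible")
            out[name] = float(np.sqrt(1.0 - expl))
        return out

    def structural_cov(self) -> np.ndarray:
        """Exact covariance of STRUCTURAL_VARS (all unit variance)."""
        # loading matrix onto independent factors (bwz, cwv, e_h, e_l, e_f)
        sds = self.noise_sds()
        lam = np.array([
            # bwz      cwv      e_h               e_l             e_f
            [self.b_h, self.a_h, sds["height_z"], 0.0, 0.0],   # height_z
            [self.b_l, self.a_l, 0.0, sds["lmr_h"], 0.0],       # lmr_h
            [0.0, self.a_f, 0.0, 0.0, sds["fmr_lm"]],           # fmr_lm
            [1.0, 0.0, 0.0, 0.0, 0.0],                          # bwz
            [0.0, 1.0, 0.0, 0.0, 0.0],                          # cwv
        ])
        return lam @ lam.T

    def bp_variance_explained(self, outcome: str = "systolic") -> float:
        beta = self.betas(outcome)
        return float(beta @ self.structural_cov() @ beta)

    def bp_noise_sd(self, outcome: str = "systolic") -> float:
        expl = self.bp_variance_explained(outcome)
        if expl >= 1.0:
            raise CalibrationError(
                f"{outcome} BP explained variance {expl:.3f} >= 1; reduce coefficients")
        return float(np.sqrt(1.0 - expl))


@dataclass
class GeneratorConfig:
    """Everything the generator needs; defaults come from the calibration."""

    structural: dict[str, StructuralParams]
    n: dict[str, int] = field(default_factory=lambda: dict(ANALYTIC_N))
    tracking_r: float = 0.5          # corr(BWz, weight-at-7 z)
    length_weight_r: float = 0.75    # corr(BWz, birth-length z)
    height_tracking_r: float = 0.6   # corr(birth-length z, height-at-7 z)
    chv_cwv_r: float = 0.6           # corr(CWV, CHV truth)
    lm_height_corr: float = 0.7      # raw lean mass vs height at 9 y
    fm_lm_corr: float = 0.6          # raw fat mass vs lean mass at 9 y
    fm_skew_sigma: float = 0.35      # lognormal shape of relative fat mass
    bp_noise_corr: dict[str, float] = field(default_factory=dict)  # per sex
    outlier_rate: float = 0.003
    outlier_sds: tuple[float, float] = (8.0, 15.0)
    missingness: dict[str, float] = field(default_factory=lambda: {
        "bw_kg": 0.011, "blen_cm": 0.20, "wt7_kg": 0.114, "ht7_cm": 0.113,
    })
    moments: dict = field(default_factory=lambda: TABLE1_MOMENTS)
    seed: int | None = None
    # logistic outcome plants: name -> {"intercept": a, "loadings": {var: log-odds}}
    logistic_outcomes: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self):
        for sex, n in self.n.items():
            if n < 50:
                raise CalibrationError(f"n for {sex} must be >= 50, got {n}")
        for r in (self.tracking_r, self.length_weight_r, self.height_tracking_r,
                  self.chv_cwv_r):
            if not abs(r) < 1.0:
                raise CalibrationError(f"correlation {r} must have |r| < 1")
        for sex, sp in self.structural.items():
            sp.noise_sds()
            sp.bp_noise_sd("systolic")
            sp.bp_noise_sd("diastolic")
            mu, sd = _lognormal_std_consts(self.fm_skew_sigma)
            if not abs(sp.a_f * sd / (self.fm_skew_sigma * mu)) < 1.0:
                raise CalibrationError(
                    f"{sex}: fat loading a_f={sp.a_f} infeasible for "
                    f"skew sigma={self.fm_skew_sigma}")

    def replace(self, **kw) -> "GeneratorConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


# ---------------------------------------------------------------------------
# analytic oracle
# ---------------------------------------------------------------------------

_MODEL_PREDICTORS = {
    "marginal_load": ("height_z", "lmr_h", "fmr_lm"),
    "marginal_growth": ("bwz", "cwv"),
    "joint_full": ("height_z", "lmr_h", "fmr_lm", "bwz", "cwv"),
}


def implied_coefficients(config: GeneratorConfig, model: str, sex: str = "male",
                         outcome: str = "systolic") -> dict[str, float]:
    """Expected large-n OLS coefficients for a model on generated data.

    For jointly specified covariances the population regression coefficients
    of BP z on a predictor subset solve Sigma_pp b = Sigma_py, with
    Sigma_py = Sigma_px beta over the full structural set.
    """
    if model not in _MODEL_PREDICTORS:
        raise SchemaError(f"model must be one of {sorted(_MODEL_PREDICTORS)}")
    sp = config.structural[sex]
    sigma = sp.structural_cov()
    beta = sp.betas(outcome)
    predictors = _MODEL_PREDICTORS[model]
    idx = [STRUCTURAL_VARS.index(p) for p in predictors]
    sigma_pp = sigma[np.ix_(idx, idx)]
    sigma_py = sigma[idx, :] @ beta
    b = np.linalg.solve(sigma_pp, sigma_py)
    return dict(zip(predictors, map(float, b)))


# ---------------------------------------------------------------------------
# default calibration
# ---------------------------------------------------------------------------

#: published systolic calibration targets, SDS per SRR / SDS per SDS
ABSTRACT_TARGETS = {
    "male": {"marginal_cwv": 0.40, "marginal_bwz": 0.00, "conditional_bwz": -0.10},
    "female": {"marginal_cwv": 0.44, "marginal_bwz": 0.03, "conditional_bwz": -0.09},
}

# fixed structural choices of the default calibration (see docs/methods.md)
_FIXED = {"beta_h": 0.30, "beta_l": 0.20, "beta_f": 0.25,
          "a_l": 0.55, "a_f": 0.50, "b_l": 0.20}


def calibrate_default_config(targets: dict | None = None,
                             n: dict[str, int] | None = None,
                             seed: int | None = None) -> GeneratorConfig:
    """Solve the default structural parameters from the headline targets.

    With the load coefficients (beta_H, beta_L, beta_F) and the lean/fat
    loadings fixed, the remaining parameters follow exactly:

        beta_C = conditional_bwz
        a_H = (marginal_cwv - beta_L*a_L - beta_F*a_F) / beta_H
        b_H = (marginal_bwz - beta_C - beta_L*b_L) / beta_H

    so ``implied_coefficients`` reproduces the targets to machine precision.
    The systolic-diastolic residual correlation is solved so the implied
    corr(SBPz, DBPz) matches the value the calibration SDs give through
    var(PP) = var(SBP) + var(DBP) - 2 cov.
    """
    targets = targets or ABSTRACT_TARGETS
    structural = {}
    for sex in SEXES:
        t = targets[sex]
        beta_c = t["conditional_bwz"]
        a_h = (t["marginal_cwv"] - _FIXED["beta_l"] * _FIXED["a_l"]
               - _FIXED["beta_f"] * _FIXED["a_f"]) / _FIXED["beta_h"]
        b_h = (t["marginal_bwz"] - beta_c - _FIXED["beta_l"] * _FIXED["b_l"]) / _FIXED["beta_h"]
        structural[sex] = StructuralParams(
            a_h=a_h, a_l=_FIXED["a_l"], a_f=_FIXED["a_f"],
            b_h=b_h, b_l=_FIXED["b_l"],
            beta_h=_FIXED["beta_h"], beta_l=_FIXED["beta_l"],
            beta_f=_FIXED["beta_f"], beta_c=beta_c,
        )
    cfg = GeneratorConfig(structural=structural, seed=seed)
    if n is not None:
        cfg = cfg.replace(n=dict(n))
    # residual correlation between the two BP equations
    bp_corr = {}
    for sex in SEXES:
        sp = cfg.structural[sex]
        target = implied_bp_correlation(sex)
        shared = float(sp.betas("systolic") @ sp.structural_cov() @ sp.betas("diastolic"))
        rho = (target - shared) / (sp.bp_noise_sd("systolic") * sp.bp_noise_sd("diastolic"))
        if not abs(rho) < 1.0:
            raise CalibrationError(
                f"{sex}: implied BP residual correlation {rho:.3f} infeasible")
        bp_corr[sex] = rho
    return cfg.replace(bp_noise_corr=bp_corr)


def logistic_plant_config(loadings: dict[str, float], intercept: float = -3.0,
                          male_log_odds: float = float(np.log(0.88)),
                          outcome_name: str = "high_bp",
                          **kwargs) -> GeneratorConfig:
    """Default config plus a binary outcome drawn from a planted logistic
    model on the structural variables (loadings on the log-odds scale)."""
    cfg = calibrate_default_config(**kwargs)
    return cfg.replace(logistic_outcomes={
        outcome_name: {"intercept": intercept, "loadings": dict(loadings),
                       "male_log_odds": male_log_odds},
    })


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def _lognormal_std_consts(sigma: float) -> tuple[float, float]:
    """(mean, sd) of exp(sigma*Z) for standard-normal Z."""
    mu = float(np.exp(sigma**2 / 2))
    sd = float(np.sqrt(np.exp(sigma**2) * (np.exp(sigma**2) - 1.0)))
    return mu, sd


def _anchored_coeffs(u: np.ndarray, w: np.ndarray, sd_target: float,
                     rho: float) -> tuple[float, float]:
    """Slope on u and scale on w so that x = g*u + s*w has SD ``sd_target``
    and corr(x, u) = ``rho``, given sample moments of (u, w)."""
    v = float(u.var())
    sd_w = float(w.std())
    c = float(np.cov(u, w)[0, 1]) / sd_w   # cov(u, standardized w)
    s = sd_target * np.sqrt((1.0 - rho**2) / (1.0 - c**2 / v))
    g = (rho * sd_target * np.sqrt(v) - s * c) / v
    return float(g), float(s / sd_w)


def _skewed_fmr(rng, n, cwv, a_f, sigma):
    """Standardised lognormal relative-fat draw with cov(FMr, CWV) = a_f.

    FMr = (exp(sigma*G) - mu)/sd for unit-Gaussian G = g*CWV + sqrt(1-g^2)*Z,
    where g is solved from a_f = g * sigma * mu / sd.
    """
    mu, sd = _lognormal_std_consts(sigma)
    g = a_f * sd / (sigma * mu)
    if not abs(g) < 1.0:
        raise CalibrationError(
            f"fat loading a_f={a_f} infeasible for skew sigma={sigma} "
            f"(Gaussian loading {g:.3f} must have |g| < 1)")
    G = g * cwv + np.sqrt(1.0 - g**2) * rng.standard_normal(n)
    return (np.exp(sigma * G) - mu) / sd


def generate_cohort(config: GeneratorConfig, seed: int | None = None,
                    refs: ReferenceSet | None = None,
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a synthetic cohort; returns (cohort, truth) tables.

    The cohort table carries only what a study would measure (the documented
    raw column dictionary plus any planted binary outcomes); the truth table
    carries the hidden structural variables, planted-outlier flags and a
    config echo in ``truth.attrs``.  Identical seed and config give a
    bit-identical cohort.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    refs = refs or synthetic_reference_set(config.moments)

    cohort_frames, truth_frames = [], []
    next_id = 1
    for sex in SEXES:
        n = config.n[sex]
        sp = config.structural[sex]
        m = config.moments[sex]
        sds = sp.noise_sds()

        bwz = rng.standard_normal(n)
        cwv = rng.standard_normal(n)
        e_h = rng.standard_normal(n) * sds["height_z"]
        e_l = rng.standard_normal(n) * sds["lmr_h"]
        height_z = sp.b_h * bwz + sp.a_h * cwv + e_h
        lmr = sp.b_l * bwz + sp.a_l * cwv + e_l
        fmr = _skewed_fmr(rng, n, cwv, sp.a_f, config.fm_skew_sigma)

        rho = config.bp_noise_corr.get(sex, 0.0)
        z1 = rng.standard_normal(n)
        z2 = rho * z1 + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
        struct = np.column_stack([height_z, lmr, fmr, bwz, cwv])
        sbp_z = struct @ sp.betas("systolic") + sp.bp_noise_sd("systolic") * z1
        dbp_z = struct @ sp.betas("diastolic") + sp.bp_noise_sd("diastolic") * z2

        # growth-history z-scores
        r = config.tracking_r
        wz7 = r * bwz + np.sqrt(1.0 - r**2) * cwv
        rl = config.length_weight_r
        blz = rl * bwz + np.sqrt(1.0 - rl**2) * rng.standard_normal(n)
        rc = config.chv_cwv_r
        chv = rc * cwv + np.sqrt(1.0 - rc**2) * rng.standard_normal(n)
        rh = config.height_tracking_r
        hz7 = rh * blz + np.sqrt(1.0 - rh**2) * chv

        # ages, clipped to the reference grids
        ga = np.clip(rng.normal(*m["gest_age_wk"], size=n), 28.0, 44.0)
        age7 = rng.normal(*m["age7_mo"], size=n)
        age9 = rng.normal(*m["age9_mo"], size=n)

        # raw back-construction through the reference tables
        bw = refs.get("weight_birth", sex).value(bwz, ga)
        blen = refs.get("length_birth", sex).value(blz, ga)
        wt7 = refs.get("weight", sex).value(wz7, age7)
        ht7 = refs.get("height", sex).value(hz7, age7)
        ht9 = refs.get("height", sex).value(height_z, age9)
        sbp = refs.get("sbp", sex).value(sbp_z, age9)
        dbp = refs.get("dbp", sex).value(dbp_z, age9)

        # body composition: invert the SRR definitions against raw height.
        # The slope/residual-scale pair (g, s) in x = mean + g*u + s*w is
        # solved from the sample moments of the conditioning variable u and
        # the planted residual w (which are correlated through the DAG), so
        # that sd(x) and corr(x, u) hit their calibration targets:
        #   s = sd_x * sqrt((1 - rho^2) / (1 - corr(u, w)^2))
        #   g = (rho * sd_x * sd_u - s * cov(u, w)) / var(u)
        mean_lm, sd_lm = m["lm9_kg"]
        g_lm, s_lm = _anchored_coeffs(ht9, lmr, sd_lm, config.lm_height_corr)
        lm = mean_lm + g_lm * (ht9 - ht9.mean()) + s_lm * (lmr - lmr.mean())
        mean_fm, sd_fm = m["fm9_kg"]
        g_fm, s_fm = _anchored_coeffs(lm, fmr, sd_fm, config.fm_lm_corr)
        fm = mean_fm + g_fm * (lm - lm.mean()) + s_fm * (fmr - fmr.mean())
        n_clipped = int((fm < 0.2).sum())
        fm = np.maximum(fm, 0.2)
        # weight = lean + fat + residual mass (bone/organs), closing Table 1
        offset = m["wt9_kg"][0] - mean_lm - mean_fm
        wt9 = lm + fm + offset

        cohort = pd.DataFrame({
            "id": np.arange(next_id, next_id + n),
            "sex": sex,
            "gest_age_wk": ga, "bw_kg": bw, "blen_cm": blen,
            "wt7_kg": wt7, "ht7_cm": ht7, "age7_mo": age7,
            "wt9_kg": wt9, "ht9_cm": ht9, "lm9_kg": lm, "fm9_kg": fm,
            "age9_mo": age9, "sbp": sbp, "dbp": dbp,
        })

        # planted logistic outcomes
        for name, plant in config.logistic_outcomes.items():
            eta = np.full(n, float(plant.get("intercept", -3.0)))
            truth_map = {"height_z": height_z, "lmr_h": lmr, "fmr_lm": fmr,
                         "bwz": bwz, "cwv": cwv}
            for var, lo in plant.get("loadings", {}).items():
                eta += lo * truth_map[var]
            if sex == "male":
                eta += float(plant.get("male_log_odds", 0.0))
            p = 1.0 / (1.0 + np.exp(-eta))
            cohort[name] = (rng.random(n) < p).astype(float)

        # gross outliers: displace one screened pair 8-15 robust SDs
        outlier_flag = np.zeros(n, dtype=bool)
        n_out = rng.binomial(n, config.outlier_rate)
        if n_out:
            rows = rng.choice(n, size=n_out, replace=False)
            pairs = [("ht9_cm", "lm9_kg"), ("lm9_kg", "fm9_kg"),
                     ("ht9_cm", "wt9_kg"), ("bw_kg", "wt7_kg")]
            lo, hi = config.outlier_sds
            clean_sd = {c: float(cohort[c].std())
                        for c in {c for pair in pairs for c in pair}}
            for row in rows:
                ca, cb = pairs[rng.integers(len(pairs))]
                radius = rng.uniform(lo, hi)
                theta = rng.uniform(0.0, 2.0 * np.pi)
                for col, delta in ((ca, radius * np.cos(theta)),
                                   (cb, radius * np.sin(theta))):
                    val = cohort.at[row, col] + delta * clean_sd[col]
                    cohort.at[row, col] = max(val, 0.05)
            outlier_flag[rows] = True

        # item-level missingness (MCAR)
        for col, rate in config.missingness.items():
            if rate > 0 and col in cohort.columns:
                mask = rng.random(n) < rate
                cohort.loc[cohort.index[mask], col] = np.nan

        truth = pd.DataFrame({
            "id": cohort["id"], "sex": sex,
            "bwz": bwz, "cwv": cwv, "height_z": height_z,
            "lmr_h": lmr, "fmr_lm": fmr, "chv": chv, "blz": blz, "wz7": wz7,
            "sbp_z": sbp_z, "dbp_z": dbp_z,
            "planted_outlier": outlier_flag,
        })
        truth.attrs["fm_clipped"] = n_clipped
        cohort_frames.append(cohort)
        truth_frames.append(truth)
        next_id += n

    cohort = pd.concat(cohort_frames, ignore_index=True)
    truth = pd.concat(truth_frames, ignore_index=True)
    fm_clipped = sum(t.attrs.get("fm_clipped", 0) for t in truth_frames)
    for df in (cohort, truth):
        df.attrs["seed"] = seed
        df.attrs["fm_clipped"] = fm_clipped
    truth.attrs["config"] = config.to_dict()
    return cohort, truth
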