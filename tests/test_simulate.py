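"""Structural cohort generator and its closed-form coefficient oracle."""

import dataclasses

import numpy as np
import pytest

import capload as cl
from capload.calibration import TABLE1_MOMENTS, implied_bp_correlation
from capload.exceptions import CalibrationError
from capload.simulate import (ABSTRACT_TARGETS, StructuralParams,
                              implied_coefficients)


def null_structural():
    return StructuralParams(a_h=0.5, a_l=0.5, a_f=0.4, b_h=0.3, b_l=0.2,
                            beta_h=0.0, beta_l=0.0, beta_f=0.0, beta_c=0.0,
                            beta_h_dia=0.0, beta_l_dia=0.0, beta_f_dia=0.0,
                            beta_c_dia=0.0)


def test_determinism_bit_identical():
    cfg = cl.calibrate_default_config(n={"male": 300, "female": 300})
    a, ta = cl.generate_cohort(cfg, seed=5)
    b, tb = cl.generate_cohort(cfg, seed=5)
    assert a.equals(b) and ta.equals(tb)
    c, _ = cl.generate_cohort(cfg, seed=6)
    assert not a.equals(c)


def test_zero_loading_config_independence():
    sp = dataclasses.replace(null_structural(), a_h=0.0, a_l=0.0, a_f=0.0,
                             b_h=0.0, b_l=0.0)
    cfg = cl.GeneratorConfig(structural={"male": sp, "female": sp},
                             n={"male": 2000, "female": 2000},
                             outlier_rate=0.0, missingness={})
    _, truth = cl.generate_cohort(cfg, seed=2)
    t = truth[truth.sex == "male"]
    cols = ["bwz", "cwv", "height_z", "lmr_h", "fmr_lm"]
    corr = t[cols].corr().to_numpy()
    off = corr[~np.eye(len(cols), dtype=bool)]
    assert np.abs(off).max() < 3 / np.sqrt(len(t))


def test_default_config_correlation_pattern(default_config):
    """Capacity correlates with height and lean load but not relative fat;
    postnatal growth correlates positively with all three."""
    _, truth = cl.generate_cohort(default_config, seed=3)
    for sex in ("male", "female"):
        t = truth[truth.sex == sex]
        n = len(t)
        assert abs(np.corrcoef(t.bwz, t.fmr_lm)[0, 1]) < 3 / np.sqrt(n)
        for load in ("height_z", "lmr_h", "fmr_lm"):
            assert np.corrcoef(t.cwv, t[load])[0, 1] > 0.2
        assert np.corrcoef(t.bwz, t.height_z)[0, 1] > 0.1
        assert abs(np.corrcoef(t.bwz, t.cwv)[0, 1]) < 3 / np.sqrt(n)


def test_unit_variance_of_structural_variables(default_config):
    _, truth = cl.generate_cohort(default_config, seed=4)
    for sex in ("male", "female"):
        t = truth[truth.sex == sex]
        for col in ("bwz", "cwv", "height_z", "lmr_h", "fmr_lm"):
            assert abs(t[col].var(ddof=1) - 1.0) < 5 / np.sqrt(len(t)), col


def test_raw_scale_calibration(default_config):
    """Raw sample moments land on the calibration anchors."""
    cohort, _ = cl.generate_cohort(default_config, seed=6)
    for sex in ("male", "female"):
        sub = cohort[cohort.sex == sex]
        n = len(sub)
        for col in ("sbp", "dbp", "bw_kg", "ht9_cm", "lm9_kg", "fm9_kg"):
            mean, sd = TABLE1_MOMENTS[sex][col]
            assert abs(sub[col].mean() - mean) < 4 * sd / np.sqrt(n), (sex, col)
        # pulse-pressure SD matches through the planted BP residual correlation
        pp_sd = (sub.sbp - sub.dbp).std()
        assert pp_sd == pytest.approx(TABLE1_MOMENTS[sex]["pp"][1], rel=0.1)


def test_implied_marginal_cancellation_identity():
    """beta_C = -(beta_H b_H + beta_L b_L) makes the marginal capacity
    coefficient exactly zero (the null marginal effect by cancellation)."""
    sp = StructuralParams(a_h=0.5, a_l=0.4, a_f=0.3, b_h=0.25, b_l=0.15,
                          beta_h=0.3, beta_l=0.2, beta_f=0.25,
                          beta_c=-(0.3 * 0.25 + 0.2 * 0.15))
    cfg = cl.GeneratorConfig(structural={"male": sp, "female": sp},
                             n={"male": 100, "female": 100})
    implied = implied_coefficients(cfg, "marginal_growth", "male")
    assert implied["bwz"] == pytest.approx(0.0, abs=1e-12)


def test_full_mediation_zero_joint_cwv():
    cfg = cl.calibrate_default_config()
    implied = implied_coefficients(cfg, "joint_full", "male")
    assert implied["cwv"] == pytest.approx(0.0, abs=1e-12)


def test_calibration_roundtrip_reproduces_targets():
    cfg = cl.calibrate_default_config()
    for sex in ("male", "female"):
        t = ABSTRACT_TARGETS[sex]
        growth = implied_coefficients(cfg, "marginal_growth", sex)
        joint = implied_coefficients(cfg, "joint_full", sex)
        assert growth["cwv"] == pytest.approx(t["marginal_cwv"], abs=1e-9)
        assert growth["bwz"] == pytest.approx(t["marginal_bwz"], abs=1e-9)
        assert joint["bwz"] == pytest.approx(t["conditional_bwz"], abs=1e-9)


def test_bp_residual_correlation_solved_from_calibration():
    cfg = cl.calibrate_default_config()
    _, truth = cl.generate_cohort(cfg.replace(n={"male": 4000, "female": 4000}),
                                  seed=9)
    for sex in ("male", "female"):
        t = truth[truth.sex == sex]
        r = np.corrcoef(t.sbp_z, t.dbp_z)[0, 1]
        assert r == pytest.approx(implied_bp_correlation(sex), abs=0.05)


def test_infeasible_configs_raise():
    with pytest.raises(CalibrationError):
        StructuralParams(a_h=0.9, a_l=0.5, a_f=0.4, b_h=0.5, b_l=0.2,
                         beta_h=0.3, beta_l=0.2, beta_f=0.25,
                         beta_c=-0.1).noise_sds()
    sp = null_structural()
    with pytest.raises(CalibrationError):
        cl.GeneratorConfig(structural={"male": sp, "female": sp},
                           n={"male": 10, "female": 10})
    with pytest.raises(CalibrationError):
        cl.GeneratorConfig(structural={"male": sp, "female": sp},
                           tracking_r=1.0)


def test_weight_closes_over_composition(default_config):
    cohort, _ = cl.generate_cohort(default_config, seed=10)
    resid = cohort.wt9_kg - cohort.lm9_kg - cohort.fm9_kg
    # residual mass offset is constant within sex (bone/organs)
    for sex in ("male", "female"):
        sub = resid[(cohort.sex == sex) & cohort.wt9_kg.notna()
                    & cohort.lm9_kg.notna() & cohort.fm9_kg.notna()]
        # planted outliers displace single columns; the bulk is constant
        assert (np.abs(sub - sub.median()) < 1e-9).mean() > 0.99


def test_planted_logistic_outcome_prevalence():
    cfg = cl.logistic_plant_config({"cwv": float(np.log(1.5))}, intercept=-3.0,
                                   n={"male": 2000, "female": 2000})
    cohort, _ = cl.generate_cohort(cfg, seed=12)
    rate = cohort["high_bp"].mean()
    assert 0.02 < rate < 0.10
    assert set(cohort["high_bp"].unique()) <= {0.0, 1.0}


def test_seed_recorded_and_missingness_rates(default_config):
    cohort, truth = cl.generate_cohort(default_config, seed=13)
    assert cohort.attrs["seed"] == 13
    assert truth.attrs["config"]["tracking_r"] == default_config.tracking_r
    frac = cohort["blen_cm"].isna().mean()
    assert frac == pytest.approx(0.20, abs=0.03)
    assert cohort["sbp"].notna().all()
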