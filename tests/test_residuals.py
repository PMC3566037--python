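"""Standardised unexplained residuals and conditional velocities."""

import numpy as np
import pandas as pd
import pytest

from capload.exceptions import DegenerateFitError, SchemaError, StratumError
from capload.residuals import (build_predictor_set, conditional_velocity,
                               standardized_residual)

# twelve-record hand table; expected values frozen from an explicit
# normal-equations evaluation (sums of squares and cross-products)
HAND_X = [1.0, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12]
HAND_Y = [2.1, 3.9, 6.2, 7.8, 10.1, 12.2, 13.8, 16.1, 18.0, 19.9, 22.2, 24.1]
HAND_SLOPE = 2.004195804196
HAND_INTERCEPT = 0.006060606061
HAND_RESID_SD = 0.148981141012
HAND_SRR = [0.6023822152, -0.768232903, 1.2172814634, -1.4957854486,
            0.4897289178, 1.1327914904, -1.5802754217, 0.4052389448,
            -0.2941502765, -0.9935394978, 0.9919748686, 0.2925856474]


def hand_table():
    return pd.DataFrame({"id": range(12), "x": HAND_X, "y": HAND_Y})


def test_hand_table_matches_normal_equations_oracle():
    rv = standardized_residual(hand_table(), "y", "x", stratify_by_sex=False)
    meta = rv.fit_meta["all"]
    assert meta["slope"] == pytest.approx(HAND_SLOPE, abs=1e-9)
    assert meta["intercept"] == pytest.approx(HAND_INTERCEPT, abs=1e-9)
    assert meta["resid_sd"] == pytest.approx(HAND_RESID_SD, abs=1e-9)
    assert meta["n_outliers"] == 0
    np.testing.assert_allclose(rv.values.to_numpy(), HAND_SRR, atol=1e-9)


def random_table(n=400, seed=0, slope_by_sex=(0.5, 0.5)):
    rng = np.random.default_rng(seed)
    sex = np.repeat(["male", "female"], n // 2)
    x = rng.normal(10, 2, n)
    slopes = np.where(sex == "male", slope_by_sex[0], slope_by_sex[1])
    y = 1.0 + slopes * x + rng.normal(0, 0.8, n)
    return pd.DataFrame({"id": range(n), "sex": sex, "x": x, "y": y})


def test_srr_invariants_per_stratum():
    """Within each sex stratum the SRR has mean 0, SD 1, and zero sample
    correlation with its regressor (to 1e-9)."""
    df = random_table()
    rv = standardized_residual(df, "y", "x")
    for sex in ("male", "female"):
        vals = rv.values[df.sex == sex].dropna()
        x = df.loc[vals.index, "x"]
        assert abs(vals.mean()) < 1e-9
        assert abs(vals.std(ddof=1) - 1.0) < 1e-9
        assert abs(np.corrcoef(vals, x)[0, 1]) < 1e-9


def test_degenerate_collinear_outcome():
    df = hand_table().assign(y=lambda d: 3 * d.x + 1)
    with pytest.raises(DegenerateFitError):
        standardized_residual(df, "y", "x", stratify_by_sex=False)


def test_zero_regressor_variance():
    df = hand_table().assign(x=5.0)
    with pytest.raises(DegenerateFitError):
        standardized_residual(df, "y", "x", stratify_by_sex=False,
                              screen_outliers=False)


def test_small_or_empty_stratum_errors():
    df = random_table(n=30)
    df = df[df.sex == "male"].iloc[:8].assign(sex="male")
    with pytest.raises(StratumError):
        standardized_residual(df, "y", "x")


def test_independent_outcome_srr_is_standardised_outcome():
    rng = np.random.default_rng(7)
    df = pd.DataFrame({"id": range(300), "x": rng.normal(size=300),
                       "y": rng.normal(size=300)})
    rv = standardized_residual(df, "y", "x", stratify_by_sex=False)
    meta = rv.fit_meta["all"]
    assert abs(meta["slope"]) < 0.15
    x = df.loc[rv.values.dropna().index, "x"]
    assert abs(np.corrcoef(rv.values.dropna(), x)[0, 1]) < 1e-9


def test_pooled_vs_stratified_sd_modes_differ():
    df = random_table(seed=3, slope_by_sex=(0.2, 1.2))
    strat = standardized_residual(df, "y", "x")
    pooled = standardized_residual(df, "y", "x", pooled_sd=True)
    assert not np.allclose(strat.values.dropna(), pooled.values.dropna())
    # pooled mode: overall SD is 1, stratum SDs need not be
    assert pooled.values.dropna().std(ddof=1) == pytest.approx(1.0, abs=0.05)


def test_conditional_velocity_tracking_slope(default_config, refs):
    """CWV's fitted slope recovers the planted tracking correlation and the
    velocity is orthogonal to the birth measure."""
    cohort, _ = __import__("capload").generate_cohort(default_config, seed=21)
    from capload.residuals import add_zscores
    work = add_zscores(cohort, refs)
    rv = conditional_velocity(work, "wz7", "bwz", name="cwv")
    for sex in ("male", "female"):
        meta = rv.fit_meta[sex]
        se = 1.0 / np.sqrt(meta["n"])
        assert meta["slope"] == pytest.approx(default_config.tracking_r, abs=4 * se)
        vals = rv.values[work.sex == sex].dropna()
        bwz = work.loc[vals.index, "bwz"]
        assert abs(np.corrcoef(vals, bwz)[0, 1]) < 1e-9


def test_conditional_velocity_degenerate_when_z_identical():
    df = random_table(n=60)
    df["z7"] = df["x"]
    with pytest.raises(DegenerateFitError):
        conditional_velocity(df, "z7", "x")


def test_build_predictor_set_missing_columns(refs):
    df = pd.DataFrame({"id": [1], "sex": ["male"]})
    with pytest.raises(SchemaError) as err:
        build_predictor_set(df, refs)
    assert "sbp" in str(err.value)


def test_build_predictor_set_full(small_cohort, refs):
    cohort, truth, cfg = small_cohort
    derived, resvars = build_predictor_set(cohort, refs)
    expected = {"wr_h", "lmr_h", "fmr_h", "fmr_lm", "cwv", "chv"}
    assert expected <= set(derived.columns)
    assert {"bwz", "blz", "height_z", "sbp_z", "dbp_z", "pp", "pp_z"} <= set(derived.columns)
    # pulse pressure is per-record systolic minus diastolic
    pd.testing.assert_series_equal(derived["pp"], derived["sbp"] - derived["dbp"],
                                   check_names=False)
    # mean PP equals mean SBP - mean DBP (linearity)
    assert derived["pp"].mean() == pytest.approx(
        derived["sbp"].mean() - derived["dbp"].mean(), abs=1e-9)
    # every SRR satisfies its invariants on the final analysed records
    # (later exclusion steps may remove a handful, shifting moments slightly)
    for name, rv in resvars.items():
        vals = rv.values.reindex(derived.index)
        for sex in ("male", "female"):
            sv = vals[derived["sex"] == sex].dropna()
            assert abs(sv.mean()) < 0.05, name
            assert abs(sv.std(ddof=1) - 1.0) < 0.05, name
        assert rv.n_outliers >= 0
    # planted gross outliers were removed
    planted = set(truth.loc[truth.planted_outlier, "id"])
    assert len(planted & set(derived["id"])) <= max(1, len(planted) // 2)


def test_pp_record_arithmetic(refs):
    from capload.residuals import add_zscores
    df = pd.DataFrame({
        "id": [1, 2], "sex": ["male", "male"],
        "sbp": [102.5, 80.0], "dbp": [57.2, 80.0],
        "age9_mo": [118.5, 118.5],
    })
    out = add_zscores(df, refs)
    assert out.loc[0, "pp"] == pytest.approx(45.3)
    assert out.loc[1, "pp"] == 0.0
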