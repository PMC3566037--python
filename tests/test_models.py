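"""Linear/logistic model suites against independent small-sample oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import capload as cl
from capload.exceptions import (ClassError, CollinearityError, DomainError,
                                SchemaError)
from capload.models import (LINEAR_MODEL_SETS, ModelSpec, classify_higher_bp,
                            fit_linear, fit_logistic, run_suite,
                            sex_interaction_pvalue)


def frame(seed=0, n=40, sexes=True):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "x1": rng.normal(size=n), "x2": rng.normal(size=n),
        "sex": np.tile(["male", "female"], n // 2) if sexes else "male",
    })
    df["y"] = 0.5 * df.x1 - 0.3 * df.x2 + rng.normal(0, 0.7, n)
    return df


def test_exact_fit_recovers_identity():
    df = frame()
    df["y"] = df["x1"]
    res = fit_linear(df, ModelSpec("y", ("x1",), stratify_by_sex=False))
    c = res.coef("x1", "all")
    assert c["beta"] == pytest.approx(1.0, abs=1e-10)
    assert c["ci_high"] - c["ci_low"] < 1e-8
    assert res.strata["all"]["r2"] == pytest.approx(1.0)


def test_single_predictor_equals_covariance_oracle():
    df = frame(seed=2)
    res = fit_linear(df, ModelSpec("y", ("x1",), stratify_by_sex=False))
    x, y = df.x1.to_numpy(), df.y.to_numpy()
    oracle = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
    assert res.coef("x1", "all")["beta"] == pytest.approx(oracle, abs=1e-9)


@pytest.mark.parametrize("seed", [1, 5, 9])
def test_multipredictor_matches_normal_equations(seed):
    """OLS on n <= 30 equals the normal-equations solution to 1e-9."""
    df = frame(seed=seed, n=30)
    res = fit_linear(df, ModelSpec("y", ("x1", "x2"), stratify_by_sex=False))
    X = np.column_stack([np.ones(30), df.x1, df.x2])
    beta = np.linalg.solve(X.T @ X, X.T @ df.y.to_numpy())
    assert res.coef("x1", "all")["beta"] == pytest.approx(beta[1], abs=1e-9)
    assert res.coef("x2", "all")["beta"] == pytest.approx(beta[2], abs=1e-9)


def test_collinearity_error_names_columns():
    df = frame()
    df["x3"] = 2 * df.x1 - 1
    with pytest.raises(CollinearityError) as err:
        fit_linear(df, ModelSpec("y", ("x1", "x2", "x3"), stratify_by_sex=False))
    assert "x1" in str(err.value) and "x3" in str(err.value)


def test_spec_validation():
    with pytest.raises(SchemaError):
        ModelSpec("y", ())
    with pytest.raises(SchemaError):
        ModelSpec("y", ("a", "a"))
    with pytest.raises(DomainError):
        ModelSpec("y", ("a",), family="logistic", higher_bp_centile=1.5)


def test_classify_higher_bp_threshold_semantics():
    zcut = stats.norm.ppf(0.95)
    df = pd.DataFrame({"z": [0.0, zcut - 1e-9, zcut, zcut + 1e-9, np.nan]})
    flag, counts = classify_higher_bp(df, "z")
    assert flag.tolist()[:4] == [0.0, 0.0, 1.0, 1.0]  # >= is inclusive
    assert np.isnan(flag.iloc[4])
    assert counts["n_high"] == 2 and counts["n"] == 4
    with pytest.raises(DomainError):
        classify_higher_bp(df, "z", centile=0.0)


def test_classify_rate_binomial_oracle():
    rng = np.random.default_rng(12)
    df = pd.DataFrame({"z": rng.standard_normal(10000)})
    _, counts = classify_higher_bp(df, "z")
    rate = counts["n_high"] / counts["n"]
    assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 10000)
    assert counts["n_high"] + counts["n_normal"] == counts["n"]


def test_all_below_threshold_none_flagged():
    df = pd.DataFrame({"z": np.linspace(-2, 1.6, 50)})
    _, counts = classify_higher_bp(df, "z")
    assert counts["n_high"] == 0


def test_logistic_null_predictor_or_near_one():
    rng = np.random.default_rng(3)
    df = pd.DataFrame({"x": rng.normal(size=2000),
                       "y": (rng.random(2000) < 0.2).astype(float)})
    res = fit_logistic(df, ModelSpec("y", ("x",), family="logistic"),
                       add_male_indicator=False)
    c = res.coef("x", "pooled")
    assert c["ci_low"] < 1.0 < c["ci_high"]
    assert abs(np.log(c["or"])) < 0.2


def test_logistic_2x2_equals_cross_product_ratio():
    """With one binary predictor the MLE odds ratio equals ad/bc."""
    rows = ([{"x": 1.0, "y": 1.0}] * 30 + [{"x": 1.0, "y": 0.0}] * 70
            + [{"x": 0.0, "y": 1.0}] * 15 + [{"x": 0.0, "y": 0.0}] * 85)
    df = pd.DataFrame(rows)
    res = fit_logistic(df, ModelSpec("y", ("x",), family="logistic"),
                       add_male_indicator=False)
    oracle = (30 * 85) / (70 * 15)
    assert res.coef("x", "pooled")["or"] == pytest.approx(oracle, rel=1e-6)


def test_logistic_score_equations_at_optimum():
    rng = np.random.default_rng(8)
    x = rng.normal(size=1500)
    p = 1 / (1 + np.exp(-(-1.0 + 0.8 * x)))
    df = pd.DataFrame({"x": x, "y": (rng.random(1500) < p).astype(float)})
    res = fit_logistic(df, ModelSpec("y", ("x",), family="logistic"),
                       add_male_indicator=False)
    b = np.array([np.log(res.strata["pooled"]["coef"]["x"]["or"])])
    # recompute the gradient of the log-likelihood at the reported optimum
    import statsmodels.api as sm
    X = sm.add_constant(df[["x"]].to_numpy())
    fit = sm.Logit(df.y.to_numpy(), X).fit(disp=0)
    grad = X.T @ (df.y.to_numpy() - 1 / (1 + np.exp(-X @ fit.params)))
    assert np.abs(grad).max() < 1e-8
    assert fit.params[1] == pytest.approx(b[0], abs=1e-8)


def test_logistic_single_class_error():
    df = pd.DataFrame({"x": [0.1, 0.4, 0.2, 0.9], "y": [1.0, 1.0, 1.0, 1.0]})
    with pytest.raises(ClassError):
        fit_logistic(df, ModelSpec("y", ("x",), family="logistic"),
                     add_male_indicator=False)


def test_frisch_waugh_cwv_orthogonality(small_cohort, refs):
    """Because CWV is constructed orthogonal to birth-weight z in-sample,
    its Model 2 coefficient equals the simple-regression coefficient."""
    cohort, _, _ = small_cohort
    derived, _ = cl.build_predictor_set(cohort, refs, predictors=("cwv",))
    sub = derived.dropna(subset=["sbp_z", "bwz", "cwv"])
    joint = fit_linear(sub, ModelSpec("sbp_z", ("bwz", "cwv")))
    simple = fit_linear(sub, ModelSpec("sbp_z", ("cwv",)))
    for sex in ("male", "female"):
        assert joint.coef("cwv", sex)["beta"] == pytest.approx(
            simple.coef("cwv", sex)["beta"], abs=1e-6)


def test_run_suite_layout_and_interaction(small_cohort, refs):
    cohort, _, _ = small_cohort
    derived, _ = cl.build_predictor_set(cohort, refs)
    report = run_suite(derived)
    assert set(report["linear"]) == {"load", "growth"}
    assert set(report["linear"]["load"]["sbp_z"]) == {"model1", "model2", "model3"}
    m3 = report["linear"]["growth"]["sbp_z"]["model3"]
    assert set(m3.strata) == {"male", "female"}
    for st in m3.strata.values():
        assert 0.0 <= st["r2"] <= 1.0
        for c in st["coef"].values():
            assert c["ci_low"] <= c["beta"] <= c["ci_high"]
    assert set(report["logistic"]) == {"sbp_z", "dbp_z"}
    p = report["interaction"]["p_value"]
    assert 0.0 <= p <= 1.0
    assert LINEAR_MODEL_SETS["growth"]["model2"] == ("bwz", "cwv")


def test_render_suite_is_text(small_cohort, refs):
    from capload.models import render_suite
    cohort, _, _ = small_cohort
    derived, _ = cl.build_predictor_set(cohort, refs, predictors=("lmr_h", "fmr_lm", "cwv"))
    text = render_suite(run_suite(derived))
    assert "Linear (growth suite)" in text and "Logistic" in text
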