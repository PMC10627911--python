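"""Acceleration residuals and association statistics against closed forms."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize
from scipy import stats as sps

from histoage.stats import (associate_adjusted, associate_univariate,
                            clock_comparison, compute_acceleration,
                            label_cognitive_impairment)


def preds_frame(ages, yhat):
    return pd.DataFrame({"slide_id": [f"s{i}" for i in range(len(ages))],
                         "age": ages, "y_hat": yhat})


def test_perfect_predictions_have_zero_residuals():
    df = compute_acceleration(preds_frame([60, 70, 80, 90], [60, 70, 80, 90]))
    np.testing.assert_allclose(df["accel"], 0.0, atol=1e-10)


def test_closed_form_least_squares_example():
    # y' on y for ages 60/70/80, preds 65/80/83: slope 0.9, intercept 13
    df = compute_acceleration(preds_frame([60, 70, 80], [65, 80, 83]))
    slope = np.polyfit(df["age"], df["y_hat"], 1)[0]
    assert slope == pytest.approx(0.9)
    np.testing.assert_allclose(df["accel"], [-2.0, 4.0, -2.0], atol=1e-10)


def test_acceleration_orthogonal_to_age_and_mean_zero():
    rng = np.random.default_rng(0)
    ages = rng.uniform(50, 100, 300)
    yhat = 20 + 0.7 * ages + rng.normal(0, 6, 300)
    df = compute_acceleration(preds_frame(ages, yhat))
    assert abs(df["accel"].mean()) < 1e-8
    assert abs(sps.pearsonr(df["accel"], df["age"])[0]) < 1e-8


def test_constant_ages_rejected():
    with pytest.raises(ValueError):
        compute_acceleration(preds_frame([70, 70, 70], [60, 70, 80]))


def test_identical_groups_give_t0_p1():
    res = associate_univariate(np.array([1.0, 2, 3, 1, 2, 3]),
                               np.array([0, 0, 0, 1, 1, 1]), "binary", "x")
    assert res.estimate == 0.0 and res.p_value == 1.0


def test_pooled_t_matches_textbook_value():
    # groups {1,2,3} (cov=0) vs {4,5,6} (cov=1): pooled t = 3.674 for high-low
    res = associate_univariate(np.array([1.0, 2, 3, 4, 5, 6]),
                               np.array([0, 0, 0, 1, 1, 1]), "binary", "x")
    assert res.estimate == pytest.approx(3.6742346, abs=1e-4)
    assert res.n == 6


def test_anova_f_closed_form():
    # groups {1,2,3},{4,5,6},{7,8,9}: SSB = 3*((2-5)^2+(8-5)^2) = 54 on 2 df,
    # SSW = 3*2 = 6 on 6 df, so F = (54/2)/(6/6) = 27
    accel = np.array([1.0, 2, 3, 4, 5, 6, 7, 8, 9])
    groups = np.repeat([0, 1, 2], 3)
    res = associate_univariate(accel, groups, "categorical", "g")
    assert res.estimate == pytest.approx(27.0)


def test_spearman_of_own_ranks_is_one():
    accel = np.array([0.3, -1.2, 2.0, 0.9, -0.4])
    ranks = sps.rankdata(accel)
    res = associate_univariate(accel, ranks, "ordinal", "r")
    assert res.estimate == pytest.approx(1.0)


def test_pearson_ci_brackets_estimate():
    rng = np.random.default_rng(1)
    a = rng.normal(size=50)
    c = a + rng.normal(size=50)
    res = associate_univariate(a, c, "continuous", "c")
    assert res.ci_low < res.estimate < res.ci_high


def test_ols_outcome_equal_to_acceleration_gives_unit_beta():
    rng = np.random.default_rng(2)
    a = rng.normal(size=60)
    sex = rng.integers(0, 2, 60)
    age = rng.uniform(50, 100, 60)
    res = associate_adjusted(a, a, sex, age, binary=False, standardize=False)
    assert res.estimate == pytest.approx(1.0, abs=1e-10)


def test_null_simulation_beta_within_3se_of_zero():
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=500)
        sex = rng.integers(0, 2, 500)
        age = rng.uniform(50, 100, 500)
        outcome = rng.normal(size=500)
        res = associate_adjusted(a, outcome, sex, age, binary=False)
        se = (res.ci_high - res.ci_low) / (2 * 1.96)
        if abs(res.estimate) <= 3 * se:
            hits += 1
    assert hits >= 9


def test_logistic_recovers_simulated_effect_within_3se():
    from histoage.synthetic import SimConfig, simulate_feature_cohort
    cfg = SimConfig(n_subjects=500, grid_shape=(2, 3), feature_dim=8, seed=6)
    _bags, _rec, truth = simulate_feature_cohort(cfg)
    t = truth.subjects
    res = associate_adjusted(t["accel"], t["impairment"], t["sex"], t["age"],
                             binary=True, standardize=True)
    # generator injects log-odds 0.5 per SD of delta
    se = (np.log(res.ci_high) - np.log(res.ci_low)) / (2 * 1.96)
    assert abs(np.log(res.estimate) - 0.5) < 3 * se


def test_logistic_matches_direct_mle_on_toy_data():
    rng = np.random.default_rng(9)
    a = np.array([-1.5, -1.0, -0.5, -0.2, 0.1, 0.4, 0.8, 1.2, 1.6, 2.0,
                  -0.8, 0.3, 0.9, -1.2, 1.1, 0.0])
    y = np.array([0, 0, 0, 1, 0, 1, 1, 1, 1, 1, 0, 1, 1, 0, 0, 1], dtype=float)
    sex = rng.integers(0, 2, 16).astype(float)
    age = rng.uniform(60, 90, 16)
    res = associate_adjusted(a, y, sex, age, binary=True, standardize=False)

    def nll(params):
        z = params[0] + params[1] * a + params[2] * sex + params[3] * (age - 75.0)
        return np.sum(np.log1p(np.exp(z)) - y * z)

    best = optimize.minimize(nll, np.zeros(4), method="Nelder-Mead",
                             options={"xatol": 1e-9, "fatol": 1e-12,
                                      "maxiter": 20000})
    assert np.log(res.estimate) == pytest.approx(best.x[1], abs=1e-3)


def test_perfect_separation_flagged_not_silent():
    a = np.array([-2.0, -1.5, -1.0, -0.5, 0.5, 1.0, 1.5, 2.0])
    y = (a > 0).astype(float)
    res = associate_adjusted(a, y, np.zeros(8), np.full(8, 80.0), binary=True)
    assert res.flag is not None


@pytest.mark.parametrize("cdr,mmse,dx,expected", [
    (0.5, 28, 0, 1.0),
    (0.0, 25, 0, 0.0),
    (None, None, None, np.nan),
    (None, 24, None, 1.0),
    (None, None, 1, 1.0),
])
def test_cognitive_impairment_composite_rule(cdr, mmse, dx, expected):
    rec = {"cdr": cdr, "mmse": mmse, "dx_impairment": dx}
    got = label_cognitive_impairment(rec)
    if np.isnan(expected):
        assert np.isnan(got)
    else:
        assert got == expected


def test_clock_identical_to_predictions_gives_unit_correlation():
    rng = np.random.default_rng(3)
    ages = rng.uniform(50, 100, 100)
    yhat = 15 + 0.8 * ages + rng.normal(0, 5, 100)
    df = compute_acceleration(preds_frame(ages, yhat))
    df["clone"] = df["y_hat"]
    r, p, _acc = clock_comparison(df, ["clone"])
    assert r.loc["histo", "clone"] == pytest.approx(1.0)
    np.testing.assert_allclose(r.to_numpy(), r.to_numpy().T)
    np.testing.assert_allclose(np.diag(r), 1.0)


def test_independent_clocks_near_zero_acceleration_correlation():
    rng = np.random.default_rng(4)
    ages = rng.uniform(50, 100, 300)
    yhat = 10 + 0.8 * ages + rng.normal(0, 5, 300)
    df = compute_acceleration(preds_frame(ages, yhat))
    df["clock_a"] = 0.6 * ages + rng.normal(0, 8, 300)
    df["clock_b"] = 0.5 * ages + rng.normal(0, 8, 300)
    r, _p, _ = clock_comparison(df, ["clock_a", "clock_b"])
    off = [r.loc["histo", "clock_a"], r.loc["histo", "clock_b"],
           r.loc["clock_a", "clock_b"]]
    assert np.max(np.abs(off)) < 0.15


def test_clock_with_too_few_pairs_is_missing():
    df = compute_acceleration(preds_frame([60, 70, 80, 90], [62, 69, 81, 88]))
    df["sparse_clock"] = [65.0, np.nan, np.nan, np.nan]
    r, _p, _ = clock_comparison(df, ["sparse_clock"])
    assert np.isnan(r.loc["histo", "sparse_clock"])
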