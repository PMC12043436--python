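"""Causal estimators against algebraic oracles and simulation checks."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from mrscreen.mr_core import (InsufficientInstruments, cochran_q,
                              egger_intercept_test, ivw, mr_egger,
                              simple_median, wald_ratio, weighted_median)
from mrscreen.synthetic import simulate_instrument_set


def _insts(bx, by, se_out, se_exp=None):
    bx = np.asarray(bx, float)
    se_exp = np.full_like(bx, 0.01) if se_exp is None else np.asarray(se_exp, float)
    return pd.DataFrame({"beta_exp": bx, "se_exp": se_exp,
                         "beta_out": np.asarray(by, float),
                         "se_out": np.asarray(se_out, float)})


def _random_insts(rng, k):
    return _insts(rng.uniform(0.05, 0.5, k) * rng.choice([-1, 1], k),
                  rng.normal(0, 0.1, k), rng.uniform(0.01, 0.05, k))


# ---------------------------------------------------------------------------
# Wald ratio


def test_wald_ratio_arithmetic():
    est = wald_ratio(_insts([0.5], [0.1], [0.05]).iloc[0])
    assert est.beta == pytest.approx(0.2)
    assert est.se == pytest.approx(0.1)
    zero = wald_ratio(_insts([0.5], [0.0], [0.05]).iloc[0])
    assert zero.beta == 0 and zero.or_ == 1
    with pytest.raises(ZeroDivisionError):
        wald_ratio(_insts([0.0], [0.1], [0.05]).iloc[0])


def test_wald_se_matches_monte_carlo_ratio_sd(rng):
    """Delta-method se agrees with the empirical sd of the ratio."""
    bx, by, se_exp, se_out = 1.0, 0.3, 0.01, 0.05
    est = wald_ratio(pd.Series({"beta_exp": bx, "beta_out": by, "se_out": se_out}))
    draws = rng.normal(by, se_out, 100_000) / rng.normal(bx, se_exp, 100_000)
    assert est.se == pytest.approx(draws.std(), rel=0.05)


# ---------------------------------------------------------------------------
# IVW


def test_ivw_single_instrument_reduces_to_wald():
    df = _insts([0.4], [0.1], [0.03])
    est = ivw(df)
    ref = wald_ratio(df.iloc[0])
    assert est.beta == pytest.approx(ref.beta)
    assert est.se == pytest.approx(ref.se)


def test_ivw_symmetric_ratios_average():
    df = _insts([0.5, 0.5], [0.05, 0.15], [0.02, 0.02])
    assert ivw(df).beta == pytest.approx(0.2)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_ivw_matches_weighted_least_squares_oracle(seed):
    rng = np.random.default_rng(seed)
    df = _random_insts(rng, 20)
    w = 1 / df["se_out"] ** 2
    oracle = float(np.sum(w * df["beta_exp"] * df["beta_out"])
                   / np.sum(w * df["beta_exp"] ** 2))
    assert ivw(df, "fixed").beta == pytest.approx(oracle, abs=1e-10)
    assert ivw(df).beta == pytest.approx(oracle, abs=1e-10)
    # independent route: statsmodels zero-intercept WLS
    fit = sm.WLS(df["beta_out"], df[["beta_exp"]], weights=w).fit()
    assert ivw(df).beta == pytest.approx(float(fit.params.iloc[0]), abs=1e-10)


def test_ivw_fixed_and_random_coincide_when_q_below_df():
    df = _insts([0.3, 0.4, 0.5], [0.06, 0.08, 0.10], [0.5, 0.5, 0.5])
    assert cochran_q(df).q <= 2
    assert ivw(df, "fixed").se == pytest.approx(ivw(df, "multiplicative_random").se)


def test_ivw_requires_instruments():
    with pytest.raises(InsufficientInstruments):
        ivw(_insts([], [], []))


# ---------------------------------------------------------------------------
# MR-Egger


def test_egger_recovers_intercept_and_slope():
    rng = np.random.default_rng(4)
    df = simulate_instrument_set(40, theta=0.2, rng=rng, se_out=1e-6,
                                 se_exp=1e-8, intercept=0.05)
    est, pleio = mr_egger(df)
    assert est.beta == pytest.approx(0.2, abs=1e-3)
    assert pleio.egger_intercept == pytest.approx(0.05, abs=1e-3)


def test_egger_exact_proportional_effects():
    bx = np.array([0.1, 0.2, 0.3, 0.4])
    df = _insts(bx, 0.7 * bx, np.full(4, 0.02))
    est, pleio = mr_egger(df)
    assert est.beta == pytest.approx(0.7, abs=1e-12)
    assert pleio.egger_intercept == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("seed", [3, 7])
def test_egger_matches_wls_with_intercept_oracle(seed):
    rng = np.random.default_rng(seed)
    df = _random_insts(rng, 15)
    sign = np.sign(df["beta_exp"])
    bx, by = df["beta_exp"] * sign, df["beta_out"] * sign
    w = 1 / df["se_out"] ** 2
    fit = sm.WLS(by, sm.add_constant(bx), weights=w).fit()
    est, pleio = mr_egger(df)
    assert est.beta == pytest.approx(float(fit.params.iloc[1]), abs=1e-10)
    assert pleio.egger_intercept == pytest.approx(float(fit.params.iloc[0]), abs=1e-10)
    # same floored multiplicative scaling applied to the oracle covariance
    scale = max(1.0, float(fit.scale))
    assert est.se == pytest.approx(float(fit.bse.iloc[1] / np.sqrt(fit.scale)
                                         * np.sqrt(scale)), abs=1e-10)


def test_egger_withheld_below_three_instruments():
    with pytest.raises(InsufficientInstruments):
        mr_egger(_insts([0.1, 0.2], [0.01, 0.02], [0.02, 0.02]))


def test_egger_intercept_power_under_directional_pleiotropy():
    rng = np.random.default_rng(8)
    df = simulate_instrument_set(50, theta=0.2, rng=rng, se_out=0.002,
                                 se_exp=1e-6, intercept=0.1)
    assert egger_intercept_test(df).pval < 1e-3


# ---------------------------------------------------------------------------
# medians


def test_weighted_median_equal_weights_midpoint():
    df = _insts([1, 1, 1, 1, 1], [1, 2, 3, 4, 5], [0.1] * 5)
    assert weighted_median(df, seed=1).beta == pytest.approx(3.0)


def test_weighted_median_dominant_instrument():
    # middle instrument carries 60% of the weight: estimate is its ratio
    df = _insts([1, 1, 1], [1, 3, 5], [np.sqrt(1 / 0.2), np.sqrt(1 / 0.6),
                                       np.sqrt(1 / 0.2)])
    assert weighted_median(df, seed=1).beta == pytest.approx(3.0)


def test_simple_median_examples():
    df = _insts([1, 1, 1], [1, 2, 9], [0.1] * 3)
    assert simple_median(df, seed=1).beta == pytest.approx(2.0)
    sym = _insts([1, 1, 1, 1], [-3, -1, 1, 3], [0.1] * 4)
    assert simple_median(sym, seed=1).beta == pytest.approx(0.0)


def _interp_oracle(ratios, weights):
    """Independent cumulative-weight interpolation implementation."""
    order = np.argsort(ratios)
    r, w = np.asarray(ratios)[order], np.asarray(weights)[order]
    cw = (np.cumsum(w) - 0.5 * w) / w.sum()
    if cw[0] >= 0.5:
        return r[0]
    if cw[-1] < 0.5:
        return r[-1]
    j = int(np.searchsorted(cw, 0.5))
    return r[j - 1] + (0.5 - cw[j - 1]) / (cw[j] - cw[j - 1]) * (r[j] - r[j - 1])


@pytest.mark.parametrize("seed", range(5))
def test_median_estimators_match_interpolation_oracle(seed):
    rng = np.random.default_rng(seed)
    df = _random_insts(rng, 9)
    ratios = (df["beta_out"] / df["beta_exp"]).to_numpy()
    w = (df["beta_exp"] ** 2 / df["se_out"] ** 2).to_numpy()
    assert weighted_median(df, seed=1).beta == pytest.approx(
        _interp_oracle(ratios, w), abs=1e-12)
    assert simple_median(df, seed=1).beta == pytest.approx(
        _interp_oracle(ratios, np.ones(9)), abs=1e-12)


def test_simple_median_equals_weighted_under_equal_weights(rng):
    df = _random_insts(rng, 11)
    df["se_out"] = 0.02
    df["beta_exp"] = np.abs(df["beta_exp"]).mean()  # equalize weights
    assert simple_median(df, seed=5).beta == pytest.approx(
        weighted_median(df, seed=5).beta)


def test_median_bootstrap_is_seed_deterministic(rng):
    df = _random_insts(rng, 10)
    a = weighted_median(df, n_boot=200, seed=42)
    b = weighted_median(df, n_boot=200, seed=42)
    assert a.se == b.se
    assert weighted_median(df, n_boot=200, seed=43).se != a.se


# ---------------------------------------------------------------------------
# heterogeneity


def test_q_zero_for_identical_ratios():
    bx = np.array([0.2, 0.4, 0.8])
    het = cochran_q(_insts(bx, 0.3 * bx, [0.02, 0.02, 0.02]))
    assert het.q == pytest.approx(0.0, abs=1e-20)
    assert het.i2 == 0.0
    assert het.label == "absent"


def test_i2_labels_follow_thresholds():
    # i2 = (q - df)/q inverted: q = df/(1 - i2)
    from mrscreen.mr_core import HeterogeneityResult
    assert HeterogeneityResult(q=10 / (1 - 0.5805), df=10, pval=0.001).label == "present"
    assert HeterogeneityResult(q=10 / (1 - 0.30), df=10, pval=0.1).label == "mild"
    assert HeterogeneityResult(q=10.0, df=10, pval=0.4).label == "absent"


def test_q_matches_direct_summation_oracle(rng):
    df = _random_insts(rng, 12)
    r = df["beta_out"] / df["beta_exp"]
    w = df["beta_exp"] ** 2 / df["se_out"] ** 2
    beta = np.sum(w * r) / np.sum(w)
    q = float(np.sum(w * (r - beta) ** 2))
    het = cochran_q(df)
    assert het.q == pytest.approx(q, abs=1e-10)
    assert het.pval == pytest.approx(float(stats.chi2.sf(q, 11)), abs=1e-12)


# ---------------------------------------------------------------------------
# estimator-wide properties


ALL_ESTIMATORS = [
    ("ivw", lambda d: ivw(d).beta),
    ("egger", lambda d: mr_egger(d)[0].beta),
    ("wmedian", lambda d: weighted_median(d, seed=2).beta),
    ("smedian", lambda d: simple_median(d, seed=2).beta),
]


@pytest.mark.parametrize("name,fn", ALL_ESTIMATORS)
def test_scale_and_sign_equivariance(name, fn, rng):
    df = _random_insts(rng, 10)
    base = fn(df)
    scaled = df.copy()
    scaled[["beta_exp", "se_exp"]] *= 3.0
    assert fn(scaled) == pytest.approx(base / 3.0, rel=1e-9)
    negated = df.copy()
    negated["beta_out"] *= -1
    assert fn(negated) == pytest.approx(-base, rel=1e-9)


def test_all_estimators_agree_on_constant_ratio(rng):
    bx = rng.uniform(0.1, 0.5, 8)
    df = _insts(bx, 0.25 * bx, np.full(8, 0.02))
    for name, fn in ALL_ESTIMATORS:
        assert fn(df) == pytest.approx(0.25, abs=1e-9), name
    assert wald_ratio(df.iloc[0]).beta == pytest.approx(0.25)
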