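"""Simulation-based calibration of the estimators and the full screen.

These routines measure, under the generator's known truth, the properties
a trustworthy MR screen must have: unbiased point estimates with honest
confidence intervals when instruments are valid, a nominally sized
Egger-intercept test when pleiotropy is absent, the expected
false-positive count of the Bonferroni rule under a global null, and
recovery of the planted mediation proportion with correct
complementary/competitive typing.  Everything is deterministic given the
seed; Monte-Carlo sizes are arguments so callers can trade precision for
runtime.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .mediation import EffectSE, mediation_proportion
from .mr_core import ivw, mr_egger, simple_median, wald_ratio, weighted_median
from .pipeline import ScreenConfig, run_screen
from .synthetic import (SimConfig, simulate_instrument_set,
                        simulate_mediation_legs, simulate_study,
                        true_mediation_proportion)


def estimator_calibration(n_rep: int = 200, k: int = 50, theta: float = 0.2,
                          seed: int = 0, n_boot: int = 1000) -> pd.DataFrame:
    """Bias and 95%-CI coverage of all five estimators with valid instruments.

    Each replicate draws ``k`` strong, pleiotropy-free instruments and
    fits every estimator; the Wald ratio uses the replicate's first
    instrument.  Returns one row per estimator with the mean estimate,
    mean bias, Monte-Carlo standard error of the mean, and empirical
    coverage of the 95% interval.
    """
    rng = np.random.default_rng(seed)
    estimates: dict[str, list[float]] = {}
    covered: dict[str, list[bool]] = {}
    or_true = float(np.exp(theta))
    for _ in range(n_rep):
        df = simulate_instrument_set(k, theta, rng)
        boot_seed = int(rng.integers(0, 2**31 - 1))
        fits = {
            "ivw": ivw(df),
            "mr_egger": mr_egger(df)[0],
            "weighted_median": weighted_median(df, n_boot, boot_seed),
            "simple_median": simple_median(df, n_boot, boot_seed),
            "wald_ratio": wald_ratio(df.iloc[0]),
        }
        for name, est in fits.items():
            estimates.setdefault(name, []).append(est.beta)
            covered.setdefault(name, []).append(est.ci_low <= or_true <= est.ci_high)
    rows = []
    for name, vals in estimates.items():
        vals = np.asarray(vals)
        mc_se = vals.std(ddof=1) / np.sqrt(n_rep)
        rows.append({"estimator": name, "truth": theta,
                     "mean_estimate": vals.mean(),
                     "mean_bias": vals.mean() - theta, "mc_se": mc_se,
                     "bias_over_mc_se": abs(vals.mean() - theta) / mc_se,
                     "coverage": float(np.mean(covered[name]))})
    return pd.DataFrame(rows)


def egger_type1_rate(n_rep: int = 500, k: int = 30, theta: float = 0.2,
                     seed: int = 0, alpha: float = 0.05) -> float:
    """Rejection rate of the Egger-intercept test under no pleiotropy."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_rep):
        df = simulate_instrument_set(k, theta, rng)
        if mr_egger(df)[1].pval < alpha:
            rejections += 1
    return rejections / n_rep


def egger_power_directional(n_rep: int = 100, k: int = 30, theta: float = 0.2,
                            intercept: float = 0.05, seed: int = 0,
                            alpha: float = 0.05) -> float:
    """Rejection rate under directional pleiotropy of the given magnitude."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_rep):
        df = simulate_instrument_set(k, theta, rng, intercept=intercept)
        if mr_egger(df)[1].pval < alpha:
            rejections += 1
    return rejections / n_rep


def null_screen_calibration(seed: int = 0, n_exposures: int = 30,
                            m_snps: int = 3000) -> dict:
    """Bonferroni-passing count of a full screen on a global-null study.

    Every causal effect is zero; exposures keep their instruments.  The
    number of exposures whose IVW p falls below the Bonferroni threshold
    0.025 should behave as Binomial(n_exposures, 0.025); the returned
    dict includes the central-99% bounds of that law.
    """
    cfg = SimConfig(seed=seed, m_snps=m_snps, n_exposures=n_exposures,
                    n_mediators=0, theta_xy=0.0, theta_xm=0.0, theta_my=0.0,
                    n_causal_exposures=0)
    study, _ = simulate_study(cfg)
    scfg = ScreenConfig(direction="forward",
                        exposure_families=["immunophenotype"], seed=seed)
    screen = run_screen(scfg, study)
    passing = int((screen["ivw_pval"] < scfg.bonferroni_alpha).sum())
    n = len(screen)
    return {
        "n_pairs": n, "n_bonferroni_passing": passing,
        "expected": n * scfg.bonferroni_alpha,
        "bound_low": int(stats.binom.ppf(0.005, n, scfg.bonferroni_alpha)),
        "bound_high": int(stats.binom.ppf(0.995, n, scfg.bonferroni_alpha)),
    }


def mediation_recovery(n_rep: int = 200, k: int = 50, theta_xy: float = 0.15,
                       theta_xm: float = 0.3, theta_my: float = 0.15,
                       seed: int = 0) -> dict:
    """Recovery of the planted mediation proportion and its typing.

    Each replicate simulates the three IVW legs of one triple, computes
    the proportion mediated and the complementary/competitive label, and
    compares against the path-diagram truth
    theta_xm*theta_my/(theta_xy + theta_xm*theta_my).  Label accuracy is
    reported over the unambiguous replicates (|indirect| > 3 Sobel se).
    """
    rng = np.random.default_rng(seed)
    truth = true_mediation_proportion(theta_xy, theta_xm, theta_my)
    indirect_true = theta_xm * theta_my
    total = theta_xy + indirect_true
    true_type = ("complementarity" if indirect_true == 0
                 or (indirect_true > 0) == (total > 0) else "competitive")
    thetas, labels, unambiguous = [], [], []
    for _ in range(n_rep):
        legs = simulate_mediation_legs(k, theta_xy, theta_xm, theta_my, rng)
        b0 = ivw(legs["exposure_outcome"])
        b1 = ivw(legs["exposure_mediator"])
        b2 = ivw(legs["mediator_outcome"])
        res = mediation_proportion(EffectSE(b0.beta, b0.se),
                                   EffectSE(b1.beta, b1.se),
                                   EffectSE(b2.beta, b2.se))
        thetas.append(res.theta)
        labels.append(res.mtype)
        ind = b1.beta * b2.beta
        se_ind = np.sqrt(b1.beta**2 * b2.se**2 + b2.beta**2 * b1.se**2)
        unambiguous.append(abs(ind) > 3 * se_ind)
    thetas = np.asarray(thetas)
    unambiguous = np.asarray(unambiguous)
    labels_arr = np.asarray(labels)
    mc_se = thetas.std(ddof=1) / np.sqrt(n_rep)
    n_unamb = int(unambiguous.sum())
    acc = (float(np.mean(labels_arr[unambiguous] == true_type))
           if n_unamb else np.nan)
    return {
        "truth": truth, "true_type": true_type,
        "mean_theta": float(thetas.mean()),
        "bias": float(thetas.mean() - truth), "mc_se": float(mc_se),
        "bias_over_mc_se": float(abs(thetas.mean() - truth) / mc_se),
        "n_unambiguous": n_unamb, "label_accuracy": acc,
    }
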