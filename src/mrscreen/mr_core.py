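"""Two-sample MR estimators and sensitivity diagnostics.

All estimators consume a harmonized instrument table (columns ``beta_exp,
se_exp, beta_out, se_out``; dropped rows are ignored) and return an
:class:`MREstimate` on the outcome scale — for a binary outcome the causal
beta is a log odds ratio, reported alongside exp-transformed OR and 95% CI.

The workhorse is the inverse-variance-weighted (IVW) estimator: a
zero-intercept regression of outcome effects on exposure effects with
weights 1/se_out².  By default standard errors use multiplicative
random-effects scaling, inflating by sqrt(Q/df) when Cochran's Q exceeds
its degrees of freedom and never deflating below the fixed-effect value.
MR-Egger frees the intercept (a nonzero intercept indicates directional
horizontal pleiotropy) with t-based inference on k-2 df; the weighted and
simple median estimators are consistent when at least half the weight
comes from valid instruments, with parametric-bootstrap standard errors.

Per-SNP Wald ratios use first-order weights throughout: se(ratio) =
se_out/|beta_exp|, so Q computed over ratios equals the residual sum of
squares of the zero-intercept weighted regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

Z95 = 1.959964  # normal 97.5% quantile at the precision used for CIs

#: Minimum instrument counts per method.
MIN_INSTRUMENTS = {
    "wald_ratio": 1, "ivw": 1, "cochran_q": 2,
    "mr_egger": 3, "weighted_median": 3, "simple_median": 3,
}


class InsufficientInstruments(ValueError):
    """Estimate withheld: fewer instruments than the method's minimum."""

    def __init__(self, method: str, k: int):
        self.method, self.k = method, k
        super().__init__(
            f"{method} withheld: {k} instrument(s) < minimum {MIN_INSTRUMENTS[method]}")


@dataclass
class MREstimate:
    method: str
    beta: float
    se: float
    pval: float
    n_snp: int

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.beta - self._crit * self.se))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.beta + self._crit * self.se))

    @property
    def _crit(self) -> float:
        if self.method == "mr_egger" and self.n_snp > 2:
            return float(stats.t.ppf(0.975, self.n_snp - 2))
        return Z95


@dataclass
class HeterogeneityResult:
    """Cochran's Q over per-SNP ratios with the I² share of heterogeneity.

    I² = max(0, (Q - df)/Q); labels follow the 25%/50% convention:
    below 25% heterogeneity is absent, below 50% mild, otherwise present.
    """

    q: float
    df: int
    pval: float

    @property
    def i2(self) -> float:
        return max(0.0, (self.q - self.df) / self.q) if self.q > 0 else 0.0

    @property
    def label(self) -> str:
        if self.i2 < 0.25:
            return "absent"
        if self.i2 < 0.50:
            return "mild"
        return "present"


@dataclass
class PleiotropyResult:
    egger_intercept: float
    se: float
    pval: float


def _arrays(insts: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    if "action" in insts.columns:
        insts = insts[insts["action"] != "dropped"]
    bx = insts["beta_exp"].to_numpy(float)
    sx = insts["se_exp"].to_numpy(float)
    by = insts["beta_out"].to_numpy(float)
    sy = insts["se_out"].to_numpy(float)
    return bx, sx, by, sy


def wald_ratio(inst: pd.DataFrame | pd.Series) -> MREstimate:
    """Single-instrument ratio estimate beta_out/beta_exp.

    First-order standard error se_out/|beta_exp| (exposure uncertainty
    ignored — adequate for strong instruments).
    """
    if isinstance(inst, pd.DataFrame):
        if len(inst) != 1:
            raise ValueError("wald_ratio takes exactly one instrument")
        inst = inst.iloc[0]
    bx, by, sy = float(inst["beta_exp"]), float(inst["beta_out"]), float(inst["se_out"])
    if bx == 0:
        raise ZeroDivisionError("wald ratio undefined for beta_exp = 0")
    beta = by / bx
    se = sy / abs(bx)
    pval = float(2 * stats.norm.sf(abs(beta) / se))
    return MREstimate("wald_ratio", beta, se, max(pval, 0.0), 1)


def ivw(insts: pd.DataFrame, effects_model: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance-weighted estimate.

    Zero-intercept weighted regression of beta_out on beta_exp, weights
    1/se_out².  ``fixed`` takes the analytic weight-sum standard error;
    ``multiplicative_random`` (default) inflates it by max(1, sqrt(Q/df)).
    With a single instrument this reduces exactly to the Wald ratio.
    """
    bx, _, by, sy = _arrays(insts)
    k = bx.size
    if k < 1:
        raise InsufficientInstruments("ivw", k)
    if np.any(bx == 0):
        raise ZeroDivisionError("ivw requires all beta_exp != 0")
    if effects_model not in {"fixed", "multiplicative_random"}:
        raise ValueError(f"unknown effects model {effects_model!r}")
    w = 1.0 / sy**2
    beta = float(np.sum(w * bx * by) / np.sum(w * bx**2))
    se = float(np.sqrt(1.0 / np.sum(w * bx**2)))
    if k >= 2 and effects_model == "multiplicative_random":
        q = float(np.sum(w * (by - beta * bx) ** 2))
        se *= max(1.0, np.sqrt(q / (k - 1)))
    pval = float(2 * stats.norm.sf(abs(beta) / se))
    return MREstimate("ivw", beta, se, pval, int(k))


def _egger_fit(insts: pd.DataFrame) -> tuple[MREstimate, PleiotropyResult]:
    bx, _, by, sy = _arrays(insts)
    k = bx.size
    if k < 3:
        raise InsufficientInstruments("mr_egger", k)
    # orientation convention: all exposure effects positive
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    w = 1.0 / sy**2
    X = np.column_stack([np.ones(k), bx])
    XtW = X.T * w
    cov_unscaled = np.linalg.inv(XtW @ X)
    coef = cov_unscaled @ (XtW @ by)
    resid = by - X @ coef
    sigma2 = float(np.sum(w * resid**2) / (k - 2))
    cov = cov_unscaled * max(1.0, sigma2)  # floor: never tighter than homoscedastic
    se = np.sqrt(np.diag(cov))
    tvals = coef / se
    pvals = 2 * stats.t.sf(np.abs(tvals), k - 2)
    est = MREstimate("mr_egger", float(coef[1]), float(se[1]), float(pvals[1]), int(k))
    pleio = PleiotropyResult(float(coef[0]), float(se[0]), float(pvals[0]))
    return est, pleio


def mr_egger(insts: pd.DataFrame) -> tuple[MREstimate, PleiotropyResult]:
    """Weighted regression with a free intercept; slope is the causal effect.

    Instruments are first oriented so every exposure effect is positive.
    Slope and intercept inference uses the t distribution with k-2 df and
    multiplicative residual scaling floored at one (the same convention as
    the default random-effects IVW).
    """
    return _egger_fit(insts)


def egger_intercept_test(insts: pd.DataFrame) -> PleiotropyResult:
    """Directional-pleiotropy test: the MR-Egger intercept row."""
    return _egger_fit(insts)[1]


def _weighted_median_rows(ratios: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Row-wise weighted median by cumulative-weight interpolation.

    ``ratios`` is (n, k); ``weights`` is (k,) or (n, k).  The estimate is
    the linear interpolation of the ordered ratios at standardized
    cumulative weight 1/2 (each point placed at its cumulative weight
    minus half its own).
    """
    ratios = np.atleast_2d(ratios)
    n, k = ratios.shape
    weights = np.broadcast_to(np.atleast_2d(weights), (n, k))
    order = np.argsort(ratios, axis=1)
    r = np.take_along_axis(ratios, order, axis=1)
    w = np.take_along_axis(weights, order, axis=1)
    cw = (np.cumsum(w, axis=1) - 0.5 * w) / np.sum(w, axis=1, keepdims=True)
    below = np.clip((cw < 0.5).sum(axis=1) - 1, 0, k - 2)
    rows = np.arange(n)
    c0, c1 = cw[rows, below], cw[rows, below + 1]
    r0, r1 = r[rows, below], r[rows, below + 1]
    frac = np.where(c1 > c0, (0.5 - c0) / np.where(c1 > c0, c1 - c0, 1.0), 0.0)
    est = r0 + np.clip(frac, 0.0, 1.0) * (r1 - r0)
    # degenerate tails: all mass below/above the midpoint
    est = np.where(cw[:, 0] >= 0.5, r[:, 0], est)
    est = np.where(cw[:, -1] < 0.5, r[:, -1], est)
    return est


def _median_estimator(insts: pd.DataFrame, weighted: bool, n_boot: int,
                      seed: int) -> MREstimate:
    method = "weighted_median" if weighted else "simple_median"
    bx, sx, by, sy = _arrays(insts)
    k = bx.size
    if k < 3:
        raise InsufficientInstruments(method, k)
    if np.any(bx == 0):
        raise ZeroDivisionError(f"{method} requires all beta_exp != 0")
    ratios = by / bx
    weights = bx**2 / sy**2 if weighted else np.ones(k)
    beta = float(_weighted_median_rows(ratios, weights)[0])
    rng = np.random.default_rng(seed)
    bx_b = rng.normal(bx, sx, size=(n_boot, k))
    by_b = rng.normal(by, sy, size=(n_boot, k))
    bx_b = np.where(bx_b == 0, np.finfo(float).tiny, bx_b)
    boot = _weighted_median_rows(by_b / bx_b, weights)
    se = float(np.std(boot, ddof=1))
    pval = float(2 * stats.norm.sf(abs(beta) / se)) if se > 0 else (1.0 if beta == 0 else 0.0)
    return MREstimate(method, beta, se, pval, int(k))


def weighted_median(insts: pd.DataFrame, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted-median estimate with parametric-bootstrap standard error.

    Per-SNP ratios are weighted by their inverse first-order variance
    beta_exp²/se_out²; the bootstrap resamples beta_exp and beta_out from
    normal(beta, se) and is deterministic given ``seed``.
    """
    return _median_estimator(insts, weighted=True, n_boot=n_boot, seed=seed)


def simple_median(insts: pd.DataFrame, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Simple (equal-weight) median estimate, bootstrap standard error."""
    return _median_estimator(insts, weighted=False, n_boot=n_boot, seed=seed)


def cochran_q(insts: pd.DataFrame) -> HeterogeneityResult:
    """Cochran's Q across per-SNP Wald ratios with first-order weights.

    Q = sum_j w_j (r_j - beta_IVW,fixed)² with r_j = beta_out/beta_exp and
    w_j = beta_exp²/se_out²; p from the upper chi-square tail on k-1 df.
    """
    bx, _, by, sy = _arrays(insts)
    k = bx.size
    if k < 2:
        raise InsufficientInstruments("cochran_q", k)
    if np.any(bx == 0):
        raise ZeroDivisionError("cochran_q requires all beta_exp != 0")
    r = by / bx
    w = bx**2 / sy**2
    beta_fixed = float(np.sum(w * r) / np.sum(w))
    q = float(np.sum(w * (r - beta_fixed) ** 2))
    df = k - 1
    pval = float(stats.chi2.sf(q, df))
    return HeterogeneityResult(q, df, pval)
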