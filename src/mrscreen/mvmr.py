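"""Multivariable MR: jointly regress outcome effects on several exposures.

Instruments are the union of each exposure's clumped instrument set,
re-clumped jointly (ranking by the minimum p across exposures), restricted
to variants present in every exposure table and the outcome, and
harmonized onto the first exposure's allele orientation.  The adjusted
causal effects are the coefficients of a zero-intercept weighted multiple
regression of outcome betas on the matrix of exposure betas with weights
1/se_out², with multiplicative residual scaling of the covariance floored
at one — so a single-exposure fit reproduces the univariable IVW exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import (InstrumentConfig, LDMatrix, harmonize,
                          kept_instruments, ld_clump, select_candidates)
from .mr_core import Z95, InsufficientInstruments


@dataclass
class MVMRResult:
    exposures: list[str]
    estimates: pd.DataFrame  # one row per exposure: beta, se, or, ci_low, ci_high, pval
    n_snp: int
    conditioned_on: str


def mvmr_fit(X: np.ndarray, y: np.ndarray, se_out: np.ndarray,
             effects_model: str = "multiplicative_random") -> tuple[np.ndarray, np.ndarray]:
    """Weighted zero-intercept multiple regression; returns (beta, se).

    Covariance is (X'WX)⁻¹ scaled by max(1, Q/(k-p)) under the default
    multiplicative random-effects model, or unscaled weight-only
    covariance under ``fixed``.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    k, p = X.shape
    if k <= p:
        raise InsufficientInstruments("ivw", k)
    w = 1.0 / np.asarray(se_out, float) ** 2
    # an all-zero column carries no information: its coefficient is pinned
    # to 0 with infinite se rather than failing the whole fit
    nonzero = np.flatnonzero(np.any(X != 0, axis=0))
    Xn = X[:, nonzero]
    XtW = Xn.T * w
    xtwx = XtW @ Xn
    rank = np.linalg.matrix_rank(xtwx) if nonzero.size else 0
    if rank < nonzero.size:
        raise np.linalg.LinAlgError(
            f"rank-deficient exposure-beta matrix (rank {rank} < {nonzero.size}): "
            "exposure effects are collinear on the shared instruments")
    beta = np.zeros(p)
    se = np.full(p, np.inf)
    if nonzero.size:
        cov_unscaled = np.linalg.inv(xtwx)
        bn = cov_unscaled @ (XtW @ y)
        if effects_model == "multiplicative_random":
            q = float(np.sum(w * (y - Xn @ bn) ** 2))
            scale = max(1.0, q / (k - p))
        elif effects_model == "fixed":
            scale = 1.0
        else:
            raise ValueError(f"unknown effects model {effects_model!r}")
        beta[nonzero] = bn
        se[nonzero] = np.sqrt(np.diag(cov_unscaled) * scale)
    return beta, se


def _union_instruments(exposure_tables: dict[str, pd.DataFrame], ld: LDMatrix,
                       cfg: InstrumentConfig) -> pd.DataFrame:
    """Union of per-exposure clumped IVs, re-clumped jointly on min-p."""
    union: dict[str, dict] = {}
    for df in exposure_tables.values():
        ivs = ld_clump(select_candidates(df, cfg), ld, cfg)
        for row in ivs.itertuples(index=False):
            entry = union.get(row.snp)
            if entry is None or row.pval < entry["pval"]:
                union[row.snp] = {"snp": row.snp, "chr": row.chr, "pos": row.pos,
                                  "effect_allele": row.effect_allele,
                                  "other_allele": row.other_allele,
                                  "eaf": row.eaf, "beta": row.beta, "se": row.se,
                                  "pval": row.pval, "n": row.n}
    if not union:
        return pd.DataFrame(columns=["snp", "chr", "pos", "pval"])
    joint = pd.DataFrame(list(union.values()))
    return ld_clump(joint, ld, cfg)


def mvmr_estimate(exposure_tables: dict[str, pd.DataFrame],
                  outcome_table: pd.DataFrame, ld: LDMatrix,
                  cfg: InstrumentConfig | None = None,
                  effects_model: str = "multiplicative_random") -> MVMRResult:
    """Mediator-adjusted causal estimates for two or more exposures.

    Variants missing from any exposure table (or dropped during any
    harmonization, e.g. intermediate-frequency palindromes) leave the
    instrument set — no zero-imputation.  Requires more instruments than
    exposures; collinear exposure effects are a hard failure.
    """
    cfg = cfg or InstrumentConfig()
    ids = list(exposure_tables)
    if len(ids) < 1:
        raise ValueError("at least one exposure table required")
    joint = _union_instruments(exposure_tables, ld, cfg)

    first = ids[0]
    ref = exposure_tables[first]
    ref_rows = ref[ref["snp"].isin(joint["snp"])]
    # align every other table (exposures and outcome) onto the reference
    aligned: dict[str, pd.DataFrame] = {}
    keep = set(ref_rows["snp"])
    for tid in ids[1:]:
        h = kept_instruments(harmonize(ref_rows, exposure_tables[tid], cfg))
        aligned[tid] = h.set_index("rsid")
        keep &= set(h["rsid"])
    h_out = kept_instruments(harmonize(ref_rows, outcome_table, cfg))
    out = h_out.set_index("rsid")
    keep &= set(out.index)
    rsids = sorted(keep)
    k, p = len(rsids), len(ids)
    if k <= p:
        raise InsufficientInstruments("ivw", k)

    ref_idx = ref_rows.set_index("snp")
    cols = [ref_idx.loc[rsids, "beta"].to_numpy(float)]
    for tid in ids[1:]:
        cols.append(aligned[tid].loc[rsids, "beta_out"].to_numpy(float))
    X = np.column_stack(cols)
    y = out.loc[rsids, "beta_out"].to_numpy(float)
    se_out = out.loc[rsids, "se_out"].to_numpy(float)

    beta, se = mvmr_fit(X, y, se_out, effects_model=effects_model)
    z = np.divide(np.abs(beta), se, out=np.zeros_like(beta), where=se > 0)
    pvals = 2 * stats.norm.sf(z)
    est = pd.DataFrame({
        "exposure": ids, "beta": beta, "se": se,
        "or": np.exp(beta),
        "ci_low": np.exp(beta - Z95 * se),
        "ci_high": np.exp(beta + Z95 * se),
        "pval": pvals,
    })
    conditioned = ",".join(ids[1:]) if len(ids) > 1 else ""
    return MVMRResult(ids, est, k, conditioned)
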