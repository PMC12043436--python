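"""Two-step mediation MR: proportion mediated, CI, p-value and typing.

For an exposure X, mediator M and outcome Y with IVW estimates
beta0 (X on Y, total), beta1 (X on M) and beta2 (M on Y), the mediation
proportion is theta = beta1*beta2/beta0.  The effect is *complementary*
when the indirect effect beta1*beta2 points the same way as the total
effect, and *competitive* when they oppose.

Inference treats the three estimates as independent (they come from
separate GWAS): the CI is a first-order delta-method interval on the
three-parameter ratio, and the p-value is the Sobel-type normal test of
the indirect effect beta1*beta2 with variance beta1²se2² + beta2²se1².
Both conventions are the package's own and are documented as such.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import pandas as pd

from .mr_core import Z95, MREstimate

logger = logging.getLogger(__name__)


class EffectSE(NamedTuple):
    """A point estimate with its standard error."""

    effect: float
    se: float


@dataclass
class MediationResult:
    exposure_id: str
    mediator_id: str
    outcome_id: str
    beta0: float
    beta1: float
    beta2: float
    theta: float
    ci_low: float
    ci_high: float
    pval: float
    mtype: str  # "complementarity" | "competitive"


def mediation_proportion(beta0: EffectSE, beta1: EffectSE, beta2: EffectSE,
                         exposure_id: str = "exposure",
                         mediator_id: str = "mediator",
                         outcome_id: str = "outcome") -> MediationResult:
    """Proportion mediated theta = beta1*beta2/beta0 with delta-method CI.

    A zero indirect effect yields theta = 0, p = 1 and the complementarity
    label by convention.  beta0 = 0 is a hard failure (undefined ratio).
    """
    b0, s0 = beta0
    b1, s1 = beta1
    b2, s2 = beta2
    if b0 == 0:
        raise ZeroDivisionError("mediation proportion undefined for zero total effect")
    for name, s in (("beta0", s0), ("beta1", s1), ("beta2", s2)):
        if s <= 0:
            raise ValueError(f"{name} standard error must be positive")
    indirect = b1 * b2
    theta = indirect / b0
    # delta method on (b1 b2)/b0 under independence
    var = (b2 / b0) ** 2 * s1**2 + (b1 / b0) ** 2 * s2**2 + (theta / b0) ** 2 * s0**2
    half = Z95 * var**0.5
    if indirect == 0:
        pval, mtype = 1.0, "complementarity"
    else:
        from scipy import stats

        se_ind = (b1**2 * s2**2 + b2**2 * s1**2) ** 0.5
        pval = float(2 * stats.norm.sf(abs(indirect) / se_ind))
        mtype = "complementarity" if (indirect > 0) == (b0 > 0) else "competitive"
    return MediationResult(exposure_id, mediator_id, outcome_id,
                           b0, b1, b2, theta, theta - half, theta + half,
                           pval, mtype)


def mediation_screen(pairs: Sequence[tuple[str, str]], outcome: str,
                     estimates: Mapping[tuple[str, str], MREstimate],
                     screen_p: float = 0.05) -> pd.DataFrame:
    """Run the two-step screen over candidate (exposure, mediator) pairs.

    ``estimates`` maps (trait_a, trait_b) to the IVW estimate of a on b.
    A triple qualifies when all three legs (X->Y, X->M, M->Y) are present
    and significant at ``screen_p``; missing legs are skipped and logged.
    The table is sorted by |theta| descending.
    """
    rows = []
    for exposure, mediator in pairs:
        legs = {}
        missing = False
        for name, key in (("beta0", (exposure, outcome)),
                          ("beta1", (exposure, mediator)),
                          ("beta2", (mediator, outcome))):
            est = estimates.get(key)
            if est is None:
                logger.info("mediation triple (%s, %s) skipped: leg %s->%s missing",
                            exposure, mediator, *key)
                missing = True
                break
            legs[name] = est
        if missing:
            continue
        if any(est.pval >= screen_p for est in legs.values()):
            continue
        res = mediation_proportion(
            EffectSE(legs["beta0"].beta, legs["beta0"].se),
            EffectSE(legs["beta1"].beta, legs["beta1"].se),
            EffectSE(legs["beta2"].beta, legs["beta2"].se),
            exposure_id=exposure, mediator_id=mediator, outcome_id=outcome)
        rows.append(res.__dict__)
    cols = ["exposure_id", "mediator_id", "outcome_id", "beta0", "beta1",
            "beta2", "theta", "ci_low", "ci_high", "pval", "mtype"]
    table = pd.DataFrame(rows, columns=cols)
    if len(table):
        table = table.reindex(table["theta"].abs().sort_values(ascending=False).index)
    return table.reset_index(drop=True)
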