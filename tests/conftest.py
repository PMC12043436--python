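import numpy as np
import pandas as pd
import pytest

from mrscreen.synthetic import SimConfig, simulate_study


def random_sumstats(rng: np.random.Generator, n: int, trait_id: str = "t1",
                    quantize: bool = True) -> pd.DataFrame:
    """A random valid summary-statistics table in the canonical dialect.

    ``quantize`` rounds floats through the writer's 10-significant-digit
    format so that write/read round-trips are exact fixpoints.
    """
    alleles = np.array(list("ACGT"))
    ea = rng.choice(alleles, size=n)
    oa = np.array([rng.choice([a for a in "ACGT" if a != e]) for e in ea])
    beta = rng.normal(0, 0.2, n)
    se = rng.uniform(0.01, 0.1, n)
    from scipy import stats
    pval = np.clip(2 * stats.norm.sf(np.abs(beta / se)), 1e-300, 1.0)
    df = pd.DataFrame({
        "snp": [f"rs{i}" for i in range(n)],
        "chr": rng.choice([str(c) for c in range(1, 23)] + ["X"], size=n),
        "pos": rng.integers(1, 10**8, size=n),
        "effect_allele": ea, "other_allele": oa,
        "eaf": rng.uniform(0.05, 0.95, n),
        "beta": beta, "se": se, "pval": pval,
        "n": np.full(n, 1000.0),
    })
    if quantize:
        for col in ("eaf", "beta", "se", "pval", "n"):
            df[col] = [float(format(v, ".10g")) for v in df[col]]
    df["trait_id"] = trait_id
    return df


@pytest.fixture(scope="session")
def small_study():
    """One modest synthetic study shared by read-only tests."""
    cfg = SimConfig(seed=11, m_snps=2000, n_exposures=6, n_mediators=2,
                    pi_instrument=0.006)
    return simulate_study(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
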