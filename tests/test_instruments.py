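"""Instrument selection, greedy LD clumping and allele harmonization."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from mrscreen.instruments import (COMPLEMENT, InstrumentConfig, LDMatrix,
                                  harmonize, kept_instruments, ld_clump,
                                  select_candidates)
from mrscreen.synthetic import SimConfig, simulate_study

from conftest import random_sumstats


def _ld_from_dense(rsids, dense):
    return LDMatrix(rsids, sparse.csr_matrix(np.asarray(dense, float)))


def _table(rows):
    return pd.DataFrame(rows, columns=["snp", "chr", "pos", "effect_allele",
                                       "other_allele", "eaf", "beta", "se",
                                       "pval", "n"])


# ---------------------------------------------------------------------------
# selection


def test_select_candidates_threshold():
    df = _table([("rs1", "1", 100, "A", "G", 0.3, 0.2, 0.04, 2e-6, 100),
                 ("rs2", "1", 200, "A", "G", 0.3, 0.2, 0.04, 5e-5, 100)])
    kept = select_candidates(df, InstrumentConfig())
    assert list(kept["snp"]) == ["rs1"]
    assert select_candidates(df.assign(pval=1.0), InstrumentConfig()).empty


def test_select_candidates_matches_brute_force(rng):
    df = random_sumstats(rng, 300)
    cfg = InstrumentConfig(p_threshold=0.05)
    kept = select_candidates(df, cfg)
    expected = df[df["pval"] < 0.05]
    assert set(kept["snp"]) == set(expected["snp"])
    assert kept["pval"].is_monotonic_increasing


# ---------------------------------------------------------------------------
# clumping


def test_clump_keeps_lowest_p_of_linked_pair():
    df = _table([("rs1", "1", 1000, "A", "G", 0.3, 0.3, 0.04, 1e-8, 100),
                 ("rs2", "1", 2000, "A", "G", 0.3, 0.2, 0.04, 1e-6, 100)])
    ld = _ld_from_dense(["rs1", "rs2"], [[1, 0.5], [0.5, 1]])
    kept = ld_clump(df, ld, InstrumentConfig())
    assert list(kept["snp"]) == ["rs1"]


def test_clump_independent_snps_all_kept(rng):
    df = random_sumstats(rng, 8).assign(pval=rng.uniform(0, 1e-6, 8))
    ld = _ld_from_dense(df["snp"].tolist(), np.eye(8))
    kept = ld_clump(df, ld, InstrumentConfig())
    assert set(kept["snp"]) == set(df["snp"])


def test_clump_missing_rsid_is_hard_failure():
    df = _table([("rsX", "1", 1000, "A", "G", 0.3, 0.3, 0.04, 1e-8, 100)])
    ld = _ld_from_dense(["rs1"], [[1.0]])
    with pytest.raises(KeyError, match="rsX"):
        ld_clump(df, ld, InstrumentConfig())


def _greedy_oracle(df, r2, cfg):
    """Literal restatement of the greedy definition, quadratic and slow."""
    remaining = df.sort_values(
        ["pval", "chr", "pos", "snp"],
        key=lambda s: s.map({"X": 23} | {str(i): i for i in range(1, 23)})
        if s.name == "chr" else s).reset_index(drop=True)
    kept = []
    rows = list(remaining.itertuples(index=False))
    while rows:
        index = rows.pop(0)
        kept.append(index.snp)
        survivors = []
        for r in rows:
            near = (r.chr == index.chr
                    and abs(r.pos - index.pos) <= cfg.clump_window_kb * 1000)
            linked = r2[(index.snp, r.snp)] >= cfg.r2_threshold
            if not (near and linked):
                survivors.append(r)
        rows = survivors
    return kept


@pytest.mark.parametrize("seed", range(8))
def test_clump_matches_step_by_step_oracle(seed):
    rng = np.random.default_rng(seed)
    n = 10
    df = random_sumstats(rng, n)
    df["chr"] = rng.choice(["1", "2"], size=n)
    df["pos"] = rng.integers(1, 50_000, size=n)
    dense = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            dense[i, j] = dense[j, i] = rng.choice([0.0, 0.002, 0.5, 0.9])
    ld = _ld_from_dense(df["snp"].tolist(), dense)
    r2 = {(a, b): dense[i, j] for i, a in enumerate(df["snp"])
          for j, b in enumerate(df["snp"])}
    cfg = InstrumentConfig(p_threshold=1.0, r2_threshold=0.01, clump_window_kb=20)
    got = ld_clump(df, ld, cfg)["snp"].tolist()
    assert got == _greedy_oracle(df, r2, cfg)


def test_clump_output_subset_and_order_invariant(rng):
    df = random_sumstats(rng, 10)
    df["chr"] = "1"
    df["pos"] = rng.integers(1, 5000, size=10)
    dense = np.full((10, 10), 0.3)
    np.fill_diagonal(dense, 1.0)
    ld = _ld_from_dense(df["snp"].tolist(), dense)
    cfg = InstrumentConfig(r2_threshold=0.2)
    kept = ld_clump(df, ld, cfg)
    assert set(kept["snp"]) <= set(df["snp"])
    shuffled = df.sample(frac=1.0, random_state=1)
    assert ld_clump(shuffled, ld, cfg)["snp"].tolist() == kept["snp"].tolist()


def test_clump_degenerate_config_returns_input(rng):
    df = random_sumstats(rng, 6)
    dense = np.full((6, 6), 0.99)
    np.fill_diagonal(dense, 1.0)
    ld = _ld_from_dense(df["snp"].tolist(), dense)
    cfg = InstrumentConfig(r2_threshold=1.0, clump_window_kb=1e-9)
    assert set(ld_clump(df, ld, cfg)["snp"]) == set(df["snp"])


# ---------------------------------------------------------------------------
# harmonization


def _exp_row(snp="rs1", ea="A", oa="G", eaf=0.3, beta=0.1):
    return _table([(snp, "1", 100, ea, oa, eaf, beta, 0.02, 1e-8, 100)])


def _out_row(snp="rs1", ea="A", oa="G", eaf=0.3, beta=-0.2):
    return _table([(snp, "1", 100, ea, oa, eaf, beta, 0.03, 0.5, 100)])


def test_swapped_orientation_flips_outcome_beta():
    h = harmonize(_exp_row(ea="A", oa="G", beta=0.1),
                  _out_row(ea="G", oa="A", beta=-0.2, eaf=0.7),
                  InstrumentConfig())
    row = h.iloc[0]
    assert row["action"] == "flipped"
    assert row["beta_out"] == pytest.approx(0.2)
    assert row["eaf_out"] == pytest.approx(0.3)


def test_strand_complement_resolved_for_non_palindromic():
    # exposure A/G, outcome reported as T/C on the other strand
    h = harmonize(_exp_row(ea="A", oa="G", beta=0.1),
                  _out_row(ea="T", oa="C", beta=0.15), InstrumentConfig())
    assert h.iloc[0]["action"] == "unchanged"
    assert h.iloc[0]["beta_out"] == pytest.approx(0.15)


def test_palindrome_intermediate_frequency_dropped():
    h = harmonize(_exp_row(ea="A", oa="T", eaf=0.50),
                  _out_row(ea="A", oa="T", eaf=0.50), InstrumentConfig())
    assert h.iloc[0]["action"] == "dropped"
    assert h.iloc[0]["drop_reason"] == "palindromic_intermediate_eaf"


def test_palindrome_missing_eaf_policy():
    cfg = InstrumentConfig()
    h = harmonize(_exp_row(ea="A", oa="T", eaf=np.nan),
                  _out_row(ea="A", oa="T", eaf=0.2), cfg)
    assert h.iloc[0]["drop_reason"] == "palindromic_missing_eaf"
    lax = InstrumentConfig(drop_palindromes_with_missing_eaf=False)
    h2 = harmonize(_exp_row(ea="A", oa="T", eaf=np.nan),
                   _out_row(ea="A", oa="T", eaf=0.2), lax)
    assert h2.iloc[0]["action"] == "unchanged"


def test_palindrome_oriented_by_frequency_side():
    cfg = InstrumentConfig()
    same = harmonize(_exp_row(ea="A", oa="T", eaf=0.2, beta=0.1),
                     _out_row(ea="A", oa="T", eaf=0.25, beta=0.3), cfg)
    assert same.iloc[0]["action"] == "unchanged"
    opposite = harmonize(_exp_row(ea="A", oa="T", eaf=0.2, beta=0.1),
                         _out_row(ea="A", oa="T", eaf=0.75, beta=0.3), cfg)
    assert opposite.iloc[0]["action"] == "flipped"
    assert opposite.iloc[0]["beta_out"] == pytest.approx(-0.3)


def test_incompatible_and_absent_variants_dropped():
    h = harmonize(_exp_row(ea="A", oa="G"), _out_row(ea="A", oa="C"),
                  InstrumentConfig())
    assert h.iloc[0]["drop_reason"] == "incompatible_alleles"
    h2 = harmonize(_exp_row(snp="rs1"), _out_row(snp="rs2"), InstrumentConfig())
    assert h2.iloc[0]["drop_reason"] == "absent_from_outcome"


def test_duplicate_rsid_is_hard_failure():
    dup = pd.concat([_exp_row(), _exp_row()], ignore_index=True)
    with pytest.raises(ValueError, match="duplicate"):
        harmonize(dup, _out_row(), InstrumentConfig())


def test_harmonization_recovers_generator_orientation():
    """Harmonized outcome betas equal the generator's truth orientation."""
    cfg = SimConfig(seed=5, m_snps=200, n_exposures=1, n_mediators=0,
                    noiseless=True, pi_instrument=1.0, ld_block_size=1,
                    theta_xm=0.0, theta_my=0.0, n_causal_exposures=1)
    study, truth = simulate_study(cfg)
    exp, out = study.tables["imm_001"], study.tables["om"]
    h = kept_instruments(harmonize(exp, out, InstrumentConfig(p_threshold=1.0)))
    assert len(h) > 100  # palindromic/intermediate drops only
    nonzero = h[h["beta_exp"].abs() > 1e-12]
    ratios = nonzero["beta_out"] / nonzero["beta_exp"]
    om_own = set(truth.instrument_effects["om"])
    clean = nonzero[~nonzero["rsid"].isin(om_own)]
    assert np.allclose(clean["beta_out"] / clean["beta_exp"],
                       truth.causal["imm_001"]["om"])


def test_harmonization_idempotent(rng):
    exp = random_sumstats(rng, 150)
    out = exp.copy()
    out["beta"] = rng.normal(0, 0.1, len(out))
    h1 = kept_instruments(harmonize(exp, out, InstrumentConfig()))
    out2 = h1.rename(columns={"rsid": "snp", "beta_out": "beta",
                              "se_out": "se", "eaf_out": "eaf"})
    out2 = out2.assign(chr="1", pos=np.arange(len(out2)) + 1, pval=0.5, n=100)
    exp2 = exp[exp["snp"].isin(h1["rsid"])]
    h2 = harmonize(exp2, out2[["snp", "chr", "pos", "effect_allele",
                               "other_allele", "eaf", "beta", "se", "pval", "n"]],
                   InstrumentConfig())
    assert (h2["action"] == "unchanged").all()
    assert np.allclose(h2["beta_out"], h1["beta_out"])


def test_harmonization_orientation_invariance(rng):
    """Flipping every outcome row leaves kept pairs identical."""
    exp = random_sumstats(rng, 200)
    out = exp.copy()
    out["beta"] = rng.normal(0, 0.1, len(out))
    cfg = InstrumentConfig()
    h1 = harmonize(exp, out, cfg)
    flipped = out.copy()
    flipped[["effect_allele", "other_allele"]] = out[["other_allele", "effect_allele"]].values
    flipped["beta"] = -out["beta"]
    flipped["eaf"] = 1 - out["eaf"]
    h2 = harmonize(exp, flipped, cfg)
    kept1, kept2 = kept_instruments(h1), kept_instruments(h2)
    assert kept1["rsid"].tolist() == kept2["rsid"].tolist()
    assert np.allclose(kept1["beta_out"], kept2["beta_out"])
    assert np.allclose(kept1["beta_exp"], kept2["beta_exp"])


def test_ld_matrix_validation_and_io(tmp_path):
    with pytest.raises(ValueError, match="symmetric"):
        LDMatrix(["a", "b"], sparse.csr_matrix(np.array([[1.0, 0.5], [0.2, 1.0]])))
    with pytest.raises(ValueError):
        LDMatrix(["a", "b"], sparse.csr_matrix(np.array([[1.0, 1.5], [1.5, 1.0]])))
    ld = LDMatrix(["a", "b", "c"], sparse.csr_matrix(
        np.array([[1, 0.4, 0], [0.4, 1, 0], [0, 0, 1.0]])))
    p = tmp_path / "ld.tsv"
    ld.write(p)
    back = LDMatrix.read(p, ["a", "b", "c"])
    assert back.r2("a", "b") == pytest.approx(0.4)
    assert back.r2("a", "c") == 0.0
    assert back.r2("c", "c") == 1.0
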