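"""Instrument selection and exposure/outcome harmonization.

Instrumental variables for an exposure are chosen by a genome-wide filter
(p below a configurable threshold, default 1e-5) followed by greedy LD
clumping: the remaining variant with the smallest p becomes an index SNP
and every remaining variant on the same chromosome within the clumping
window *and* correlated above the r² cutoff is discarded.  The surviving
index SNPs are approximately independent instruments.

Harmonization aligns each instrument's outcome association onto the
exposure's effect allele, flipping signs for swapped allele labels,
complementing strand-flipped records, and applying the conservative
palindrome policy: A/T and C/G variants are dropped when either allele
frequency is missing (configurable) or intermediate, and otherwise
oriented by matching frequency sides across the two studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Chromosome sort order (1..22 then X).
_CHROM_ORDER = {str(i): i for i in range(1, 23)} | {"X": 23}


@dataclass
class InstrumentConfig:
    """Tunable knobs of instrument selection and harmonization.

    Defaults follow common practice for multi-trait MR screens: IV
    significance 1e-5, clumping at r² < 0.001 within 10,000 kb, and a
    palindrome "intermediate frequency" band of [0.42, 0.58).
    """

    p_threshold: float = 1e-5
    r2_threshold: float = 0.001
    clump_window_kb: float = 10_000.0
    palindrome_eaf_band: tuple[float, float] = (0.42, 0.58)
    drop_palindromes_with_missing_eaf: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold <= 1):
            raise ValueError("p_threshold must be in (0, 1]")
        if not (0 <= self.r2_threshold <= 1):
            raise ValueError("r2_threshold must be in [0, 1]")
        if self.clump_window_kb <= 0:
            raise ValueError("clump_window_kb must be positive")
        lo, hi = self.palindrome_eaf_band
        if not (0 < lo <= 0.5 <= hi < 1):
            raise ValueError("palindrome_eaf_band must lie in (0,1) and contain 0.5")


class LDMatrix:
    """Pairwise squared-correlation structure over an ordered variant list.

    Stored sparsely (absent pair => r² = 0) with an exactly unit diagonal.
    Symmetry and range are enforced at construction.
    """

    def __init__(self, rsids: list[str], r2: sparse.spmatrix):
        r2 = sparse.csr_matrix(r2)
        if r2.shape != (len(rsids), len(rsids)):
            raise ValueError("r2 shape does not match rsid list")
        if r2.nnz and ((r2.data < 0).any() or (r2.data > 1).any()):
            raise ValueError("r2 entries must lie in [0, 1]")
        if (abs(r2 - r2.T) > 1e-12).nnz:
            raise ValueError("r2 matrix must be symmetric")
        r2 = r2.tolil()
        r2.setdiag(1.0)
        self.rsids = list(rsids)
        self._index = {rs: i for i, rs in enumerate(self.rsids)}
        if len(self._index) != len(self.rsids):
            raise ValueError("duplicate rsids in LD matrix")
        self._r2 = r2.tocsr()

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index

    def r2(self, a: str, b: str) -> float:
        try:
            i, j = self._index[a], self._index[b]
        except KeyError as exc:
            raise KeyError(f"rsid {exc.args[0]!r} absent from LD matrix") from None
        return float(self._r2[i, j])

    def r2_row(self, a: str, others: list[str]) -> np.ndarray:
        """r² of ``a`` against each of ``others`` (vectorised lookup)."""
        try:
            i = self._index[a]
        except KeyError:
            raise KeyError(f"rsid {a!r} absent from LD matrix") from None
        row = self._r2.getrow(i).toarray().ravel()
        idx = []
        for b in others:
            try:
                idx.append(self._index[b])
            except KeyError:
                raise KeyError(f"rsid {b!r} absent from LD matrix") from None
        return row[idx]

    @classmethod
    def from_pairs(cls, rsids: list[str], pairs: pd.DataFrame) -> "LDMatrix":
        """Build from a sparse pair table with columns rsid_a, rsid_b, r2."""
        index = {rs: i for i, rs in enumerate(rsids)}
        rows, cols, vals = [], [], []
        for a, b, v in pairs[["rsid_a", "rsid_b", "r2"]].itertuples(index=False):
            i, j = index[a], index[b]
            rows += [i, j]
            cols += [j, i]
            vals += [float(v), float(v)]
        m = sparse.coo_matrix((vals, (rows, cols)), shape=(len(rsids), len(rsids)))
        m = m.tocsr()
        m.data = np.minimum(m.data, 1.0)  # duplicated pair rows may have summed
        return cls(rsids, m)

    def to_pairs(self) -> pd.DataFrame:
        coo = sparse.triu(self._r2, k=1).tocoo()
        return pd.DataFrame({
            "rsid_a": [self.rsids[i] for i in coo.row],
            "rsid_b": [self.rsids[j] for j in coo.col],
            "r2": coo.data,
        })

    def write(self, path: str | Path) -> None:
        """Write the sparse upper triangle as a rsid_a/rsid_b/r2 TSV."""
        df = self.to_pairs()
        lines = ["rsid_a\trsid_b\tr2"]
        for a, b, v in df.itertuples(index=False):
            lines.append(f"{a}\t{b}\t{format(float(v), '.10g')}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def read(cls, path: str | Path, rsids: list[str]) -> "LDMatrix":
        pairs = pd.read_csv(path, sep="\t")
        return cls.from_pairs(rsids, pairs)


def select_candidates(exposure: pd.DataFrame, cfg: InstrumentConfig) -> pd.DataFrame:
    """Keep rows significant at cfg.p_threshold, ordered by (pval, chr, pos)."""
    kept = exposure[exposure["pval"] < cfg.p_threshold].copy()
    kept["_chrom_order"] = kept["chr"].map(_CHROM_ORDER)
    kept = kept.sort_values(["pval", "_chrom_order", "pos", "snp"], kind="mergesort")
    return kept.drop(columns="_chrom_order").reset_index(drop=True)


def ld_clump(candidates: pd.DataFrame, ld: LDMatrix, cfg: InstrumentConfig) -> pd.DataFrame:
    """Greedy lowest-p clumping.

    Repeatedly takes the remaining variant with the smallest p as an index
    SNP and discards every remaining variant on the same chromosome within
    ``clump_window_kb`` *and* with r² >= ``r2_threshold`` against it.  Ties
    on p break by (chr, pos) then rsid, so output is order-invariant.
    """
    if candidates.empty:
        return candidates.reset_index(drop=True)
    for rs in candidates["snp"]:
        if rs not in ld:
            raise KeyError(f"rsid {rs!r} absent from LD matrix")
    ordered = candidates.copy()
    ordered["_chrom_order"] = ordered["chr"].map(_CHROM_ORDER)
    ordered = ordered.sort_values(["pval", "_chrom_order", "pos", "snp"], kind="mergesort")
    ordered = ordered.drop(columns="_chrom_order").reset_index(drop=True)

    window_bp = cfg.clump_window_kb * 1000.0
    alive = np.ones(len(ordered), dtype=bool)
    keep_idx: list[int] = []
    chroms = ordered["chr"].to_numpy()
    poss = ordered["pos"].to_numpy(float)
    snps = ordered["snp"].tolist()
    for i in range(len(ordered)):
        if not alive[i]:
            continue
        keep_idx.append(i)
        alive[i] = False
        rest = np.flatnonzero(alive)
        if rest.size == 0:
            break
        same_chrom = chroms[rest] == chroms[i]
        near = np.abs(poss[rest] - poss[i]) <= window_bp
        cand = rest[same_chrom & near]
        if cand.size:
            r2 = ld.r2_row(snps[i], [snps[j] for j in cand])
            alive[cand[r2 >= cfg.r2_threshold]] = False
    return ordered.iloc[keep_idx].reset_index(drop=True)


def _is_palindromic(a1: str, a2: str) -> bool:
    return COMPLEMENT[a1] == a2


def harmonize(exposure_iv: pd.DataFrame, outcome: pd.DataFrame,
              cfg: InstrumentConfig) -> pd.DataFrame:
    """Align outcome associations onto the exposure's effect alleles.

    Returns one row per exposure instrument with columns ``rsid,
    effect_allele, other_allele, beta_exp, se_exp, eaf_exp, beta_out,
    se_out, eaf_out, action, drop_reason`` where action is one of
    ``unchanged``, ``flipped``, ``dropped``.  Matching is by rsid.

    Cases: identical allele pair same orientation -> unchanged; swapped
    orientation -> outcome beta negated and eaf complemented; strand
    complement of a non-palindromic pair -> complement, then as above;
    palindromic pair -> dropped on missing (when configured) or
    intermediate frequency, else oriented by frequency side; any other
    allele pair -> dropped as incompatible.
    """
    for name, df in (("exposure", exposure_iv), ("outcome", outcome)):
        dup = df["snp"][df["snp"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate rsid {dup.iloc[0]!r} in {name} table")

    lo, hi = cfg.palindrome_eaf_band
    out_by_snp = outcome.set_index("snp")
    rows = []
    for exp in exposure_iv.itertuples(index=False):
        rec = {
            "rsid": exp.snp, "effect_allele": exp.effect_allele,
            "other_allele": exp.other_allele,
            "beta_exp": exp.beta, "se_exp": exp.se, "eaf_exp": exp.eaf,
            "beta_out": np.nan, "se_out": np.nan, "eaf_out": np.nan,
            "action": "dropped", "drop_reason": None,
        }
        if exp.snp not in out_by_snp.index:
            rec["drop_reason"] = "absent_from_outcome"
            rows.append(rec)
            continue
        out = out_by_snp.loc[exp.snp]
        ea_x, oa_x = exp.effect_allele, exp.other_allele
        ea_y, oa_y = out["effect_allele"], out["other_allele"]
        beta_y, se_y, eaf_y = float(out["beta"]), float(out["se"]), out["eaf"]
        eaf_y = float(eaf_y) if pd.notna(eaf_y) else np.nan
        eaf_x = float(exp.eaf) if pd.notna(exp.eaf) else np.nan

        pal = _is_palindromic(ea_x, oa_x)
        pair_x = {ea_x, oa_x}
        if {ea_y, oa_y} == pair_x:
            matched = True
        elif not pal and {COMPLEMENT[ea_y], COMPLEMENT[oa_y]} == pair_x:
            # outcome reported on the other strand: complement its labels
            ea_y, oa_y = COMPLEMENT[ea_y], COMPLEMENT[oa_y]
            matched = True
        else:
            matched = False
        if not matched:
            rec["drop_reason"] = "incompatible_alleles"
            rows.append(rec)
            continue

        if pal:
            if np.isnan(eaf_x) or np.isnan(eaf_y):
                if cfg.drop_palindromes_with_missing_eaf:
                    rec["drop_reason"] = "palindromic_missing_eaf"
                    rows.append(rec)
                    continue
                flip = ea_y != ea_x  # trust labels when frequency is unusable
            elif (lo <= eaf_x < hi) or (lo <= eaf_y < hi):
                rec["drop_reason"] = "palindromic_intermediate_eaf"
                rows.append(rec)
                continue
            else:
                # strand-proof orientation: frequencies on the same side of
                # 0.5 mean the effect alleles already agree
                flip = (eaf_x < 0.5) != (eaf_y < 0.5)
        else:
            flip = ea_y != ea_x

        if flip:
            beta_y = -beta_y
            eaf_y = 1.0 - eaf_y if not np.isnan(eaf_y) else np.nan
        rec.update(beta_out=beta_y, se_out=se_y, eaf_out=eaf_y,
                   action="flipped" if flip else "unchanged")
        rows.append(rec)

    result = pd.DataFrame(rows, columns=[
        "rsid", "effect_allele", "other_allele", "beta_exp", "se_exp",
        "eaf_exp", "beta_out", "se_out", "eaf_out", "action", "drop_reason",
    ])
    return result


def kept_instruments(harmonized: pd.DataFrame) -> pd.DataFrame:
    """Rows of a harmonized table that survived (action != dropped)."""
    return harmonized[harmonized["action"] != "dropped"].reset_index(drop=True)
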