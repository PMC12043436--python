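"""Reading, validating and writing per-trait GWAS summary-statistics tables.

A summary-statistics table is a :class:`pandas.DataFrame` in a strict
tab-separated dialect: UTF-8, one header line, canonical column names
``snp, chr, pos, effect_allele, other_allele, eaf, beta, se, pval, n``.
Common aliases (``rsid`` for ``snp``, ``p`` for ``pval``, ...) are accepted
case-insensitively on read.  Positions are 1-based GRCh37.  Only biallelic
single-nucleotide variants are accepted: indels and multi-allelic records
are rejected at read time because downstream strand/palindrome logic is
defined only for single bases.

Validation is total: every input row is either accepted (satisfying all
record invariants) or rejected with a reason, and the two counts add up to
the input row count.  The dropped-row tally is attached to the returned
frame as ``df.attrs["n_dropped"]`` and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml
from scipy import stats

logger = logging.getLogger(__name__)

#: Canonical column order of the dialect.
CANONICAL_COLUMNS = [
    "snp", "chr", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]

#: Columns that must be present (possibly via alias) and non-missing per row.
MANDATORY_COLUMNS = [
    "snp", "chr", "pos", "effect_allele", "other_allele", "beta", "se", "pval",
]

#: Case-insensitive header aliases mapped onto the canonical names.
COLUMN_ALIASES = {
    "rsid": "snp", "variant_id": "snp", "markername": "snp", "id": "snp",
    "chrom": "chr", "chromosome": "chr",
    "bp": "pos", "position": "pos", "base_pair_location": "pos",
    "a1": "effect_allele", "ea": "effect_allele", "allele1": "effect_allele",
    "a2": "other_allele", "oa": "other_allele", "nea": "other_allele",
    "allele0": "other_allele", "allele2": "other_allele",
    "effect_allele_frequency": "eaf", "freq": "eaf", "af": "eaf", "maf": "eaf",
    "b": "beta", "effect": "beta",
    "stderr": "se", "standard_error": "se",
    "p": "pval", "pvalue": "pval", "p_value": "pval",
    "sample_size": "n", "nsample": "n",
}

VALID_CHROMS = frozenset([str(i) for i in range(1, 23)] + ["X"])
BASES = frozenset("ACGT")

#: Smallest p-value the dialect stores; guards log/underflow arithmetic.
P_FLOOR = 1e-300


@dataclass
class TraitMeta:
    """Metadata sidecar for one trait's GWAS.

    ``family`` is one of ``immunophenotype`` (quantitative immune-cell
    trait), ``inflammatory_protein`` (circulating protein level) or
    ``disease`` (binary outcome on the log-odds scale).  Immunophenotypes
    carry a ``subtype`` — AC (absolute cell count), MFI (median
    fluorescence intensity), MP (morphological parameter) or RC (relative
    cell count); case/control counts are meaningful only for diseases.
    """

    trait_id: str
    label: str
    family: str
    subtype: str | None = None
    n_cases: int | None = None
    n_controls: int | None = None
    ancestry: str = "European"

    def __post_init__(self) -> None:
        if self.family not in {"immunophenotype", "inflammatory_protein", "disease"}:
            raise ValueError(f"unknown trait family {self.family!r}")
        if self.family == "disease":
            if not (self.n_cases and self.n_cases >= 1 and self.n_controls and self.n_controls >= 1):
                raise ValueError("disease traits require n_cases >= 1 and n_controls >= 1")
        if self.subtype is not None and self.family != "immunophenotype":
            raise ValueError("subtype is only meaningful for immunophenotypes")
        if self.family == "immunophenotype" and self.subtype is not None:
            if self.subtype not in {"AC", "MFI", "MP", "RC"}:
                raise ValueError(f"unknown immunophenotype subtype {self.subtype!r}")


def _canonicalize_header(columns: Iterable[str]) -> dict[str, str]:
    """Map raw header names to canonical ones, case-insensitively."""
    mapping = {}
    for col in columns:
        low = col.strip().lower()
        canonical = COLUMN_ALIASES.get(low, low)
        if canonical in CANONICAL_COLUMNS:
            mapping[col] = canonical
    return mapping


def validate_records(df: pd.DataFrame, trait_id: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a raw table into accepted records and rejected rows with reasons.

    Accepted rows satisfy every record invariant: single-base distinct
    alleles, chr in 1–22/X, integer pos >= 1, se > 0, pval in (0, 1],
    eaf missing or in [0, 1], and (snp) unique within the table.
    """
    df = df.copy()
    reasons = pd.Series("", index=df.index, dtype=object)

    def _flag(mask: pd.Series, reason: str) -> None:
        fresh = mask & (reasons == "")
        reasons[fresh] = reason

    for col in ("eaf", "n"):
        if col not in df.columns:
            df[col] = np.nan
    for col in ("pos", "eaf", "beta", "se", "pval", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("snp", "chr", "effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.strip()
    df["effect_allele"] = df["effect_allele"].str.upper()
    df["other_allele"] = df["other_allele"].str.upper()

    _flag(~df["chr"].isin(VALID_CHROMS), "invalid_chromosome")
    _flag(df["pos"].isna() | (df["pos"] < 1) | (df["pos"] % 1 != 0), "invalid_position")
    _flag(~df["effect_allele"].isin(BASES), "non_snv_effect_allele")
    _flag(~df["other_allele"].isin(BASES), "non_snv_other_allele")
    _flag(df["effect_allele"] == df["other_allele"], "identical_alleles")
    _flag(df["beta"].isna(), "unparseable_beta")
    _flag(df["se"].isna() | (df["se"] <= 0), "nonpositive_se")
    _flag(df["pval"].isna() | (df["pval"] <= 0) | (df["pval"] > 1), "pval_out_of_range")
    _flag(df["eaf"].notna() & ((df["eaf"] < 0) | (df["eaf"] > 1)), "eaf_out_of_range")
    _flag(df["snp"].duplicated(keep="first"), "duplicate_rsid")

    bad = reasons != ""
    rejected = df.loc[bad].copy()
    rejected["reason"] = reasons[bad]
    accepted = df.loc[~bad].copy()
    accepted["pos"] = accepted["pos"].astype(np.int64)
    accepted["trait_id"] = trait_id
    accepted = accepted[CANONICAL_COLUMNS + ["trait_id"]].reset_index(drop=True)
    return accepted, rejected


def read_summary_stats(path: str | Path, trait_id: str) -> pd.DataFrame:
    """Read one trait's summary statistics, validating every row.

    Returns the accepted records in input order with the number of dropped
    malformed rows in ``df.attrs["n_dropped"]``.  A missing mandatory
    column is a hard failure naming the column; a malformed row (bad
    allele, non-positive se, out-of-range p, ...) is rejected and logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA", "na", ""])
    raw = raw.rename(columns=_canonicalize_header(raw.columns))
    missing = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s) {missing} in {path}")
    accepted, rejected = validate_records(raw, trait_id)
    if len(rejected):
        counts = rejected["reason"].value_counts().to_dict()
        logger.warning("%s: dropped %d malformed row(s): %s", path.name, len(rejected), counts)
    accepted.attrs["n_dropped"] = int(len(rejected))
    accepted.attrs["source"] = str(path)
    return accepted


def _format_value(x: object) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return "NA"
    if isinstance(x, (float, np.floating)):
        return format(float(x), ".10g")
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    return str(x)


def write_summary_stats(records: pd.DataFrame, path: str | Path) -> None:
    """Write records in the canonical dialect (10-significant-digit floats).

    Numeric formatting is deterministic, so identical tables produce
    byte-identical files; a written file reads back to an equal table.
    """
    path = Path(path)
    cols = [c for c in CANONICAL_COLUMNS if c in records.columns]
    lines = ["\t".join(cols)]
    for row in records[cols].itertuples(index=False):
        lines.append("\t".join(_format_value(v) for v in row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def zscore_consistency_check(records: pd.DataFrame, tol: float = 0.05) -> list[str]:
    """Flag rows whose stored p disagrees with the p implied by beta/se.

    The implied p is the two-sided normal tail 2*Phi(-|beta/se|); a row is
    flagged when the relative discrepancy exceeds ``tol``.  Purely a sanity
    gate before estimation — flags never alter the data.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    z = np.abs(records["beta"].to_numpy() / records["se"].to_numpy())
    implied = np.clip(2.0 * stats.norm.sf(z), P_FLOOR, 1.0)
    stored = np.clip(records["pval"].to_numpy(float), P_FLOOR, 1.0)
    rel = np.abs(implied - stored) / stored
    return list(records.loc[rel > tol, "snp"])


# ---------------------------------------------------------------------------
# Trait metadata sidecar


def write_trait_meta(metas: list[TraitMeta], path: str | Path) -> None:
    """Write trait metadata as a deterministic YAML sidecar."""
    payload = []
    for m in sorted(metas, key=lambda m: m.trait_id):
        entry = {"trait_id": m.trait_id, "label": m.label, "family": m.family,
                 "ancestry": m.ancestry}
        if m.subtype is not None:
            entry["subtype"] = m.subtype
        if m.family == "disease":
            entry["n_cases"] = m.n_cases
            entry["n_controls"] = m.n_controls
        payload.append(entry)
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True), encoding="utf-8")


def read_trait_meta(path: str | Path) -> list[TraitMeta]:
    payload = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or []
    return [TraitMeta(**entry) for entry in payload]
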