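"""Orchestration of the full bidirectional MR screen.

For every exposure–outcome pair the screen runs instrument selection,
greedy LD clumping, harmonization, the five estimators (Wald/IVW,
MR-Egger, weighted and simple median), Cochran's Q with I², and the
Egger-intercept pleiotropy test.  The IVW p-value drives multiplicity
control: a family-wise Bonferroni threshold alpha = 0.05/n_families
(default 2 families: immunophenotypes and inflammatory proteins, so
0.025) and Benjamini–Hochberg FDR, applied per family by default.

Significance tiers: ``bonferroni_significant`` passes both the Bonferroni
threshold and FDR; ``fdr_significant`` passes FDR only; ``marginal``
passes the Bonferroni threshold but fails FDR (the screen's "marginally
significant" rule); ``null`` otherwise.  The reverse direction swaps
exposure and outcome roles; mediation and MVMR steps build on the
forward results.  Everything is deterministic given the configured seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import __version__
from .instruments import (InstrumentConfig, LDMatrix, harmonize,
                          kept_instruments, ld_clump, select_candidates)
from .mediation import mediation_screen
from .mr_core import (InsufficientInstruments, MREstimate, cochran_q, ivw,
                      mr_egger, simple_median, weighted_median)
from .mvmr import mvmr_estimate
from .synthetic import StudyData

logger = logging.getLogger(__name__)

_TIERS = ["bonferroni_significant", "fdr_significant", "marginal", "null"]


@dataclass
class ScreenConfig:
    """Configuration of one screening run."""

    exposure_families: list[str] = field(
        default_factory=lambda: ["immunophenotype", "inflammatory_protein"])
    outcome_id: str = "om"
    direction: str = "forward"  # forward | reverse | both
    bonferroni_families: int = 2
    fdr_alpha: float = 0.05
    genomewide_alpha: float = 5e-8
    fdr_pooled: bool = False
    mediation_screen_p: float = 0.05
    seed: int = 0
    n_boot: int = 1000
    effects_model: str = "multiplicative_random"
    instruments: InstrumentConfig = field(default_factory=InstrumentConfig)
    reverse_instruments: InstrumentConfig | None = None

    def __post_init__(self) -> None:
        if not (0 < self.fdr_alpha < 1):
            raise ValueError("fdr_alpha must be in (0, 1)")
        if self.bonferroni_families < 1:
            raise ValueError("bonferroni_families must be >= 1")
        if self.direction not in {"forward", "reverse", "both"}:
            raise ValueError(f"unknown direction {self.direction!r}")

    @property
    def bonferroni_alpha(self) -> float:
        return 0.05 / self.bonferroni_families


def bh_fdr(pvals: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    pvals = np.asarray(pvals, float)
    if pvals.size == 0:
        return pvals
    if np.any((pvals <= 0) | (pvals > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def analyse_pair(exposure: pd.DataFrame, outcome: pd.DataFrame, ld: LDMatrix,
                 cfg: ScreenConfig,
                 icfg: InstrumentConfig | None = None) -> dict:
    """Select, clump, harmonize and estimate for one exposure–outcome pair.

    Returns a flat record with all estimates, diagnostics, stage counts
    and withheld-method reasons; raises nothing for below-minimum
    instrument counts (those are recorded as withheld).
    """
    icfg = icfg or cfg.instruments
    candidates = select_candidates(exposure, icfg)
    clumped = ld_clump(candidates, ld, icfg)
    harm = harmonize(clumped, outcome, icfg)
    kept = kept_instruments(harm)
    rec: dict = {
        "n_candidates": len(candidates), "n_clumped": len(clumped),
        "n_harmonized": len(kept), "withheld": [],
    }
    estimators = {
        "ivw": lambda d: ivw(d, effects_model=cfg.effects_model),
        "mr_egger": lambda d: mr_egger(d)[0],
        "weighted_median": lambda d: weighted_median(d, cfg.n_boot, cfg.seed),
        "simple_median": lambda d: simple_median(d, cfg.n_boot, cfg.seed),
    }
    for name, fn in estimators.items():
        try:
            est = fn(kept)
        except InsufficientInstruments:
            rec["withheld"].append(name)
            continue
        rec[name] = est
    try:
        rec["heterogeneity"] = cochran_q(kept)
    except InsufficientInstruments:
        rec["withheld"].append("cochran_q")
    try:
        rec["pleiotropy"] = mr_egger(kept)[1]
    except InsufficientInstruments:
        if "mr_egger" not in rec["withheld"]:
            rec["withheld"].append("egger_intercept")
    return rec


def _flatten(rec: dict, exposure_id: str, outcome_id: str, family: str) -> dict:
    row = {
        "exposure": exposure_id, "outcome": outcome_id, "family": family,
        "n_candidates": rec["n_candidates"], "n_clumped": rec["n_clumped"],
        "nsnp": rec["n_harmonized"], "withheld": ";".join(rec["withheld"]),
    }
    for name in ("ivw", "mr_egger", "weighted_median", "simple_median"):
        est: MREstimate | None = rec.get(name)
        prefix = {"ivw": "ivw", "mr_egger": "egger",
                  "weighted_median": "wmedian", "simple_median": "smedian"}[name]
        if est is None:
            row.update({f"{prefix}_{f}": np.nan for f in
                        ("beta", "se", "or", "ci_low", "ci_high", "pval")})
        else:
            row.update({f"{prefix}_beta": est.beta, f"{prefix}_se": est.se,
                        f"{prefix}_or": est.or_, f"{prefix}_ci_low": est.ci_low,
                        f"{prefix}_ci_high": est.ci_high, f"{prefix}_pval": est.pval})
    het = rec.get("heterogeneity")
    row.update({"q": het.q if het else np.nan, "q_df": het.df if het else np.nan,
                "q_pval": het.pval if het else np.nan,
                "i2": het.i2 if het else np.nan,
                "het_label": het.label if het else ""})
    pl = rec.get("pleiotropy")
    row.update({"egger_intercept": pl.egger_intercept if pl else np.nan,
                "egger_intercept_se": pl.se if pl else np.nan,
                "egger_intercept_pval": pl.pval if pl else np.nan})
    return row


def assign_tiers(results: pd.DataFrame, cfg: ScreenConfig) -> pd.DataFrame:
    """Attach FDR-adjusted p-values and significance tiers (IVW-driven)."""
    results = results.copy()
    results["fdr_pval"] = np.nan
    groups = [results.index] if cfg.fdr_pooled else [
        idx for _, idx in results.groupby("family").groups.items()]
    for idx in groups:
        sub = results.loc[idx]
        ok = sub["ivw_pval"].notna()
        if ok.any():
            results.loc[sub.index[ok], "fdr_pval"] = bh_fdr(sub.loc[ok, "ivw_pval"].to_numpy())
    bonf = results["ivw_pval"] < cfg.bonferroni_alpha
    fdr = results["fdr_pval"] < cfg.fdr_alpha
    tier = np.select(
        [bonf & fdr, fdr & ~bonf, bonf & ~fdr],
        ["bonferroni_significant", "fdr_significant", "marginal"],
        default="null")
    tier = np.where(results["ivw_pval"].isna(), "failed", tier)
    results["tier"] = tier
    return results


def run_screen(cfg: ScreenConfig, study: StudyData | str | Path) -> pd.DataFrame:
    """Run the configured screen over every exposure–outcome pair.

    ``direction="forward"`` tests each family trait on the outcome;
    ``"reverse"`` tests the outcome on each trait; ``"both"`` runs forward
    then reverse restricted to forward pairs with raw IVW p < 0.05.
    A pair whose analysis fails is recorded with reason and skipped.
    """
    if not isinstance(study, StudyData):
        from .synthetic import load_study
        study = load_study(study)
    outcome_id = cfg.outcome_id
    if outcome_id not in study.tables:
        raise KeyError(f"outcome trait {outcome_id!r} not in study")
    exposures = [t for fam in cfg.exposure_families for t in study.family(fam)]
    fam_of = {m.trait_id: m.family for m in study.meta}

    def one_direction(pairs: list[tuple[str, str]], icfg: InstrumentConfig,
                      direction: str) -> pd.DataFrame:
        rows = []
        for exp_id, out_id in pairs:
            if exp_id == out_id:
                raise ValueError(f"self-causation screen refused for {exp_id!r}")
            try:
                rec = analyse_pair(study.tables[exp_id], study.tables[out_id],
                                   study.ld, cfg, icfg)
            except (ValueError, KeyError, ZeroDivisionError) as exc:
                logger.warning("pair %s -> %s aborted: %s", exp_id, out_id, exc)
                rows.append({"exposure": exp_id, "outcome": out_id,
                             "family": fam_of.get(exp_id, ""), "error": str(exc)})
                continue
            fam = fam_of.get(exp_id if direction == "forward" else out_id, "")
            row = _flatten(rec, exp_id, out_id, fam)
            row["direction"] = direction
            rows.append(row)
        return pd.DataFrame(rows)

    frames = []
    if cfg.direction in {"forward", "both"}:
        fwd = one_direction([(e, outcome_id) for e in exposures],
                            cfg.instruments, "forward")
        if len(fwd):
            fwd = assign_tiers(fwd, cfg)
        frames.append(fwd)
    if cfg.direction == "reverse":
        rev = one_direction([(outcome_id, e) for e in exposures],
                            cfg.reverse_instruments or cfg.instruments, "reverse")
        if len(rev):
            rev = assign_tiers(rev, cfg)
        frames.append(rev)
    elif cfg.direction == "both":
        fwd = frames[0]
        hits = fwd.loc[fwd.get("ivw_pval", pd.Series(dtype=float)) < 0.05, "exposure"]
        if len(hits):
            rev = one_direction([(outcome_id, e) for e in hits],
                                cfg.reverse_instruments or cfg.instruments, "reverse")
            if len(rev):
                rev = assign_tiers(rev, cfg)
            frames.append(rev)
    result = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    if result.empty or ("ivw_pval" in result and result["ivw_pval"].isna().all()):
        if result.empty:
            raise RuntimeError("screen produced no results")
    return result


def ivw_store(screen: pd.DataFrame) -> dict[tuple[str, str], MREstimate]:
    """Map (exposure, outcome) -> IVW estimate from a screen table."""
    store: dict[tuple[str, str], MREstimate] = {}
    for row in screen.itertuples(index=False):
        pval = getattr(row, "ivw_pval", np.nan)
        if pd.isna(pval):
            continue
        store[(row.exposure, row.outcome)] = MREstimate(
            "ivw", row.ivw_beta, row.ivw_se, pval, int(row.nsnp))
    return store


def run_mediation(cfg: ScreenConfig, study: StudyData,
                  forward: pd.DataFrame) -> pd.DataFrame:
    """Two-step mediation over cross-family pairs screened in at p < 0.05.

    Candidate (exposure, mediator) pairs cross the two families in both
    directions among traits whose forward outcome leg has raw IVW
    p < ``mediation_screen_p``; the exposure->mediator and
    mediator->outcome legs are estimated on demand.
    """
    p0 = cfg.mediation_screen_p
    sig = forward[(forward["direction"] == "forward")
                  & (forward["ivw_pval"] < p0)]
    by_family: dict[str, list[str]] = {}
    for row in sig.itertuples(index=False):
        by_family.setdefault(row.family, []).append(row.exposure)
    fams = list(by_family)
    pairs: list[tuple[str, str]] = []
    for fa in fams:
        for fb in fams:
            if fa == fb:
                continue
            for e in by_family[fa]:
                for m_ in by_family[fb]:
                    pairs.append((e, m_))
    store = ivw_store(forward)
    for e, m_ in pairs:
        for a, b in ((e, m_), (m_, cfg.outcome_id)):
            if (a, b) in store:
                continue
            try:
                rec = analyse_pair(study.tables[a], study.tables[b], study.ld, cfg)
            except (ValueError, KeyError, ZeroDivisionError) as exc:
                logger.warning("mediation leg %s -> %s aborted: %s", a, b, exc)
                continue
            if "ivw" in rec:
                store[(a, b)] = rec["ivw"]
    return mediation_screen(pairs, cfg.outcome_id, store, screen_p=p0)


def run_mvmr(cfg: ScreenConfig, study: StudyData,
             mediation: pd.DataFrame) -> pd.DataFrame:
    """Mediator-adjusted MVMR for every triple in the mediation table."""
    rows = []
    for trip in mediation.itertuples(index=False):
        tables = {trip.exposure_id: study.tables[trip.exposure_id],
                  trip.mediator_id: study.tables[trip.mediator_id]}
        try:
            res = mvmr_estimate(tables, study.tables[cfg.outcome_id], study.ld,
                                cfg.instruments, effects_model=cfg.effects_model)
        except (InsufficientInstruments, np.linalg.LinAlgError) as exc:
            logger.warning("MVMR for (%s, %s) withheld: %s",
                           trip.exposure_id, trip.mediator_id, exc)
            continue
        focal = res.estimates.iloc[0]
        rows.append({
            "exposure": trip.exposure_id, "adjusted_for": trip.mediator_id,
            "nsnp": res.n_snp, "beta": focal["beta"], "se": focal["se"],
            "or": focal["or"], "ci_low": focal["ci_low"],
            "ci_high": focal["ci_high"], "pval": focal["pval"],
        })
    return pd.DataFrame(rows, columns=["exposure", "adjusted_for", "nsnp", "beta",
                                       "se", "or", "ci_low", "ci_high", "pval"])


def extract_significant_loci(tables: dict[str, pd.DataFrame],
                             alpha: float = 5e-8) -> pd.DataFrame:
    """Genome-wide-significant loci per trait, deduplicated, sorted by p."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    rows = []
    for trait_id, df in tables.items():
        hits = df[df["pval"] < alpha]
        for row in hits.itertuples(index=False):
            rows.append({"trait_id": trait_id, "rsid": row.snp,
                         "chrom": row.chr, "pos": row.pos, "pval": row.pval})
    loci = pd.DataFrame(rows, columns=["trait_id", "rsid", "chrom", "pos", "pval"])
    loci = loci.drop_duplicates(subset=["trait_id", "rsid"])
    return loci.sort_values("pval", kind="mergesort").reset_index(drop=True)


def _write_tsv(df: pd.DataFrame, path: Path, float_format: str = "%.6g") -> None:
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def render_report(out_dir: str | Path, screen: pd.DataFrame | None = None,
                  mediation: pd.DataFrame | None = None,
                  mvmr: pd.DataFrame | None = None,
                  loci: pd.DataFrame | None = None,
                  cfg: ScreenConfig | None = None) -> dict[str, Path]:
    """Write the report tables and run metadata.

    Emits a forest-style estimates TSV, a heterogeneity/pleiotropy
    diagnostics TSV, a mediation TSV (percent scale), the MVMR TSV, the
    loci TSV and a metadata JSON with seed, config hash and versions.
    Deterministic: identical inputs give byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    if screen is not None:
        forest_cols = ["exposure", "outcome", "direction", "family", "nsnp"]
        for prefix in ("ivw", "egger", "wmedian", "smedian"):
            forest_cols += [f"{prefix}_{f}" for f in
                            ("beta", "se", "or", "ci_low", "ci_high", "pval")]
        forest_cols += ["fdr_pval", "tier"]
        cols = [c for c in forest_cols if c in screen.columns]
        written["forest"] = out_dir / "mr_estimates.tsv"
        _write_tsv(screen[cols], written["forest"])
        diag_cols = [c for c in ["exposure", "outcome", "direction", "nsnp", "q",
                                 "q_df", "q_pval", "i2", "het_label",
                                 "egger_intercept", "egger_intercept_se",
                                 "egger_intercept_pval"] if c in screen.columns]
        written["diagnostics"] = out_dir / "diagnostics.tsv"
        _write_tsv(screen[diag_cols], written["diagnostics"])

    med_out = pd.DataFrame(columns=["exposure", "mediating", "proportion_pct",
                                    "ci_low_pct", "ci_high_pct", "pval", "type"])
    if mediation is not None and len(mediation):
        med_out = pd.DataFrame({
            "exposure": mediation["exposure_id"],
            "mediating": mediation["mediator_id"],
            "proportion_pct": 100.0 * mediation["theta"],
            "ci_low_pct": 100.0 * mediation["ci_low"],
            "ci_high_pct": 100.0 * mediation["ci_high"],
            "pval": mediation["pval"],
            "type": mediation["mtype"].str.capitalize(),
        })
    written["mediation"] = out_dir / "mediation.tsv"
    _write_tsv(med_out, written["mediation"])

    if mvmr is not None:
        written["mvmr"] = out_dir / "mvmr.tsv"
        _write_tsv(mvmr, written["mvmr"])
    if loci is not None:
        written["loci"] = out_dir / "significant_loci.tsv"
        _write_tsv(loci, written["loci"])

    meta = {"package": "mrscreen", "version": __version__}
    if cfg is not None:
        cfg_dict = asdict(cfg)
        meta["seed"] = cfg.seed
        meta["config"] = cfg_dict
        meta["config_sha256"] = hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()).hexdigest()
    written["metadata"] = out_dir / "run_metadata.json"
    written["metadata"].write_text(json.dumps(meta, sort_keys=True, indent=1,
                                              default=str), encoding="utf-8")
    return written


def run_all(cfg: ScreenConfig, study: StudyData,
            out_dir: str | Path | None = None) -> dict[str, pd.DataFrame]:
    """Forward + reverse screen, mediation, MVMR, loci, optional report."""
    cfg_both = cfg if cfg.direction == "both" else ScreenConfig(
        **{**asdict_shallow(cfg), "direction": "both"})
    screen = run_screen(cfg_both, study)
    forward = screen[screen["direction"] == "forward"]
    mediation = run_mediation(cfg_both, study, forward)
    mvmr_table = run_mvmr(cfg_both, study, mediation)
    loci = extract_significant_loci(study.tables, cfg.genomewide_alpha)
    if out_dir is not None:
        render_report(out_dir, screen=screen, mediation=mediation,
                      mvmr=mvmr_table, loci=loci, cfg=cfg_both)
    return {"screen": screen, "mediation": mediation, "mvmr": mvmr_table,
            "loci": loci}


def asdict_shallow(cfg: ScreenConfig) -> dict:
    """dataclasses.asdict without recursing into nested configs."""
    return {f: getattr(cfg, f) for f in cfg.__dataclass_fields__}
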