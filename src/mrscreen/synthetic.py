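"""Synthetic multi-trait GWAS summary statistics with known causal truth.

The generator emulates the three data families a bidirectional
immune–inflammation MR screen consumes: a large panel of quantitative
immune-cell exposures (cohort n = 3,757), a smaller family of circulating
inflammatory-protein mediators (n = 876), and one binary disease outcome
on the log-odds scale (1,881 cases / 391,037 controls) — together with
block-exchangeable LD, palindromic variants, and per-file allele-label
discordance, so every pipeline stage (selection, clumping, harmonization,
estimation, mediation, MVMR) is exercisable without downloads.

Summary statistics are simulated directly on the effect scale: each trait
draws sparse per-SNP instrument effects, causal paths propagate upstream
effects downstream (exposure -> mediator -> outcome plus a direct
exposure -> outcome path), LD smears true marginal effects within blocks
through the signed correlation matrix, and the observed beta adds
sampling noise with se = 1/sqrt(2 n eaf(1-eaf)) (n replaced by the
effective case/control size 4/(1/n_cases + 1/n_controls) for the binary
outcome).  Stored p-values are the two-sided normal tails of beta/se, so
generated tables always pass the z-score consistency gate.

Every draw flows from a single mandatory seed; identical configurations
produce byte-identical study directories.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .gwas_io import P_FLOOR, TraitMeta, write_summary_stats, write_trait_meta
from .instruments import COMPLEMENT, LDMatrix

_NONPALINDROMIC_PAIRS = [("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
                         ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G")]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class SimConfig:
    """Generating conditions of a synthetic study.

    Cohort sizes default to the three real families the screen emulates
    (3,757 exposure individuals; 876 mediator individuals; 1,881 cases and
    391,037 controls).  ``n_exposures``/``n_mediators`` are scaled-down
    stand-ins for the 731-phenotype and 70-protein families.  Instrument
    effect scales differ by family: protein mediators get larger
    per-variant effects (sigma 0.5 vs 0.2), mirroring the strong cis
    effects protein GWAS report despite small cohorts.  The first
    ``n_causal_exposures`` exposures carry a direct effect ``theta_xy``
    (log-OR) on the disease; the first of them additionally acts through
    mediator 0 via ``theta_xm`` and ``theta_my``.
    """

    seed: int
    m_snps: int = 5000
    n_exposures: int = 30
    n_mediators: int = 5
    n_exp_sample: int = 3757
    n_med_sample: int = 876
    n_cases: int = 1881
    n_controls: int = 391_037
    pi_instrument: float = 0.004
    sigma_gamma: float = 0.2
    sigma_gamma_mediator: float = 0.5
    sigma_gamma_outcome: float = 0.2
    theta_xy: float = 0.15
    theta_xm: float = 0.3
    theta_my: float = 0.15
    n_causal_exposures: int = 2
    pleiotropy: str = "none"  # none | balanced | directional
    pleiotropy_magnitude: float = 0.05
    ld_block_size: int = 10
    ld_r: float = 0.6  # within-block correlation (signed); r2 = ld_r**2
    frac_palindromic: float = 0.2
    flip_prob: float = 0.3  # per-file allele-label swap probability
    strand_flip_prob: float = 0.1  # per-file strand relabelling (non-palindromic)
    noiseless: bool = False

    def __post_init__(self) -> None:
        for name in ("n_exp_sample", "n_med_sample", "n_cases", "n_controls"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        if self.pleiotropy not in {"none", "balanced", "directional"}:
            raise ValueError(f"unknown pleiotropy mode {self.pleiotropy!r}")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if not (0 <= self.ld_r < 1):
            raise ValueError("ld_r must be in [0, 1)")

    @property
    def n_eff_outcome(self) -> float:
        """Effective sample size of the case/control GWAS."""
        return 4.0 / (1.0 / self.n_cases + 1.0 / self.n_controls)


@dataclass
class SyntheticTruth:
    """Ground truth behind a simulated study.

    ``instrument_effects`` holds each trait's sparse direct per-SNP
    effects; ``causal`` the total causal effect of each trait on each
    other (row -> column); ``mediation_proportions`` the true proportion
    theta_xm*theta_my/(theta_xy + theta_xm*theta_my) per (exposure,
    mediator) pair on a causal path; ``orientation`` records, per trait
    file, which SNPs had allele labels swapped and/or strand-relabelled
    relative to the panel.
    """

    seed: int
    instrument_effects: dict[str, dict[str, float]]
    causal: dict[str, dict[str, float]]
    mediation_proportions: dict[str, float]  # "exposure|mediator" -> theta
    orientation: dict[str, dict[str, dict[str, bool]]]  # trait -> rsid -> flags
    pleiotropy_effects: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), sort_keys=True, indent=1),
                              encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text(encoding="utf-8")))


@dataclass
class StudyData:
    """In-memory bundle of a simulated (or loaded) study."""

    tables: dict[str, pd.DataFrame]
    meta: list[TraitMeta]
    ld: LDMatrix
    panel: pd.DataFrame

    @property
    def outcome_id(self) -> str:
        for m in self.meta:
            if m.family == "disease":
                return m.trait_id
        raise ValueError("study has no disease trait")

    def family(self, family: str) -> list[str]:
        return [m.trait_id for m in self.meta if m.family == family]


def true_mediation_proportion(theta_xy: float, theta_xm: float, theta_my: float) -> float:
    """Proportion mediated under the standard path diagram.

    The total exposure effect is theta_xy + theta_xm*theta_my, of which
    the indirect path contributes theta_xm*theta_my.
    """
    total = theta_xy + theta_xm * theta_my
    if total == 0:
        raise ZeroDivisionError("total effect is zero; proportion undefined")
    return theta_xm * theta_my / total


def simulate_panel(cfg: SimConfig, rng: np.random.Generator | None = None
                   ) -> tuple[pd.DataFrame, LDMatrix, sparse.csr_matrix]:
    """Variant panel plus LD structure.

    Blocks of ``ld_block_size`` adjacent variants share an exchangeable
    signed correlation ``ld_r`` (r² = ld_r² off-diagonal); blocks are
    independent and placed 20 Mb apart across chromosomes 1–22, 1 kb
    between neighbours within a block.  Returns the panel table, the r²
    matrix the pipeline consumes, and the signed correlation matrix the
    generator uses to propagate marginal effects.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    m = cfg.m_snps
    bs = cfg.ld_block_size
    n_blocks = int(np.ceil(m / bs))
    rsids = [f"rs{i + 1}" for i in range(m)]
    block_of = np.arange(m) // bs
    chroms = (block_of % 22 + 1).astype(int)
    block_on_chrom = block_of // 22
    pos = (block_on_chrom * 20_000_000 + (np.arange(m) % bs) * 1000 + 1).astype(np.int64)

    pal = rng.random(m) < cfg.frac_palindromic
    ea = np.empty(m, dtype=object)
    oa = np.empty(m, dtype=object)
    pal_pick = rng.integers(0, len(_PALINDROMIC_PAIRS), size=m)
    non_pick = rng.integers(0, len(_NONPALINDROMIC_PAIRS), size=m)
    for i in range(m):
        ea[i], oa[i] = (_PALINDROMIC_PAIRS[pal_pick[i]] if pal[i]
                        else _NONPALINDROMIC_PAIRS[non_pick[i]])
    eaf = rng.uniform(0.05, 0.95, size=m)

    panel = pd.DataFrame({
        "snp": rsids, "chr": chroms.astype(str), "pos": pos,
        "effect_allele": ea, "other_allele": oa, "eaf": eaf,
    })

    rows, cols, rvals = [], [], []
    for b in range(n_blocks):
        members = np.arange(b * bs, min((b + 1) * bs, m))
        for ii, i in enumerate(members):
            for j in members[ii + 1:]:
                rows += [i, j]
                cols += [j, i]
                rvals += [cfg.ld_r, cfg.ld_r]
    R = sparse.coo_matrix((rvals, (rows, cols)), shape=(m, m)).tocsr()
    R = R + sparse.identity(m, format="csr")
    r2 = R.copy()
    r2.data = r2.data**2
    ld = LDMatrix(rsids, r2)
    return panel, ld, R


def _trait_se(eaf: np.ndarray, n: float) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * n * eaf * (1.0 - eaf))


def simulate_trait_stats(panel: pd.DataFrame, R: sparse.csr_matrix,
                         direct_effects: np.ndarray, n_effective: float,
                         rng: np.random.Generator, cfg: SimConfig,
                         trait_id: str, truth_orientation: dict | None = None
                         ) -> pd.DataFrame:
    """One trait's observed summary statistics from its true direct effects.

    The true marginal effect vector is R @ direct_effects (LD smears causal
    effects across the block); observed beta adds N(0, se) noise unless the
    configuration is noiseless.  Allele labels are independently swapped
    per SNP with probability ``flip_prob`` (beta negated, eaf complemented)
    and, for non-palindromic SNPs, strand-relabelled with probability
    ``strand_flip_prob``; the truth is recorded in ``truth_orientation``.
    """
    m = len(panel)
    eaf = panel["eaf"].to_numpy(float)
    se = _trait_se(eaf, n_effective)
    true_marginal = np.asarray(R @ direct_effects).ravel()
    if cfg.noiseless:
        beta = true_marginal.copy()
    else:
        beta = true_marginal + rng.normal(0.0, se)
    pval = np.clip(2.0 * stats.norm.sf(np.abs(beta) / se), P_FLOOR, 1.0)

    ea = panel["effect_allele"].to_numpy(object).copy()
    oa = panel["other_allele"].to_numpy(object).copy()
    out_eaf = eaf.copy()
    flip = rng.random(m) < cfg.flip_prob
    pal = np.array([COMPLEMENT[a] == b for a, b in zip(ea, oa)])
    strand = (rng.random(m) < cfg.strand_flip_prob) & ~pal
    for i in np.flatnonzero(flip):
        ea[i], oa[i] = oa[i], ea[i]
    beta = np.where(flip, -beta, beta)
    out_eaf = np.where(flip, 1.0 - out_eaf, out_eaf)
    for i in np.flatnonzero(strand):
        ea[i], oa[i] = COMPLEMENT[ea[i]], COMPLEMENT[oa[i]]
    if truth_orientation is not None:
        snps = panel["snp"].tolist()
        for i in range(m):
            if flip[i] or strand[i]:
                truth_orientation[snps[i]] = {"flipped": bool(flip[i]),
                                              "strand": bool(strand[i])}

    df = pd.DataFrame({
        "snp": panel["snp"], "chr": panel["chr"], "pos": panel["pos"],
        "effect_allele": ea, "other_allele": oa, "eaf": out_eaf,
        "beta": beta, "se": se, "pval": pval,
        "n": float(round(n_effective)),
    })
    df["trait_id"] = trait_id
    df.attrs["n_dropped"] = 0
    return df


def _draw_instrument_effects(m: int, pi: float, sigma: float,
                             rng: np.random.Generator,
                             allowed: np.ndarray | None = None) -> np.ndarray:
    """Sparse per-SNP direct effects, optionally restricted to ``allowed``.

    Restricting each trait's instruments to its own LD blocks keeps
    instruments cross-trait independent, so no unintended correlated
    pleiotropy leaks through shared blocks; pleiotropy is injected only
    through the explicit configuration knob.
    """
    gamma = np.zeros(m)
    n_inst = max(1, int(round(pi * m)))
    pool = np.arange(m) if allowed is None else np.asarray(allowed)
    n_inst = min(n_inst, pool.size)
    idx = rng.choice(pool, size=n_inst, replace=False)
    gamma[idx] = rng.normal(0.0, sigma, size=n_inst)
    return gamma


def _partition_blocks(m: int, block_size: int, n_traits: int,
                      rng: np.random.Generator) -> list[np.ndarray]:
    """Assign LD blocks round-robin (shuffled) to traits.

    Each trait draws instruments only from its own blocks.  When there
    are fewer blocks than traits, blocks are shared (small toy panels).
    """
    n_blocks = int(np.ceil(m / block_size))
    order = rng.permutation(n_blocks)
    members = [np.arange(b * block_size, min((b + 1) * block_size, m))
               for b in range(n_blocks)]
    if n_blocks < n_traits:
        return [members[order[t % n_blocks]] for t in range(n_traits)]
    pools: list[list[np.ndarray]] = [[] for _ in range(n_traits)]
    for i, b in enumerate(order):
        pools[i % n_traits].append(members[b])
    return [np.concatenate(p) for p in pools]


def simulate_study(cfg: SimConfig, out_dir: str | Path | None = None,
                   overwrite: bool = False) -> tuple[StudyData, SyntheticTruth]:
    """Generate a full study: exposures, mediators, outcome, LD, truth.

    Causal architecture: exposures ``imm_001 .. imm_{n_causal}`` have a
    direct log-OR effect ``theta_xy`` on the disease; ``imm_001``
    additionally affects mediator ``inf_01`` (theta_xm), which affects the
    disease (theta_my).  All other traits are causally null (their SNPs
    still carry instrument effects).  Directional or balanced pleiotropy,
    when enabled, adds direct SNP-to-outcome effects at the first
    exposure's instruments.

    Writing to ``out_dir`` emits one TSV per trait, the sparse LD TSV,
    the trait-metadata YAML and a truth JSON; identical seeds give
    byte-identical directories.
    """
    rng = np.random.default_rng(cfg.seed)
    panel, ld, R = simulate_panel(cfg, rng)
    m = cfg.m_snps

    exposures = [f"imm_{i + 1:03d}" for i in range(cfg.n_exposures)]
    mediators = [f"inf_{j + 1:02d}" for j in range(cfg.n_mediators)]
    outcome = "om"

    all_traits = exposures + mediators + [outcome]
    pools = _partition_blocks(m, cfg.ld_block_size, len(all_traits), rng)
    pool_of = dict(zip(all_traits, pools))
    gammas: dict[str, np.ndarray] = {}
    for t in exposures:
        gammas[t] = _draw_instrument_effects(m, cfg.pi_instrument, cfg.sigma_gamma,
                                             rng, pool_of[t])
    for t in mediators:
        gammas[t] = _draw_instrument_effects(m, cfg.pi_instrument,
                                             cfg.sigma_gamma_mediator, rng, pool_of[t])
    gammas[outcome] = _draw_instrument_effects(m, cfg.pi_instrument,
                                               cfg.sigma_gamma_outcome, rng,
                                               pool_of[outcome])

    # causal matrix (direct effects trait -> trait)
    causal_direct: dict[str, dict[str, float]] = {t: {} for t in gammas}
    causal_exposures = exposures[:cfg.n_causal_exposures]
    mediated_exposure = causal_exposures[0] if causal_exposures and mediators else None
    for t in causal_exposures:
        causal_direct[t][outcome] = cfg.theta_xy
    if mediated_exposure is not None:
        causal_direct[mediated_exposure][mediators[0]] = cfg.theta_xm
        causal_direct[mediators[0]][outcome] = cfg.theta_my

    # true direct per-SNP effect of every trait, in topological order
    direct: dict[str, np.ndarray] = {}
    for t in exposures:
        direct[t] = gammas[t]
    for t in mediators:
        eff = gammas[t].copy()
        for x in exposures:
            theta = causal_direct[x].get(t, 0.0)
            if theta:
                eff += theta * direct[x]
        direct[t] = eff
    eff_y = gammas[outcome].copy()
    for t in exposures + mediators:
        theta = causal_direct[t].get(outcome, 0.0)
        if theta:
            eff_y += theta * direct[t]
    pleio: dict[str, float] = {}
    if cfg.pleiotropy != "none" and mediated_exposure is not None:
        inst = np.flatnonzero(gammas[mediated_exposure])
        if cfg.pleiotropy == "directional":
            alpha = np.full(inst.size, cfg.pleiotropy_magnitude)
        else:
            alpha = rng.normal(0.0, cfg.pleiotropy_magnitude, size=inst.size)
        eff_y[inst] += alpha
        snps = panel["snp"].to_numpy(object)
        pleio = {str(snps[i]): float(a) for i, a in zip(inst, alpha)}
    direct[outcome] = eff_y

    # observed tables
    tables: dict[str, pd.DataFrame] = {}
    orientation: dict[str, dict] = {}
    for t in exposures:
        orientation[t] = {}
        tables[t] = simulate_trait_stats(panel, R, direct[t], cfg.n_exp_sample,
                                         rng, cfg, t, orientation[t])
    for t in mediators:
        orientation[t] = {}
        tables[t] = simulate_trait_stats(panel, R, direct[t], cfg.n_med_sample,
                                         rng, cfg, t, orientation[t])
    orientation[outcome] = {}
    tables[outcome] = simulate_trait_stats(panel, R, direct[outcome],
                                           cfg.n_eff_outcome, rng, cfg,
                                           outcome, orientation[outcome])

    subtypes = ["AC", "MFI", "MP", "RC"]
    meta = [TraitMeta(t, f"immune phenotype {i + 1}", "immunophenotype",
                      subtype=subtypes[i % 4]) for i, t in enumerate(exposures)]
    meta += [TraitMeta(t, f"inflammatory protein {j + 1}", "inflammatory_protein")
             for j, t in enumerate(mediators)]
    meta.append(TraitMeta(outcome, "osteomyelitis", "disease",
                          n_cases=cfg.n_cases, n_controls=cfg.n_controls))

    # total causal effects (direct + mediated) and true mediation proportions
    causal_total: dict[str, dict[str, float]] = {t: dict(causal_direct[t]) for t in gammas}
    med_props: dict[str, float] = {}
    if mediated_exposure is not None:
        med = mediators[0]
        total = cfg.theta_xy + cfg.theta_xm * cfg.theta_my
        causal_total[mediated_exposure][outcome] = total
        if total != 0:
            med_props[f"{mediated_exposure}|{med}"] = true_mediation_proportion(
                cfg.theta_xy, cfg.theta_xm, cfg.theta_my)

    truth = SyntheticTruth(
        seed=cfg.seed,
        instrument_effects={
            t: {str(panel["snp"].iloc[i]): float(g[i]) for i in np.flatnonzero(g)}
            for t, g in gammas.items()},
        causal=causal_total,
        mediation_proportions=med_props,
        orientation=orientation,
        pleiotropy_effects=pleio,
    )
    study = StudyData(tables, meta, ld, panel)

    if out_dir is not None:
        out_dir = Path(out_dir)
        if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
            raise FileExistsError(f"output directory {out_dir} is not empty")
        out_dir.mkdir(parents=True, exist_ok=True)
        for t, df in tables.items():
            write_summary_stats(df, out_dir / f"{t}.tsv")
        ld.write(out_dir / "ld.tsv")
        write_trait_meta(meta, out_dir / "traits.yaml")
        truth.to_json(out_dir / "truth.json")
    return study, truth


def load_study(directory: str | Path) -> StudyData:
    """Read a study directory written by :func:`simulate_study`."""
    from .gwas_io import read_summary_stats, read_trait_meta

    directory = Path(directory)
    meta = read_trait_meta(directory / "traits.yaml")
    tables = {m.trait_id: read_summary_stats(directory / f"{m.trait_id}.tsv", m.trait_id)
              for m in meta}
    first = next(iter(tables.values()))
    rsids = first["snp"].tolist()
    ld = LDMatrix.read(directory / "ld.tsv", rsids)
    panel = first[["snp", "chr", "pos"]].copy()
    return StudyData(tables, meta, ld, panel)


# ---------------------------------------------------------------------------
# Effect-scale generators for estimator calibration


def simulate_instrument_set(k: int, theta: float, rng: np.random.Generator,
                            se_exp: float = 0.005, se_out: float = 0.02,
                            gamma_low: float = 0.1, gamma_high: float = 0.5,
                            intercept: float = 0.0,
                            pleiotropy_sd: float = 0.0) -> pd.DataFrame:
    """A harmonized instrument table with known causal effect ``theta``.

    True exposure effects are U(gamma_low, gamma_high) with random sign;
    observed effects add independent normal noise at the stated standard
    errors.  ``intercept`` adds a constant outcome shift per instrument
    (directional pleiotropy in the Egger orientation); ``pleiotropy_sd``
    adds balanced instrument-specific outcome effects.
    """
    gamma = rng.uniform(gamma_low, gamma_high, size=k) * rng.choice([-1.0, 1.0], size=k)
    alpha = intercept * np.sign(gamma)  # constant after Egger orientation
    if pleiotropy_sd > 0:
        alpha = alpha + rng.normal(0.0, pleiotropy_sd, size=k)
    bx = gamma + rng.normal(0.0, se_exp, size=k)
    by = theta * gamma + alpha + rng.normal(0.0, se_out, size=k)
    return pd.DataFrame({
        "rsid": [f"iv{i}" for i in range(k)],
        "beta_exp": bx, "se_exp": np.full(k, se_exp),
        "beta_out": by, "se_out": np.full(k, se_out),
        "action": "unchanged",
    })


def simulate_mediation_legs(k: int, theta_xy: float, theta_xm: float,
                            theta_my: float, rng: np.random.Generator,
                            se_exp: float = 0.005, se_out: float = 0.02
                            ) -> dict[str, pd.DataFrame]:
    """Instrument tables for the three legs of one mediation triple.

    The exposure legs (total X on Y, X on M) share the exposure's
    instruments; the mediator leg (M on Y) uses an independent instrument
    set.  Total X-on-Y effect is theta_xy + theta_xm*theta_my.
    """
    total = theta_xy + theta_xm * theta_my
    gx = rng.uniform(0.1, 0.5, size=k) * rng.choice([-1.0, 1.0], size=k)
    gm = rng.uniform(0.1, 0.5, size=k) * rng.choice([-1.0, 1.0], size=k)
    bx = gx + rng.normal(0.0, se_exp, size=k)

    def table(b_exp, true_out, se_o):
        return pd.DataFrame({
            "beta_exp": b_exp, "se_exp": np.full(k, se_exp),
            "beta_out": true_out + rng.normal(0.0, se_o, size=k),
            "se_out": np.full(k, se_o),
        })

    return {
        "exposure_outcome": table(bx, total * gx, se_out),
        "exposure_mediator": table(bx, theta_xm * gx, se_out),
        "mediator_outcome": table(gm + rng.normal(0.0, se_exp, size=k),
                                  theta_my * gm, se_out),
    }
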