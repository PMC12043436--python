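"""Generate the synthetic study the downstream analyses consume.

Simulates GWAS summary statistics for 30 immune-cell exposure phenotypes
(n = 3,757), 5 inflammatory-protein mediators (n = 876) and one binary
disease outcome (1,881 cases / 391,037 controls) over a 5,000-variant
panel with block LD, palindromic variants and per-file allele-label
discordance.  Two exposures carry a true effect on the disease; the
first additionally acts through mediator inf_01.  The study directory
(large, regenerable) goes under scratch/; summary counts under results/.
"""

import sys
from pathlib import Path

import pandas as pd

from mrscreen.synthetic import SimConfig, simulate_study

SEED = 20260928
ROOT = Path(__file__).resolve().parents[1]


def study_config() -> SimConfig:
    return SimConfig(seed=SEED)


def main() -> None:
    cfg = study_config()
    out = ROOT / "scratch" / "study"
    study, truth = simulate_study(cfg, out_dir=out, overwrite=True)
    rows = []
    for meta in study.meta:
        df = study.tables[meta.trait_id]
        rows.append({
            "trait_id": meta.trait_id, "family": meta.family,
            "n_snps": len(df),
            "n_instrument_snps": len(truth.instrument_effects[meta.trait_id]),
            "n_p_below_1e5": int((df["pval"] < 1e-5).sum()),
        })
    summary = pd.DataFrame(rows)
    res = ROOT / "results"
    res.mkdir(exist_ok=True)
    summary.to_csv(res / "study_summary.tsv", sep="\t", index=False)
    print(f"study written to {out} ({len(study.tables)} traits, "
          f"{cfg.m_snps} variants)")
    print("planted truth:", {k: v for k, v in truth.causal.items() if v})
    print("true mediation proportion:", truth.mediation_proportions)
    print(summary.groupby("family")[["n_instrument_snps", "n_p_below_1e5"]]
          .mean().round(1).to_string())


if __name__ == "__main__":
    sys.exit(main())
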