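"""Reverse MR: does the disease causally shift the screened-in traits?

For every trait whose forward IVW leg reached p < 0.05, the roles are
swapped: disease-associated variants become the instruments and the trait
the outcome.  The generator plants no disease-to-trait effects, so a
well-behaved screen should find nothing here.
"""

import importlib
import sys
from pathlib import Path

from mrscreen.pipeline import ScreenConfig, run_screen
from mrscreen.synthetic import simulate_study

sim = importlib.import_module("01_simulate_study")
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    study, _ = simulate_study(sim.study_config())
    cfg = ScreenConfig(direction="both", seed=sim.SEED)
    screen = run_screen(cfg, study)
    rev = screen[screen["direction"] == "reverse"].copy()
    res = ROOT / "results"
    res.mkdir(exist_ok=True)
    cols = ["exposure", "outcome", "nsnp", "ivw_or", "ivw_ci_low",
            "ivw_ci_high", "ivw_pval"]
    rev[cols].to_csv(res / "reverse_screen.tsv", sep="\t", index=False,
                     float_format="%.4g")
    print(f"{len(rev)} reverse pairs tested (forward hits at p < 0.05)")
    if len(rev):
        print(rev[cols].to_string(index=False))
        n_sig = int((rev["ivw_pval"] < 0.05).sum())
        print(f"{n_sig} reverse association(s) at p < 0.05 "
              f"(generator plants none)")


if __name__ == "__main__":
    sys.exit(main())
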