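# mrscreen

Bidirectional two-sample Mendelian randomization (MR) screening for
immune–inflammation studies: does genetic variation that shifts an
immune-cell phenotype or a circulating inflammatory protein also shift
the risk of a binary disease such as osteomyelitis?

The package is aimed at genetic epidemiologists who work from GWAS
summary statistics alone. It covers the full screen:

- strict summary-statistics IO with total row validation (`gwas_io`);
- instrument selection at p < 1e-5, greedy lowest-p LD clumping
  (r² < 0.001 within 10,000 kb) and allele harmonization with a
  conservative palindrome policy (`instruments`);
- causal estimators — Wald ratio, IVW (β̂ = Σwβxβy / Σwβx², w = 1/σy²),
  MR-Egger with its intercept test for directional pleiotropy, weighted
  and simple medians with bootstrap standard errors — plus Cochran's Q
  and I² (`mr_core`);
- two-step mediation: proportion mediated θ = β₁β₂/β₀ with delta-method
  CI, Sobel p, and complementary/competitive typing (`mediation`);
- multivariable MR for mediator-adjusted direct effects (`mvmr`);
- a screening pipeline with Bonferroni (α = 0.05/2 families) + BH-FDR
  tiers, reverse-direction follow-up, genome-wide locus extraction and
  TSV/JSON reports (`pipeline`, `mrscreen` CLI);
- a synthetic GWAS generator with known causal truth — block LD,
  palindromic variants, discordant allele labels, configurable
  pleiotropy — so every stage is testable without downloads
  (`synthetic`), plus Monte-Carlo calibration utilities (`calibration`).

See `docs/methods.md` for the statistical model, conventions, and the
generator's scope.

## Worked example

The numbered scripts under `analysis/` run the whole study on one
simulated data set (30 immune phenotypes at n = 3,757, 5 inflammatory
proteins at n = 876, one disease outcome with 1,881 cases / 391,037
controls; three planted causal effects, one of them mediated):

```sh
python analysis/01_simulate_study.py
python analysis/02_forward_screen.py
python analysis/03_reverse_screen.py
python analysis/04_mediation_mvmr.py
python analysis/05_calibration.py
```

`02_forward_screen.py` prints, for this seed:

```
35 traits screened against the disease outcome
3 pass Bonferroni+FDR, 0 marginal
exposure               family  nsnp   ivw_or  ivw_ci_low  ivw_ci_high     ivw_pval  ...                   tier
 imm_001      immunophenotype     8 1.164771    1.100531     1.232762 1.369001e-07  bonferroni_significant
 imm_002      immunophenotype     7 1.179810    1.142077     1.218790 2.056012e-23  bonferroni_significant
  inf_01 inflammatory_protein     8 1.168018    1.151255     1.185024 1.924719e-98  bonferroni_significant
planted causal traits: ['imm_001', 'imm_002', 'inf_01']; recovered: ['imm_001', 'imm_002', 'inf_01']
```

i.e. exactly the three traits given true effects (log-ORs 0.195, 0.15,
0.15 → ORs 1.22, 1.16, 1.16) are flagged, each with the forest-plot
columns (instrument count, OR, 95% CI, IVW p, FDR p, I², Egger-intercept
p). `03` finds no reverse (disease → trait) effect, matching the
generator; `04` recovers the planted mediated path with a proportion of
23.7% (truth 23.1%, complementary) and a mediator-adjusted direct effect
of 0.112 (truth 0.15) for the exposure; `05` shows every estimator
unbiased with 95%-CI coverage between 0.90 and 0.98, the
Egger-intercept test at its nominal size, and a global-null screen
producing 0 Bonferroni false positives (expected 0.75).

The same machinery is scriptable, e.g.

```sh
mrscreen --seed 11 simulate study_dir
mrscreen --seed 11 --out-dir results all study_dir
```

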