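# periomr

Two-sample Mendelian randomization (MR) of periodontal-disease liability
on cardiovascular outcomes, as a reusable, tested Python pipeline.

Genetic variants associated with dental caries and periodontitis serve
as instrumental variables: because alleles assort randomly at meiosis, a
variant's effect on a cardiovascular outcome that runs *through* the
periodontal liability estimates a causal effect free of the confounding
that plagues observational dental–cardiovascular associations. The
package covers the whole summary-statistics workflow:

- **Instruments** — 47 independent SNPs from the largest GWAS of the
  combined caries/periodontitis liability (n = 487,823), bundled at
  printed precision; selection at p < 5 × 10⁻⁸ and outcome-side
  exclusion of absent or outcome-significant SNPs.
- **Harmonization** — exposure and outcome effects expressed on a common
  effect allele, with configurable handling of palindromic (A/T, C/G)
  variants and an effect-allele-only mode for sources that publish a
  single allele.
- **Estimation** — per-SNP Wald ratios pooled three ways:
  inverse-variance weighted (IVW, multiplicative random effects by
  default), MR-Egger (slope = causal effect, intercept = directional
  pleiotropy, t inference on J−2 df), and the weighted median
  (bootstrap SE). Cochran Q heterogeneity throughout.
- **Pipeline** — one exposure against any number of outcomes with
  Bonferroni correction at α/m (0.05/8 = 0.00625 for the study grid),
  forest-plot tables, audit logs, full determinism given a seed.
- **Synthetic data** — a two-sample GWAS generator with known causal
  effect, configurable pleiotropy and invalid-instrument fraction, plus
  a replication harness for bias/coverage/robustness studies.

The statistical model, parameter choices and their rationale are
documented in [docs/methods.md](docs/methods.md).

## Worked example

```python
from periomr import (
    MRConfig, SimConfig, load_table1_fixture, select_instruments,
    run_mr, simulate_two_sample,
)

instruments = select_instruments(load_table1_fixture(), 5e-8)
print(len(instruments))                      # 47

# outcome-side consortium data are not public: simulate an outcome GWAS
# under a known causal effect and run the pipeline on it
exposure, outcome, truth = simulate_two_sample(
    SimConfig(n_snps=47, theta_true=0.1, seed=7)
)
result = run_mr(exposure, {"synthetic CAD": outcome}, MRConfig(seed=7))[0]
for method, est in result.estimates.items():
    print(f"{method}: {est.theta:.3f} ({est.ci_low:.3f}, {est.ci_high:.3f})")
```

prints

```
47
IVW: 0.106 (0.092, 0.120)
MR-Egger: 0.097 (0.069, 0.126)
weighted-median: 0.101 (0.081, 0.122)
```

— all three estimators recover the generating effect θ = 0.1, with
MR-Egger's wider interval reflecting its weaker identifying assumptions.

A command-line interface wraps the same functions:

```sh
periomr simulate --n-snps 47 --theta 0.1 --seed 7 --outdir sim/
periomr analyze sim/exposure.tsv sim/outcome.tsv --outdir mr/
periomr harmonize sim/exposure.tsv sim/outcome.tsv -o harmonized.tsv
```

## The analysis

Numbered drivers under `analysis/` reproduce the study shape — one
exposure, eight cardiovascular outcomes (CAD, HF, AF, stroke, AIS, CES,
LAS, SVS) at their consortium sample sizes — on synthetic outcome data
generated under the null, plus an estimator calibration study:

```sh
python analysis/01_select_instruments.py    # 47 instruments -> results/
python analysis/02_simulate_outcome_grid.py # 8 synthetic outcome GWASs
python analysis/03_run_mr_grid.py           # full MR grid + forest table
python analysis/04_estimator_calibration.py # bias/coverage/robustness
```

Outputs land in `results/` as tab-separated tables.

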