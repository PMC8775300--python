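"""Simulate the eight-outcome cardiovascular grid.

The consortium outcome summary statistics (CAD, HF, AF and the four
stroke phenotypes) are not redistributable, so this study emulates them:
one synthetic exposure GWAS at the real exposure sample size and eight
outcome GWASs at the consortium sample sizes, generated under a true
null (theta = 0) — the regime the study's conclusions describe. Files
land in results/simulated_gwas/ together with the generating truth.
"""

from pathlib import Path

from periomr import SimConfig, simulate_two_sample, write_summary_table
from periomr.synthetic_data import write_truth_table

SEED = 20211222  # study date, used as the base seed of this analysis
N_EXPOSURE = 487_823
OUTCOME_SIZES = {
    "CAD": 184_305,
    "HF": 977_323,
    "AF": 588_190,
    "stroke": 521_612,
    "AIS": 521_612,
    "CES": 521_612,
    "LAS": 521_612,
    "SVS": 521_612,
}

OUT = Path("results/simulated_gwas")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    exposure, _, truth = simulate_two_sample(
        SimConfig(n_snps=47, theta_true=0.0, n_exposure=N_EXPOSURE, seed=SEED)
    )
    write_summary_table(exposure, OUT / "exposure.tsv")
    write_truth_table(truth, exposure.snp_ids(), OUT / "exposure_truth.tsv")
    print(f"exposure: 47 SNPs at n={N_EXPOSURE} -> {OUT / 'exposure.tsv'}")
    for i, (name, n_outcome) in enumerate(OUTCOME_SIZES.items()):
        _, outcome, _ = simulate_two_sample(
            SimConfig(
                n_snps=47,
                theta_true=0.0,
                n_exposure=N_EXPOSURE,
                n_outcome=n_outcome,
                seed=SEED + 1 + i,
            )
        )
        write_summary_table(outcome, OUT / f"{name}.tsv")
        print(f"outcome {name}: n={n_outcome} -> {OUT / name}.tsv")


if __name__ == "__main__":
    main()
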