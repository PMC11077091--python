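#!/usr/bin/env python
"""Methylation-aware mutation-burden baselines for selection analysis.

Generates a cohort-scale gene-burden table with planted methylation-group
multipliers (c3 x0.8, c1 x1.2) and held-out driver genes (x1.45), then
cross-validates the three burden-model variants (base covariates-only,
+methylation groups, +shuffled labels). A useful methylation covariate should
lower the CV RMSE in essentially every run while the shuffled control stays
at the base level, and the held-out drivers' excess burden should recover the
planted +45%.
"""

from pathlib import Path

import pandas as pd

from genegrad.selection_baseline import crossvalidate_burden
from genegrad.synthetic_data import make_gene_burden

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results" / "selection"
SEED = 7


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    features = make_gene_burden(
        seed=SEED,
        n_genes=3000,
        group_effects={"c3": 0.8, "c1": 1.2},
        driver_frac=0.05,
        driver_multiplier=1.45,
        dispersion_alpha=0.02,
    )
    print(f"{len(features)} genes, "
          f"{int(features['is_cancer_gene'].sum())} held-out drivers, "
          f"mean burden {features['y'].mean():.1f} mutations/gene")

    report = crossvalidate_burden(features, runs=15, folds=5, seed=SEED)
    report.rmse.to_csv(OUT / "cv_rmse.tsv", sep="\t", index=False)
    report.lrt.to_csv(OUT / "group_term_lrt.tsv", sep="\t", index=False)
    report.excess.to_csv(OUT / "excess_burden.tsv", sep="\t", index=False)

    wide = report.rmse.pivot(index="run", columns="variant", values="rmse")
    print("mean CV RMSE (mutations/gene):")
    print(wide.mean().round(3).to_string())
    wins = int((wide["methylation"] < wide["base"]).sum())
    print(f"methylation-aware model beats base in {wins}/{len(wide)} runs")
    lrt = report.lrt
    shuf_sig = (lrt.loc[lrt['variant'] == 'shuffled', 'pvalue'] < 0.01).mean()
    meth_sig = (lrt.loc[lrt['variant'] == 'methylation', 'pvalue'] < 0.01).mean()
    print(f"group-term LRT significant at p<0.01: methylation "
          f"{meth_sig:.0%}, shuffled {shuf_sig:.0%} of 75 iterations")
    drivers = report.excess["is_cancer_gene"]
    print(f"driver mean excess burden: "
          f"{report.excess.loc[drivers, 'excess_methylation'].mean():.1f}% "
          "(planted +45%)")
    print(f"outputs -> {OUT}")


if __name__ == "__main__":
    main()
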