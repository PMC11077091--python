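#!/usr/bin/env python
"""Simulate the demonstration cohort used by the downstream analyses.

Generates a 300-gene genome with CpG-island promoters, a methylome with the
five planted archetypes (c1 methylated .. c5 hypomethylated body), and a
somatic catalog of three signatures whose site rates couple to methylation
(SBS1-like positively, SBS2-like negatively, SBS5-like flat). Writes the
standard-format inputs plus the planted truth under results/cohort/.
"""

import json
from pathlib import Path

from genegrad import core_model
from genegrad.synthetic_data import SimConfig, simulate_cohort

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"
SEED = 7


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = SimConfig(seed=SEED, n_genes=300)
    cohort = simulate_cohort(config)

    cohort.genome.to_fasta(OUT / "genome.fa")
    cohort.genes.to_csv(OUT / "genes.tsv", sep="\t", index=False)
    core_model.write_mutations(cohort.mutations, OUT / "mutations.tsv")
    core_model.write_methylation(cohort.methylome, OUT / "methylation.tsv")
    config.signatures.to_tsv(OUT / "signatures.tsv")
    truth = {
        "seed": SEED,
        "archetype": cohort.truth.gene_archetype.to_dict(),
        "umrs": cohort.truth.umrs.to_dict(orient="records"),
    }
    (OUT / "truth.json").write_text(json.dumps(truth, indent=1))

    print(f"cohort: {len(cohort.genes)} genes over "
          f"{sum(cohort.genome.lengths.values()) / 1e6:.1f} Mb")
    print(f"mutations: {len(cohort.mutations)} SNVs in "
          f"{cohort.mutations['sample_id'].nunique()} samples")
    print("per signature:",
          cohort.mutations["signature"].value_counts().to_dict())
    print("archetypes:",
          cohort.truth.gene_archetype.value_counts().to_dict())
    print("planted hypomethylated regions:",
          cohort.truth.umrs["label"].value_counts().to_dict())
    print(f"outputs -> {OUT}")


if __name__ == "__main__":
    main()
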