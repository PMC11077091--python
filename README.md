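# genegrad

Somatic mutation rates in human genomes vary not only across megabase
replication-timing domains and at single-trinucleotide resolution, but also at
the kilobase scale *within* genes: several mutational processes leave a
coldspot (or, for APOBEC/AID cytosine deaminases, a hotspot) spanning the
transcription start site and the first few kilobases of the gene body, and the
width and depth of that feature tracks local DNA methylation. `genegrad`
implements the full quantitative workflow for studying this sub-gene-scale
heterogeneity, exercisable end to end on synthetic cohorts with planted
effects:

1. **Bin-level rate estimation.** Genes are segmented into oriented 250 bp
   bins over extended 5′/3′ windows, a central window and a downstream 1 kb
   reference bin. For each analysis set (signature × expression tertile) the
   local relative rate is estimated by negative-binomial offset regression,

   log μ<sub>g,b</sub> = α + β<sub>b</sub> + log E<sub>g,b</sub>,

   with one observation per (gene, bin) and the trinucleotide-expected
   opportunity E<sub>g,b</sub> = Σ<sub>t</sub> n<sub>g,b,t</sub> w<sub>t</sub>
   as offset (w is the signature's 32-context marginal). exp(β<sub>b</sub>) is
   the rate of bin b relative to the reference bin, adjusted for sequence
   composition.
2. **Profile factorization.** Per-set coefficient profiles are stacked and
   factorized with centred (unscaled) PCA, plus an L1-penalized variant whose
   penalty-0 limit reproduces the plain PCA exactly.
3. **Methylation archetypes.** Gene-level WGBS profiles (50 bp segments over
   TSS/TES windows) are factorized with unscaled PCA and clustered with
   k-medoids into groups c1 (methylated promoter) … c5 (hypomethylated gene
   body); group gradients are summarized with exact order-statistic median
   CIs.
4. **Hypomethylated regions.** A deterministic UMR/LMR caller (smoothed
   per-CpG fractions below a cutoff, gap and CpG-count thresholds), tissue
   specificity filtering, overlap statistics (Fisher odds ratios, contingency
   O/E, upset subsets), and region-versus-flank / paired-locus NB rate
   contrasts.
5. **Selection baselines.** Gene-level burden models (length offset,
   trinucleotide composition, epigenomic covariates, optionally the
   methylation group label), repeated cross-validation against a
   shuffled-label control, and per-gene excess burden
   100·(y − ŷ)/ŷ as an effect-size proxy for positive selection.
6. **Synthetic cohorts.** A seeded generator for genomes with CpG-island
   promoters, archetype methylomes, and SNV catalogs whose per-site rates
   couple to methylation — positively (fraction<sup>κ</sup>) for NCG>T
   deamination-type signatures, negatively (1 + γ(1 − fraction)) for
   APOBEC-type — with planted 5′ depletions, hypomethylated regions, group
   multipliers and driver excesses serving as ground truth.

## Worked example

```python
from genegrad.synthetic_data import SimConfig, simulate_cohort
from genegrad import gene_binning as gb, mutation_gradients as mg
import numpy as np

cohort = simulate_cohort(SimConfig(seed=7, n_genes=300))
genes, genome = cohort.genes, cohort.genome
bins = gb.filter_overlapping_bins(gb.bin_gene_ends(genes, genome), genes)
counts = gb.count_mutations_per_bin(cohort.mutations, bins, by_signature=True)
ctx = gb.trinucleotide_counts_per_bin(genome, bins)
for sig in ("SBS1", "SBS2", "SBS5"):
    w32 = cohort.config.signatures.context_marginal(sig)
    table = mg.fit_bin_rates(counts, ctx, w32, count_col=f"n_{sig}")
    five = table.loc[table.region == "five_prime", "beta"].mean()
    print(sig, round(float(np.exp(five)), 3))
```

prints

```
SBS1 0.625
SBS2 1.19
SBS5 0.983
```

i.e. on this cohort the deamination-type signature is depleted ~37% across
the 5′ window relative to the reference bin (its sites are hypomethylated
there), the APOBEC-type signature is enriched ~19%, and the flat signature
shows no gradient — the planted coupling, recovered from raw SNVs.

The same workflow is laid out as a narrated analysis under `analysis/`
(`01_simulate_cohort.py` … `05_selection_baseline.py`, writing tables to
`results/`), and as a one-command pipeline:

```bash
genegrad run --config run.yaml     # simulate → bins → gradients → groups →
                                   # UMR/LMR → region rates → selection
```

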