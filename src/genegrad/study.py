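"""Study-scale experiments on synthetic cohorts with planted effects.

Each function runs one self-contained experiment — generate a cohort with a
known planted effect, run the corresponding estimator, and measure recovery —
and returns a dict of summary quantities. The analysis drivers narrate these
results and the acceptance machinery asserts on them; sizes default to the
study conditions (documented in the methods note) and every function is fully
seeded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from . import gene_binning as gb
from . import hypomethylated_regions as hr
from . import methylation_clustering as mc
from . import mutation_gradients as mg
from . import selection_baseline as sb
from .synthetic_data import (
    SimConfig,
    make_gene_burden,
    make_genome,
    make_methylome,
    make_mutations,
    simulate_cohort,
)

# ---------------------------------------------------------------------------
# 1. Null calibration of the bin-rate regression
# ---------------------------------------------------------------------------


def null_calibration(
    seed: int,
    n_sets: int = 200,
    n_genes: int = 120,
    mutations_per_set: float = 5000.0,
) -> dict:
    """Per-bin Wald-test calibration under a uniform-rate cohort.

    One genome is segmented once; each analysis set (signature x expression
    tertile, replicated to ``n_sets``) draws Poisson counts from the
    trinucleotide-expected opportunities with no positional effect (d = 1),
    exactly the marginal law of uniform-rate site sampling. Returns the
    fraction of non-reference bins with beta p < 0.05.
    """
    config = SimConfig(seed=seed, n_genes=n_genes)
    genome, genes, _ = make_genome(config)
    bins = gb.filter_overlapping_bins(gb.bin_gene_ends(genes, genome), genes)
    ctx = gb.trinucleotide_counts_per_bin(genome, bins)
    tert = genes.set_index("gene_id")["expression_tertile"]
    bin_tert = bins["gene_id"].map(tert).to_numpy()
    catalog = config.signatures
    rng = np.random.default_rng([seed, 10])

    pvals: list[float] = []
    sigs = catalog.signatures
    for i in range(n_sets):
        sig = sigs[i % len(sigs)]
        t = 1 + (i // len(sigs)) % 3
        sel = bin_tert == t
        counts = bins.loc[sel, ["gene_id", "region", "k"]].copy()
        w32 = catalog.context_marginal(sig)
        E = mg.compute_offsets(ctx[sel], w32)
        lam = mutations_per_set / E.sum()
        counts["n"] = rng.poisson(lam * E)
        table = mg.fit_bin_rates(counts, ctx[sel], w32, min_mutations=1)
        pvals.extend(table["pvalue"].dropna().tolist())
    pvals = np.asarray(pvals)
    return {
        "n_sets": n_sets,
        "n_tests": int(pvals.size),
        "fraction_significant": float((pvals < 0.05).mean()),
    }


# ---------------------------------------------------------------------------
# 2. Planted 5' depletion recovery
# ---------------------------------------------------------------------------


def depletion_recovery(
    seed: int,
    n_genes: int = 2000,
    d: float = 0.5,
    mutations_per_sample: float = 1000.0,
    n_samples: int = 20,
) -> dict:
    """Recovery of a planted 5'-window relative rate with the NB regression.

    A flat-spectrum cohort of ~n_samples x mutations_per_sample SNVs carries a
    planted relative rate ``d`` on the oriented [TSS-2kb, TSS+4kb) windows.
    Reports the pooled (geometric-mean) exp(beta) over 5' bins and the
    fraction of out-of-window bins whose 95% CI covers 1.0.
    """
    config = SimConfig(
        seed=seed,
        n_genes=n_genes,
        depletion_d=d,
        mutations_per_sample={"SBS5": mutations_per_sample},
        n_samples=n_samples,
    )
    genome, genes, truth = make_genome(config)
    mutations, truth = make_mutations(genome, genes, config, truth)
    bins = gb.filter_overlapping_bins(gb.bin_gene_ends(genes, genome), genes)
    counts = gb.count_mutations_per_bin(mutations, bins)
    ctx = gb.trinucleotide_counts_per_bin(genome, bins)
    w32 = config.signatures.context_marginal("SBS5")
    table = mg.fit_bin_rates(counts, ctx, w32)

    in_window = table["region"] == "five_prime"
    out_window = table["region"].isin(["three_prime", "central"])
    pooled = float(np.exp(table.loc[in_window, "beta"].mean()))
    covers = (
        (table.loc[out_window, "ci_low"] <= 0.0)
        & (0.0 <= table.loc[out_window, "ci_high"])
    )
    return {
        "n_mutations": int(len(mutations)),
        "planted_d": d,
        "in_window_rel_rate": pooled,
        "per_bin_rel_rates": table.loc[in_window, "rel_rate"].tolist(),
        "out_window_ci_coverage": float(covers.mean()),
        "table": table,
    }


# ---------------------------------------------------------------------------
# 3. Factorization recovery
# ---------------------------------------------------------------------------


def factorization_recovery(seed: int, n_sets: int = 60, n_bins: int = 56) -> dict:
    """Two planted orthogonal gradient profiles recovered by the PCA.

    The coefficient matrix is a noisy mixture of two orthonormal profiles with
    independent amplitudes (the dominant one 3x stronger). Reports the signal
    variance captured by the top-2 PC subspace, the |cosine| between PC1 and
    the dominant profile, and the penalty-0 sparse-PCA agreement.
    """
    rng = np.random.default_rng([seed, 20])
    x = np.linspace(0, 1, n_bins)
    p1 = np.exp(-(((x - 0.2) / 0.15) ** 2))
    p1 /= np.linalg.norm(p1)
    p2 = np.sin(2 * np.pi * x)
    p2 -= p2 @ p1 * p1  # orthogonalize
    p2 /= np.linalg.norm(p2)
    a1 = rng.normal(0, 3.0, n_sets)
    a2 = rng.normal(0, 1.0, n_sets)
    signal = np.outer(a1, p1) + np.outer(a2, p2)
    X = signal + rng.normal(0, 0.05, (n_sets, n_bins))
    matrix = pd.DataFrame(X, columns=[f"five_prime:{k}" for k in range(n_bins)])

    fact = mg.factorize_gradients(matrix, n_components=3)
    V = fact.loadings.iloc[:2].to_numpy()  # top-2 loadings (rows)
    signal_c = signal - signal.mean(axis=0)
    captured = float(((signal_c @ V.T) ** 2).sum() / (signal_c**2).sum())
    cos1 = float(abs(fact.loadings.iloc[0].to_numpy() @ p1))
    sparse0 = mg.sparse_factorize(matrix, l1_penalty=0.0, n_components=3)
    max_dev = float(
        np.abs(fact.loadings.to_numpy() - sparse0.loadings.to_numpy()).max()
    )
    return {
        "top2_signal_capture": captured,
        "pc1_cosine": cos1,
        "sparse_zero_penalty_max_dev": max_dev,
    }


# ---------------------------------------------------------------------------
# 5. Methylation archetype clustering
# ---------------------------------------------------------------------------


def clustering_recovery(seed: int, n_genes: int = 1000) -> dict:
    """ARI between k-medoids methylation groups and the planted archetypes."""
    config = SimConfig(seed=seed, n_genes=n_genes)
    genome, genes, truth = make_genome(config)
    track, truth = make_methylome(genome, genes, config, truth)
    segments = gb.bin_methylation_segments(genes, genome)
    matrix = mc.build_profile_matrix(track, segments, max_missing=0.8)
    fact = mc.pca_profiles(matrix, n_components=3)
    grouping = mc.cluster_genes(
        fact.coordinates, k=5, seed=seed, profile_matrix=matrix
    )
    truth_labels = truth.gene_archetype.reindex(matrix.index)
    ari = adjusted_rand_score(truth_labels.to_numpy(), grouping.labels.to_numpy())
    rerun = mc.cluster_genes(
        fact.coordinates, k=5, seed=seed, profile_matrix=matrix
    )
    return {
        "n_genes_clustered": int(len(matrix)),
        "ari": float(ari),
        "deterministic": bool((grouping.labels == rerun.labels).all()),
        "explained_variance_ratio": fact.explained_variance_ratio.tolist(),
    }


# ---------------------------------------------------------------------------
# 6. UMR/LMR caller recovery
# ---------------------------------------------------------------------------


def umr_recovery(seed: int, n_genes: int = 200) -> dict:
    """Base-pair Jaccard and class agreement of called vs planted regions."""
    config = SimConfig(seed=seed, n_genes=n_genes)
    genome, genes, truth = make_genome(config)
    track, truth = make_methylome(genome, genes, config, truth)
    called = hr.call_umr_lmr(track, hr.SegmentationParams())

    L = sum(genome.lengths.values())
    cov_t = np.zeros(L, dtype=bool)
    cov_c = np.zeros(L, dtype=bool)
    for r in truth.umrs.itertuples(index=False):
        cov_t[r.start:r.end] = True
    for r in called.itertuples(index=False):
        cov_c[r.start:r.end] = True
    jaccard = float((cov_t & cov_c).sum() / (cov_t | cov_c).sum())

    matched, agree = 0, 0
    for t in truth.umrs.itertuples(index=False):
        ov = called[(called["start"] < t.end) & (called["end"] > t.start)]
        if len(ov):
            matched += 1
            best = ov.iloc[
                int(np.argmax(np.minimum(ov["end"], t.end)
                              - np.maximum(ov["start"], t.start)))
            ]
            agree += int(best["label"] == t.label)
    return {
        "n_truth": int(len(truth.umrs)),
        "n_called": int(len(called)),
        "jaccard": jaccard,
        "class_agreement": float(agree / matched) if matched else np.nan,
        "matched": matched,
    }


# ---------------------------------------------------------------------------
# 7. Region-vs-flank estimator coverage
# ---------------------------------------------------------------------------


def flank_coverage(
    seed: int,
    n_replicates: int = 100,
    n_genes: int = 50,
    n_mutations: int = 10_000,
    depletion: float = 0.5,
) -> dict:
    """CI coverage of the region-vs-flank estimator over many catalogs.

    One genome with planted UMRs is fixed; each replicate redraws a flat
    catalog with per-site rates multiplied by ``depletion`` inside the truth
    regions (and a matched null with no effect). Reports the fraction of
    replicates whose 95% CI covers the planted value.
    """
    config = SimConfig(seed=seed, n_genes=n_genes,
                       archetype_probs={"c1": 0.4, "c4": 0.6})
    genome, genes, truth = make_genome(config)
    track, truth = make_methylome(genome, genes, config, truth)
    regions = truth.umrs[truth.umrs["label"] == "UMR"].reset_index(drop=True)
    contig = config.contig
    L = genome.lengths[contig]
    seq = genome.contigs[contig]
    inside = np.zeros(L, dtype=bool)
    for r in regions.itertuples(index=False):
        inside[r.start:r.end] = True
    w32 = np.full(32, 1 / 32)
    rng = np.random.default_rng([seed, 30])

    def replicate(rate_in: float) -> hr.RateContrast:
        weights = np.where(inside, rate_in, 1.0)
        cum = np.cumsum(weights)
        cum /= cum[-1]
        sites = np.searchsorted(cum, rng.random(n_mutations))
        muts = pd.DataFrame(
            {
                "sample_id": "s0",
                "contig": contig,
                "pos": sites,
                "ref": [seq[i] for i in sites],
                "alt": "T",
                "context": "ACA",
            }
        )
        return hr.region_vs_flank_rate(muts, regions, genome, w32=w32)

    cover_depleted, cover_null, estimates = 0, 0, []
    for _ in range(n_replicates):
        c = replicate(depletion)
        estimates.append(c.rel_rate)
        cover_depleted += int(c.ci_low <= depletion <= c.ci_high)
        c0 = replicate(1.0)
        cover_null += int(c0.ci_low <= 1.0 <= c0.ci_high)
    return {
        "n_replicates": n_replicates,
        "coverage_depleted": cover_depleted / n_replicates,
        "coverage_null": cover_null / n_replicates,
        "mean_rel_rate": float(np.mean(estimates)),
        "n_regions": int(len(regions)),
    }


# ---------------------------------------------------------------------------
# 8. Selection baseline with planted group effects
# ---------------------------------------------------------------------------


def selection_study(
    seed: int,
    n_genes: int = 3000,
    runs: int = 15,
    folds: int = 5,
    group_effects: dict | None = None,
    driver_multiplier: float = 1.45,
    driver_frac: float = 0.05,
) -> dict:
    """Cross-validated burden-model comparison with planted effects.

    Planted per-group multipliers (default c3 x0.8, c1 x1.2) and held-out
    driver genes (x1.45). Reports mean RMSE per variant, the number of runs in
    which the methylation-aware model beats the base model, the fraction of
    shuffled-label LRTs significant at p<0.01, and the driver mean excess.
    """
    group_effects = group_effects or {"c3": 0.8, "c1": 1.2}
    features = make_gene_burden(
        seed=seed,
        n_genes=n_genes,
        group_effects=group_effects,
        driver_frac=driver_frac,
        driver_multiplier=driver_multiplier,
        dispersion_alpha=0.02,
    )
    report = sb.crossvalidate_burden(features, runs=runs, folds=folds, seed=seed)
    wide = report.rmse.pivot(index="run", columns="variant", values="rmse")
    lrt = report.lrt
    shuf = lrt[lrt["variant"] == "shuffled"]
    meth = lrt[lrt["variant"] == "methylation"]
    drivers = report.excess["is_cancer_gene"]
    return {
        "rmse_base": float(wide["base"].mean()),
        "rmse_methylation": float(wide["methylation"].mean()),
        "rmse_shuffled": float(wide["shuffled"].mean()),
        "runs_methylation_beats_base": int((wide["methylation"] < wide["base"]).sum()),
        "runs": runs,
        "shuffled_sig_fraction": float((shuf["pvalue"] < 0.01).mean()),
        "methylation_sig_fraction": float((meth["pvalue"] < 0.01).mean()),
        "n_lrt_iterations": int(len(shuf)),
        "driver_mean_excess_pct": float(
            report.excess.loc[drivers, "excess_methylation"].mean()
        ),
        "planted_driver_excess_pct": 100.0 * (driver_multiplier - 1.0),
    }


# ---------------------------------------------------------------------------
# Methylation-coupled gradient demonstration (analysis driver support)
# ---------------------------------------------------------------------------


def coupled_gradient_study(seed: int, n_genes: int = 300) -> dict:
    """Full-cohort demonstration: signature-specific 5' gradients and UMR rates.

    Simulates a methylation-coupled cohort and measures, per signature, the
    pooled 5'-window relative rate and the UMR-vs-flank relative rate: the
    deamination-type signature should be locally depleted and the APOBEC-type
    enriched, with the flat signature in between.
    """
    config = SimConfig(seed=seed, n_genes=n_genes)
    cohort = simulate_cohort(config)
    genes, genome = cohort.genes, cohort.genome
    bins = gb.filter_overlapping_bins(gb.bin_gene_ends(genes, genome), genes)
    counts = gb.count_mutations_per_bin(cohort.mutations, bins, by_signature=True)
    ctx = gb.trinucleotide_counts_per_bin(genome, bins)
    catalog = config.signatures

    five_prime_rel = {}
    tables = {}
    for sig in catalog.signatures:
        table = mg.fit_bin_rates(
            counts, ctx, catalog.context_marginal(sig), count_col=f"n_{sig}"
        )
        if table is None:
            continue
        sel = table["region"] == "five_prime"
        five_prime_rel[sig] = float(np.exp(table.loc[sel, "beta"].mean()))
        tables[("synthetic", sig, 0)] = table

    called = hr.call_umr_lmr(cohort.methylome, hr.SegmentationParams())
    umrs = called[called["label"] == "UMR"].reset_index(drop=True)
    umr_rel = {}
    for sig in catalog.signatures:
        sub = cohort.mutations[cohort.mutations["signature"] == sig]
        contrast = hr.region_vs_flank_rate(
            sub.reset_index(drop=True), umrs, genome,
            w32=catalog.context_marginal(sig),
        )
        if contrast is not None:
            umr_rel[sig] = contrast.rel_rate

    matrix, _ = mg.build_coefficient_matrix(tables)
    fact = mg.factorize_gradients(matrix, n_components=2)
    return {
        "five_prime_rel_rate": five_prime_rel,
        "umr_rel_rate": umr_rel,
        "n_umrs": int(len(umrs)),
        "explained_variance_ratio": fact.explained_variance_ratio.tolist(),
    }
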