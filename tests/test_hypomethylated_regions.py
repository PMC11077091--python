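"""UMR/LMR calling, overlap statistics and region-rate contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from genegrad.core_model import GenomeSequence, make_region_set
from genegrad.hypomethylated_regions import (
    SegmentationParams,
    call_umr_lmr,
    contingency_enrichment,
    make_universe,
    paired_locus_rate,
    promoter_windows,
    region_overlap_odds,
    region_vs_flank_rate,
    subtract_elements,
    tissue_specific_regions,
    upset_intersections,
    _rate_contrast_glm,
)


def _track(pos, frac, coverage=30):
    return pd.DataFrame(
        {"contig": "chr1", "pos": np.asarray(pos),
         "fraction": np.asarray(frac, dtype=float), "coverage": coverage}
    )


def _regions(triples, label="UMR"):
    return make_region_set(
        [{"contig": "chr1", "start": s, "end": e, "label": lbl}
         for s, e, lbl in [(t + (label,))[:3] if len(t) == 2 else t for t in triples]]
    )


class TestCallUmrLmr:
    def test_clean_umr_in_methylated_background(self):
        pos = np.arange(0, 20_000, 100)
        frac = np.full(pos.size, 0.8)
        frac[(pos >= 5000) & (pos < 9000)] = 0.0  # 40 consecutive CpGs
        regions = call_umr_lmr(_track(pos, frac))
        assert len(regions) == 1
        r = regions.iloc[0]
        assert r["label"] == "UMR"
        assert r["n_cpg"] == 40
        assert (r["start"], r["end"]) == (5000, 8902)

    def test_few_intermediate_cpgs_are_lmr(self):
        pos = np.arange(0, 10_000, 100)
        frac = np.full(pos.size, 0.8)
        frac[10:20] = 0.3  # 10 CpGs at 0.3
        regions = call_umr_lmr(_track(pos, frac))
        assert len(regions) == 1
        assert regions.iloc[0]["label"] == "LMR"

    def test_empty_track(self):
        regions = call_umr_lmr(
            pd.DataFrame(columns=["contig", "pos", "fraction", "coverage"])
        )
        assert len(regions) == 0

    def test_large_gap_splits_region(self):
        pos = np.concatenate([np.arange(0, 1000, 50), np.arange(3000, 4000, 50)])
        frac = np.zeros(pos.size)
        regions = call_umr_lmr(_track(pos, frac))
        assert len(regions) == 2

    def test_output_disjoint_and_sorted(self, cohort60):
        regions = call_umr_lmr(cohort60.methylome)
        assert len(regions) > 10
        by_contig = regions.sort_values(["contig", "start"])
        pd.testing.assert_frame_equal(regions, by_contig)
        assert (regions["start"].shift(-1).dropna()
                >= regions["end"][:-1]).all()

    def test_called_bases_monotone_in_alpha(self, cohort60):
        """A stricter methylation cutoff never calls more bases."""
        total = []
        for alpha in (0.2, 0.4, 0.6, 0.8):
            r = call_umr_lmr(
                cohort60.methylome, SegmentationParams(alpha_meth=alpha)
            )
            total.append(int((r["end"] - r["start"]).sum()))
        assert all(a <= b for a, b in zip(total, total[1:]))

    def test_coverage_filter_applied_first(self):
        pos = np.arange(0, 2000, 50)
        frac = np.zeros(pos.size)
        track = _track(pos, frac, coverage=2)  # below the default minimum
        assert len(call_umr_lmr(track)) == 0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SegmentationParams(alpha_meth=1.5)
        with pytest.raises(ValueError):
            SegmentationParams(min_cpgs=0)


class TestTissueSpecific:
    def test_region_absent_elsewhere_retained(self):
        sets = {
            "colon": _regions([(100, 200), (1000, 1100)]),
            "brain": _regions([(5000, 5100)]),
        }
        out = tissue_specific_regions(sets, "colon")
        assert len(out) == 2

    def test_contained_region_removed(self):
        sets = {
            "colon": _regions([(100, 200)]),
            "brain": _regions([(50, 300)]),
        }
        assert len(tissue_specific_regions(sets, "colon")) == 0

    def test_fractional_threshold(self):
        sets = {
            "colon": _regions([(100, 200)]),
            "brain": _regions([(150, 300)]),  # 50% of colon region overlapped
        }
        assert len(tissue_specific_regions(sets, "colon", 0.2)) == 0
        assert len(tissue_specific_regions(sets, "colon", 0.6)) == 1

    def test_missing_target_fatal(self):
        with pytest.raises(ValueError, match="target"):
            tissue_specific_regions({"brain": _regions([(0, 10)])}, "colon")


class TestRegionOverlapOdds:
    def test_balanced_table_gives_or_one(self):
        # 40 units of 10 bp; A covers units 0..19, B covers 0..9 and 20..29
        universe = make_universe({"chr1": 400}, unit=10)
        A = _regions([(0, 200)])
        B = _regions([(0, 100), (200, 300)])
        res = region_overlap_odds(A, B, universe)
        assert res["table"].tolist() == [[10, 10], [10, 10]]
        assert res["odds_ratio"] == pytest.approx(1.0)

    def test_association_table(self):
        # [[30,10],[10,30]] -> OR 9
        universe = make_universe({"chr1": 800}, unit=10)
        A = _regions([(0, 400)])
        B = _regions([(0, 300), (400, 500)])
        res = region_overlap_odds(A, B, universe)
        assert res["table"].tolist() == [[30, 10], [10, 30]]
        assert res["odds_ratio"] == pytest.approx(9.0)

    def test_identical_sets_guarded_by_correction(self):
        universe = make_universe({"chr1": 400}, unit=10)
        A = _regions([(0, 200)])
        res = region_overlap_odds(A, A, universe)
        assert np.isfinite(res["odds_ratio"])
        assert res["pvalue"] < 1e-9

    def test_matches_brute_force_unit_tally(self, rng):
        universe = make_universe({"chr1": 5000}, unit=25)
        A = _regions([(int(s), int(s) + 40) for s in rng.integers(0, 4900, 30)])
        B = _regions([(int(s), int(s) + 60) for s in rng.integers(0, 4900, 20)])
        res = region_overlap_odds(A, B, universe)
        tally = np.zeros((2, 2), dtype=int)
        for u in universe.itertuples(index=False):
            in_a = any(r.start < u.end and u.start < r.end
                       for r in A.itertuples(index=False))
            in_b = any(r.start < u.end and u.start < r.end
                       for r in B.itertuples(index=False))
            tally[0 if in_a else 1][0 if in_b else 1] += 1
        assert res["table"].tolist() == tally.tolist()
        fisher_or, fisher_p = stats.fisher_exact(tally)
        assert res["pvalue"] == pytest.approx(fisher_p)

    def test_empty_universe_fatal(self):
        with pytest.raises(ValueError, match="universe"):
            region_overlap_odds(
                _regions([(0, 10)]), _regions([(0, 10)]),
                pd.DataFrame(columns=["contig", "start", "end"]),
            )


class TestContingencyEnrichment:
    def test_perfectly_aligned_balanced_labels(self):
        labels = np.repeat(["x", "y", "z"], 30)
        out = contingency_enrichment(labels, labels)
        diag = out[out["a"] == out["b"]]
        off = out[out["a"] != out["b"]]
        assert np.allclose(diag["oe"], 3.0)
        assert np.allclose(off["observed"], 0)

    def test_single_class_row_is_flat(self, rng):
        a = np.array(["only"] * 90)
        b = rng.choice(["x", "y", "z"], 90)
        out = contingency_enrichment(a, b)
        assert np.allclose(out["oe"], 1.0)

    def test_independent_labels_rarely_significant(self, rng):
        a = rng.choice(["p", "q", "r"], 3000)
        b = rng.choice(["x", "y"], 3000)
        out = contingency_enrichment(a, b)
        assert (out["qvalue"] < 0.05).mean() <= 0.05


class TestUpset:
    def test_exact_subset_semantics(self):
        regions = _regions([(100, 200)])
        elements = {
            "promoter": _regions([(150, 400)], label="promoter"),
            "loop": _regions([(50, 120)], label="loop"),
            "enhancer": _regions([(5000, 5100)], label="enhancer"),
        }
        out = upset_intersections(regions, elements)
        assert out.loc[0, "elements"] == "loop|promoter"
        assert out["count"].sum() == 1

    def test_no_elements_all_none(self):
        regions = _regions([(0, 10), (20, 30)])
        out = upset_intersections(regions, {})
        assert out.loc[0, "elements"] == "(none)"
        assert out.loc[0, "count"] == 2

    def test_counts_partition_regions(self, rng):
        regions = _regions(
            [(int(s), int(s) + 50) for s in rng.integers(0, 10_000, 40)]
        )
        elements = {
            "a": _regions([(0, 3000)], label="a"),
            "b": _regions([(2000, 6000)], label="b"),
        }
        out = upset_intersections(regions, elements)
        assert out["count"].sum() == len(regions)


class TestSubtractElements:
    def test_promoter_overlap_removed_entirely(self):
        genes = pd.DataFrame(
            [{"gene_id": "g", "contig": "chr1", "start": 10_000,
              "end": 20_000, "strand": "+", "expression": 1.0}]
        )
        prom = promoter_windows(genes)  # [-1000, +2000) around the TSS
        umrs = _regions([(10_400, 10_600), (30_000, 30_200)])
        out = subtract_elements(umrs, prom)
        assert list(out["start"]) == [30_000]

    def test_distant_region_kept_and_output_subset(self):
        umrs = _regions([(0, 100), (5000, 5100), (9000, 9100)])
        elements = _regions([(4990, 5050)], label="loop")
        out = subtract_elements(umrs, {"loop": elements})
        assert len(out) == 2
        merged = out.merge(umrs, how="left", indicator=True)
        assert (merged["_merge"] == "both").all()


class TestRateContrasts:
    def test_glm_matches_ratio_of_sums_on_poisson(self, rng):
        """The in-vs-reference NB coefficient equals the ratio of sums."""
        n = 400
        E = rng.uniform(20, 60, n)
        is_in = (np.arange(n) % 2).astype(float)
        y = rng.poisson(E * np.where(is_in == 1, 0.6, 1.0))
        rel, lo, hi, p, _ = _rate_contrast_glm(y, E, is_in)
        oracle = (y[is_in == 1].sum() / E[is_in == 1].sum()) / (
            y[is_in == 0].sum() / E[is_in == 0].sum()
        )
        assert rel == pytest.approx(oracle, rel=0.01)
        assert lo < rel < hi

    def test_planted_umr_depletion_recovered(self, rng, flat_genome):
        regions = _regions([(s, s + 1500) for s in range(10_000, 190_000, 10_000)])
        inside = np.zeros(200_000, dtype=bool)
        for r in regions.itertuples(index=False):
            inside[r.start:r.end] = True
        weights = np.where(inside, 0.5, 1.0)
        cum = np.cumsum(weights)
        cum /= cum[-1]
        sites = np.searchsorted(cum, rng.random(12_000))
        seq = flat_genome.contigs["chr1"]
        muts = pd.DataFrame(
            {"sample_id": "s", "contig": "chr1", "pos": sites,
             "ref": [seq[i] for i in sites], "alt": "T",
             "context": "ACA"}
        )
        contrast = region_vs_flank_rate(
            muts, regions, flat_genome, w32=np.full(32, 1 / 32)
        )
        assert contrast.ci_low < 0.5 < contrast.ci_high or (
            0.42 < contrast.rel_rate < 0.58
        )
        assert contrast.depletion_pct == pytest.approx(
            100 * (1 - contrast.rel_rate)
        )

    def test_all_zero_counts_flagged(self, flat_genome):
        regions = _regions([(10_000, 11_000)])
        muts = pd.DataFrame(
            {"sample_id": [], "contig": [], "pos": [], "ref": [], "alt": [],
             "context": []}
        )
        assert region_vs_flank_rate(
            muts, regions, flat_genome, w32=np.full(32, 1 / 32)
        ) is None

    def test_paired_locus_null_covers_one(self, rng, flat_genome):
        loci = _regions(
            [(s, s + 1000, "cpg_island") for s in range(20_000, 180_000, 20_000)]
        )
        sites = rng.integers(0, 200_000, 15_000)
        seq = flat_genome.contigs["chr1"]
        muts = pd.DataFrame(
            {"sample_id": rng.choice(["sA", "sB"], sites.size),
             "contig": "chr1", "pos": sites,
             "ref": [seq[i] for i in sites], "alt": "T", "context": "ACA",
             "signature": "SBS5"}
        )
        out = paired_locus_rate(
            muts, loci, flat_genome, w32=np.full(32, 1 / 32),
            sample_groups={"sA": "male", "sB": "female"},
        )
        assert len(out) == 2  # one regression per sample group
        assert ((out["ci_low"] < 1.0) & (1.0 < out["ci_high"])).all()

    def test_paired_locus_group_specific_effect(self, rng, flat_genome):
        loci = _regions(
            [(s, s + 1000, "promoter") for s in range(20_000, 180_000, 20_000)]
        )
        inside = np.zeros(200_000, dtype=bool)
        for r in loci.itertuples(index=False):
            inside[r.start:r.end] = True
        seq = flat_genome.contigs["chr1"]
        frames = []
        for sample, group_weight in [("sA", 2.0), ("sB", 1.0)]:
            weights = np.where(inside, group_weight, 1.0)
            cum = np.cumsum(weights)
            cum /= cum[-1]
            sites = np.searchsorted(cum, rng.random(10_000))
            frames.append(pd.DataFrame(
                {"sample_id": sample, "contig": "chr1", "pos": sites,
                 "ref": [seq[i] for i in sites], "alt": "T",
                 "context": "ACA", "signature": "SBS5"}
            ))
        muts = pd.concat(frames, ignore_index=True)
        out = paired_locus_rate(
            muts, loci, flat_genome, w32=np.full(32, 1 / 32),
            sample_groups={"sA": "groupA", "sB": "groupB"},
        ).set_index("group")
        assert out.loc["groupA", "rel_rate"] == pytest.approx(2.0, rel=0.15)
        assert out.loc["groupB", "rel_rate"] == pytest.approx(1.0, rel=0.15)

    def test_reference_window_off_contig_dropped(self, rng, flat_genome):
        loci = _regions([(2000, 3000, "promoter")])  # upstream ref would be < 0
        sites = rng.integers(0, 200_000, 500)
        seq = flat_genome.contigs["chr1"]
        muts = pd.DataFrame(
            {"sample_id": "s", "contig": "chr1", "pos": sites,
             "ref": [seq[i] for i in sites], "alt": "T", "context": "ACA",
             "signature": "SBS5"}
        )
        out = paired_locus_rate(muts, loci, flat_genome,
                                w32=np.full(32, 1 / 32))
        assert out.attrs["n_loci_dropped"] == 1
        assert len(out) == 0

    def test_umr_depletion_in_coupled_cohort(self, cohort60):
        """Deamination-type mutations are depleted inside called UMRs."""
        regions = call_umr_lmr(cohort60.methylome)
        umrs = regions[regions["label"] == "UMR"].reset_index(drop=True)
        muts = cohort60.mutations
        sbs1 = muts[muts["signature"] == "SBS1"].reset_index(drop=True)
        sbs2 = muts[muts["signature"] == "SBS2"].reset_index(drop=True)
        catalog = cohort60.config.signatures
        c1 = region_vs_flank_rate(
            sbs1, umrs, cohort60.genome, w32=catalog.context_marginal("SBS1")
        )
        c2 = region_vs_flank_rate(
            sbs2, umrs, cohort60.genome, w32=catalog.context_marginal("SBS2")
        )
        assert c1.rel_rate < 0.5  # strong hypomutation of NCG>T in UMRs
        assert c2.rel_rate > 1.0  # APOBEC-type enrichment
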