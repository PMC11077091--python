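"""Bin-rate regression oracles, factorization and confounder adjustment."""

import numpy as np
import pandas as pd
import pytest

from genegrad.core_model import SignatureCatalog, CLASSES_96
from genegrad.mutation_gradients import (
    adjust_for_covariate,
    assign_signatures,
    build_coefficient_matrix,
    compute_offsets,
    factorize_gradients,
    fit_bin_rates,
    sparse_factorize,
)
from genegrad.synthetic_data import default_signature_catalog


# ---------------------------------------------------------------------------
# helpers: count-level data with known per-bin rates
# ---------------------------------------------------------------------------


def make_counts(
    rng,
    n_genes=100,
    positions=(("reference", 0), ("five_prime", 0), ("five_prime", 1),
               ("five_prime", 2), ("central", 0), ("three_prime", 0)),
    rates=None,
    mean_E=80.0,
):
    """One observation per (gene, bin position): y ~ Poisson(rate_b * E)."""
    rates = rates or {}
    rows, ctx = [], []
    for g in range(n_genes):
        for region, k in positions:
            counts32 = rng.integers(0, 20, size=32)
            counts32[0] += int(mean_E)  # keep E well away from zero
            w = np.full(32, 1 / 32)
            E = counts32 @ w
            r = rates.get((region, k), 1.0)
            rows.append(
                {
                    "gene_id": f"g{g}",
                    "region": region,
                    "k": k,
                    "n": rng.poisson(r * E),
                }
            )
            ctx.append(counts32)
    return pd.DataFrame(rows), np.array(ctx), np.full(32, 1 / 32)


def ratio_of_sums(counts, ctx, w32, region, k):
    """Closed-form oracle: (sum y / sum E) at a bin over the same at reference."""
    E = compute_offsets(ctx, w32)
    sel = (counts["region"] == region) & (counts["k"] == k)
    ref = (counts["region"] == "reference") & (counts["k"] == 0)
    num = counts.loc[sel, "n"].sum() / E[sel.to_numpy()].sum()
    den = counts.loc[ref, "n"].sum() / E[ref.to_numpy()].sum()
    return num / den


class TestAssignSignatures:
    def test_single_signature_labels_everything(self, cohort60):
        catalog = default_signature_catalog()
        muts = cohort60.mutations.head(200).copy()
        expo = pd.DataFrame(
            {"SBS5": 1.0},
            index=sorted(muts["sample_id"].unique()),
        )
        out = assign_signatures(muts, catalog, expo)
        assert (out["signature"] == "SBS5").all()
        assert (out["posterior"] == 1.0).all()

    def test_disjoint_spectra_recover_truth(self, cohort60):
        """SBS1 (NCG>T) and SBS2 (TCW) have disjoint spectra."""
        catalog = default_signature_catalog()
        muts = cohort60.mutations
        muts = muts[muts["signature"].isin(["SBS1", "SBS2"])].copy()
        truth = muts["signature"].copy()
        expo = pd.DataFrame(
            {"SBS1": 1.0, "SBS2": 1.0},
            index=sorted(muts["sample_id"].unique()),
        )
        out = assign_signatures(muts.drop(columns="signature"), catalog, expo)
        assert (out["signature"].to_numpy() == truth.to_numpy()).all()

    def test_tie_broken_lexicographically(self):
        spectra = pd.DataFrame(
            {"B_sig": np.full(96, 1 / 96), "A_sig": np.full(96, 1 / 96)},
            index=CLASSES_96,
        )
        catalog = SignatureCatalog(spectra)
        muts = pd.DataFrame(
            {
                "sample_id": ["s1"],
                "contig": ["chr1"],
                "pos": [5],
                "ref": ["C"],
                "alt": ["T"],
                "context": ["ACG"],
                "class96": ["A[C>T]G"],
            }
        )
        expo = pd.DataFrame({"B_sig": [1.0], "A_sig": [1.0]}, index=["s1"])
        out = assign_signatures(muts, catalog, expo)
        assert out.loc[0, "signature"] == "A_sig"

    def test_missing_exposures_unassigned_and_counted(self):
        catalog = default_signature_catalog()
        muts = pd.DataFrame(
            {
                "sample_id": ["s1", "s_unknown"],
                "contig": ["chr1"] * 2,
                "pos": [5, 6],
                "ref": ["C"] * 2,
                "alt": ["T"] * 2,
                "context": ["ACG"] * 2,
                "class96": ["A[C>T]G"] * 2,
            }
        )
        expo = pd.DataFrame({"SBS1": [1.0]}, index=["s1"])
        out = assign_signatures(muts, catalog, expo)
        assert out["signature"].isna().sum() == 1
        assert out.attrs["n_unassigned"] == 1


class TestFitBinRates:
    def test_poisson_matches_ratio_of_sums(self, rng):
        counts, ctx, w32 = make_counts(rng, n_genes=300)
        table = fit_bin_rates(counts, ctx, w32)
        for row in table.itertuples(index=False):
            oracle = ratio_of_sums(counts, ctx, w32, row.region, row.k)
            assert row.rel_rate == pytest.approx(oracle, rel=0.01)

    def test_planted_rate_recovered(self, rng):
        rates = {("five_prime", 0): 0.5, ("five_prime", 1): 0.5}
        counts, ctx, w32 = make_counts(rng, n_genes=400, rates=rates)
        table = fit_bin_rates(counts, ctx, w32)
        fp = table[(table["region"] == "five_prime") & (table["k"] < 2)]
        assert ((fp["rel_rate"] > 0.45) & (fp["rel_rate"] < 0.55)).all()
        assert (fp["pvalue"] < 1e-6).all()

    def test_reference_beta_is_zero(self, rng):
        counts, ctx, w32 = make_counts(rng)
        table = fit_bin_rates(counts, ctx, w32)
        ref = table[(table["region"] == "reference") & (table["k"] == 0)]
        assert ref["beta"].iloc[0] == 0.0

    def test_offset_scale_invariance(self, rng):
        """Scaling all context counts shifts the intercept, not the betas."""
        counts, ctx, w32 = make_counts(rng, n_genes=150)
        t1 = fit_bin_rates(counts, ctx, w32)
        t2 = fit_bin_rates(counts, ctx * 7, w32)
        assert np.allclose(t1["beta"], t2["beta"], atol=1e-8)
        assert t2.attrs["intercept"] == pytest.approx(
            t1.attrs["intercept"] - np.log(7), abs=1e-8
        )

    def test_nb_at_small_dispersion_matches_poisson(self, rng):
        counts, ctx, w32 = make_counts(rng, n_genes=200)
        nb = fit_bin_rates(counts, ctx, w32, model="nb")
        po = fit_bin_rates(counts, ctx, w32, model="poisson")
        assert np.allclose(nb["beta"], po["beta"], atol=1e-4)

    def test_min_mutations_skip(self, rng):
        counts, ctx, w32 = make_counts(rng, n_genes=2, mean_E=1.0)
        assert fit_bin_rates(counts, ctx, w32, min_mutations=10_000) is None

    def test_zero_offset_rows_dropped(self, rng):
        counts, ctx, w32 = make_counts(rng, n_genes=50)
        ctx[5] = 0  # this observation has no opportunity
        table = fit_bin_rates(counts, ctx, w32)
        assert table is not None
        assert np.isfinite(table["beta"]).all()


class TestCoefficientMatrix:
    def _tables(self, rng, keys):
        tables = {}
        for key in keys:
            counts, ctx, w32 = make_counts(rng, n_genes=30)
            tables[key] = fit_bin_rates(counts, ctx, w32)
        return tables

    def test_full_cross_row_count(self, rng):
        keys = [
            (t, s, q)
            for t in ("tissueA", "tissueB")
            for s in ("SBS1", "SBS2", "SBS5", "SBS7")
            for q in (1, 2, 3)
        ]
        tables = self._tables(rng, keys)
        matrix, mask = build_coefficient_matrix(tables)
        assert matrix.shape[0] == 24
        assert mask.all().all()
        assert matrix.index.names == ["tissue", "signature", "tertile"]

    def test_missing_positions_imputed_zero_with_mask(self, rng):
        keys = [("t", "SBS1", 1), ("t", "SBS2", 1)]
        tables = self._tables(rng, keys)
        tables[("t", "SBS1", 1)] = tables[("t", "SBS1", 1)].iloc[:-1]
        matrix, mask = build_coefficient_matrix(tables)
        dropped_col = matrix.columns[-1]
        assert matrix.loc[("t", "SBS1", 1), dropped_col] == 0.0
        assert not mask.loc[("t", "SBS1", 1), dropped_col]

    def test_annotation_round_trip_through_serialization(self, rng, tmp_path):
        tables = self._tables(rng, [("t", "SBS1", 1), ("t", "SBS2", 2)])
        matrix, _ = build_coefficient_matrix(tables)
        path = tmp_path / "m.tsv"
        matrix.to_csv(path, sep="\t")
        back = pd.read_csv(path, sep="\t", index_col=[0, 1, 2])
        assert list(back.index.names) == ["tissue", "signature", "tertile"]
        assert np.allclose(back.to_numpy(), matrix.to_numpy())


class TestFactorization:
    def _rank1(self, rng, n_sets=40, n_bins=56):
        profile = np.sin(np.linspace(0, 3, n_bins))
        profile /= np.linalg.norm(profile)
        amps = rng.normal(0, 2, n_sets)
        X = np.outer(amps, profile) + rng.normal(0, 1e-3, (n_sets, n_bins))
        cols = [f"five_prime:{k}" for k in range(n_bins)]
        return pd.DataFrame(X, columns=cols), profile

    def test_rank1_recovery(self, rng):
        matrix, profile = self._rank1(rng)
        fact = factorize_gradients(matrix)
        assert fact.explained_variance_ratio[0] > 0.99
        cos = abs(fact.loadings.iloc[0].to_numpy() @ profile)
        assert cos > 0.99

    def test_row_permutation_leaves_loadings_unchanged(self, rng):
        matrix, _ = self._rank1(rng)
        f1 = factorize_gradients(matrix)
        perm = matrix.sample(frac=1.0, random_state=3)
        f2 = factorize_gradients(perm)
        assert np.allclose(
            f1.loadings.to_numpy(), f2.loadings.to_numpy(), atol=1e-9
        )

    def test_explained_variance_non_increasing(self, rng):
        matrix = pd.DataFrame(rng.normal(size=(30, 20)))
        fact = factorize_gradients(matrix, n_components=5)
        evr = fact.explained_variance_ratio
        assert (np.diff(evr) <= 1e-12).all()

    def test_sign_convention(self, rng):
        matrix, _ = self._rank1(rng)
        fact = factorize_gradients(matrix)
        for _, loading in fact.loadings.iterrows():
            arr = loading.to_numpy()
            assert arr[np.argmax(np.abs(arr))] > 0

    def test_signature_mean_coordinates(self, rng):
        matrix, _ = self._rank1(rng, n_sets=12)
        idx = pd.MultiIndex.from_product(
            [["t1", "t2"], ["SBS1", "SBS2"], [1, 2, 3]],
            names=["tissue", "signature", "tertile"],
        )
        matrix.index = idx
        fact = factorize_gradients(matrix)
        assert set(fact.signature_means.index) == {"SBS1", "SBS2"}
        manual = fact.coordinates.groupby(level="signature").mean()
        assert np.allclose(fact.signature_means, manual)


class TestSparseFactorization:
    def test_zero_penalty_equals_plain_pca(self, rng):
        matrix = pd.DataFrame(rng.normal(size=(40, 25)))
        plain = factorize_gradients(matrix, n_components=3)
        sparse = sparse_factorize(matrix, l1_penalty=0.0, n_components=3)
        assert np.allclose(
            plain.loadings.to_numpy(), sparse.loadings.to_numpy(), atol=1e-6
        )

    def test_zero_count_monotone_in_penalty(self, rng):
        matrix = pd.DataFrame(rng.normal(size=(60, 30)))
        zeros = []
        for lam in [0.0, 0.5, 1.0, 2.0, 4.0]:
            fact = sparse_factorize(matrix, l1_penalty=lam, n_components=2)
            zeros.append(int((fact.loadings.to_numpy() == 0).sum()))
        assert all(a <= b for a, b in zip(zeros, zeros[1:]))

    def test_compact_profile_recovered_sparsely(self, rng):
        n_bins = 40
        profile = np.zeros(n_bins)
        profile[5:12] = 1.0
        profile /= np.linalg.norm(profile)
        amps = rng.normal(0, 3, 80)
        X = np.outer(amps, profile) + rng.normal(0, 0.05, (80, n_bins))
        matrix = pd.DataFrame(X)
        fact = sparse_factorize(matrix, l1_penalty=1.0, n_components=1)
        loading = fact.loadings.iloc[0].to_numpy()
        assert (loading[list(range(0, 5)) + list(range(12, n_bins))] == 0).all()
        assert (loading[5:12] > 0).all()

    def test_negative_penalty_rejected(self, rng):
        matrix = pd.DataFrame(rng.normal(size=(10, 5)))
        with pytest.raises(ValueError):
            sparse_factorize(matrix, l1_penalty=-1.0)


class TestAdjustForCovariate:
    def _depleted(self, rng, n_genes=250, gene_jitter=True):
        positions = [("reference", 0)] + [("five_prime", k) for k in range(6)]
        depleted = {("five_prime", k) for k in range(3)}
        rows, ctx, cov = [], [], []
        for g in range(n_genes):
            for region, k in positions:
                counts32 = rng.integers(0, 20, size=32)
                counts32[0] += 80
                E = counts32 @ np.full(32, 1 / 32)
                x = 1.0 if (region, k) in depleted else 0.0
                rows.append(
                    {
                        "gene_id": f"g{g}",
                        "region": region,
                        "k": k,
                        "n": rng.poisson(0.5**x * E),
                    }
                )
                ctx.append(counts32)
                cov.append(x)
        return (
            pd.DataFrame(rows),
            np.array(ctx),
            np.full(32, 1 / 32),
            np.array(cov),
        )

    def test_confounder_explains_gradient(self, rng):
        """Adjusting for the true depletion indicator kills the bin factor."""
        counts, ctx, w32, cov = self._depleted(rng)
        res = adjust_for_covariate(counts, ctx, w32, cov)
        assert res.lrt_bins_base < 1e-6
        assert res.lrt_bins_adjusted > 0.05
        # the indicator is collinear with the bin dummies, so only the sign
        # of gamma is identified here (magnitude is tested separately below)
        assert res.gamma < 0

    def test_gamma_magnitude_with_continuous_covariate(self, rng):
        """A per-observation covariate effect exp(gamma*x) is recovered."""
        positions = [("reference", 0)] + [("five_prime", k) for k in range(4)]
        rows, ctx, cov = [], [], []
        for g in range(400):
            for region, k in positions:
                counts32 = rng.integers(0, 20, size=32)
                counts32[0] += 80
                E = counts32 @ np.full(32, 1 / 32)
                x = rng.uniform(0, 1)
                rows.append({"gene_id": f"g{g}", "region": region, "k": k,
                             "n": rng.poisson(np.exp(np.log(0.5) * x) * E)})
                ctx.append(counts32)
                cov.append(x)
        res = adjust_for_covariate(
            pd.DataFrame(rows), np.array(ctx), np.full(32, 1 / 32), np.array(cov)
        )
        assert res.gamma == pytest.approx(np.log(0.5), abs=0.1)

    def test_noise_covariate_changes_nothing(self, rng):
        counts, ctx, w32, _ = self._depleted(rng)
        noise = rng.normal(size=len(counts))
        res = adjust_for_covariate(counts, ctx, w32, noise)
        base, adj = res.base, res.adjusted
        overlap = (
            (adj["beta"] >= base["ci_low"]) & (adj["beta"] <= base["ci_high"])
        )
        # reference row has a degenerate zero-width CI; ignore it
        assert overlap[1:].mean() >= 0.95
        assert res.lrt_bins_adjusted < 1e-6

    def test_gamma_sign_recovers_direction(self, rng):
        counts, ctx, w32, cov = self._depleted(rng)
        res = adjust_for_covariate(counts, ctx, w32, cov)
        assert res.gamma < 0  # depletion indicator lowers the rate

    def test_constant_covariate_flagged(self, rng):
        counts, ctx, w32, _ = self._depleted(rng, n_genes=60)
        res = adjust_for_covariate(counts, ctx, w32, np.ones(len(counts)))
        assert res.covariate_constant
        assert res.lrt_bins_adjusted == res.lrt_bins_base
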