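"""Hypomethylated-region calling and region-level mutation-rate contrasts.

A deterministic segmentation (smoothed per-CpG methylation below a cutoff,
bounded gaps, minimum CpG count) stands in for HMM-based WGBS segmenters:
regions are classified UMR (near-zero methylation, many CpGs) or LMR
(intermediate methylation). Region sets can be filtered for tissue
specificity, intersected with functional-element annotations (odds ratios,
contingency O/E, upset subsets), and contrasted against their flanks or
against paired upstream reference loci with the trinucleotide-adjusted
negative-binomial regression used for the gene-body gradients.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd
from intervaltree import Interval, IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._glm import fit_count_glm
from .core_model import GenomeSequence, make_region_set, trinucleotide_counts
from .mutation_gradients import compute_offsets

# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class SegmentationParams:
    """Parameters of the simplified UMR/LMR caller."""

    coverage_min: int = 5
    smooth_cpgs: int = 3  # running-mean window, in CpGs
    alpha_meth: float = 0.5  # methylation cutoff
    min_cpgs: int = 4
    umr_min_cpgs: int = 30
    umr_max_mean: float = 0.1
    max_gap: int = 1000  # max within-region inter-CpG gap, bp

    def __post_init__(self) -> None:
        if not 0 < self.alpha_meth < 1:
            raise ValueError("alpha_meth must be in (0, 1)")
        if min(self.coverage_min, self.smooth_cpgs, self.min_cpgs,
               self.umr_min_cpgs, self.max_gap) <= 0:
            raise ValueError("thresholds must be positive")


def _running_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Centred running mean with shrinking windows at the edges."""
    if window <= 1 or x.size <= 1:
        return x.astype(float)
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(x, dtype=float)])
    n = x.size
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def call_umr_lmr(
    track: pd.DataFrame, params: SegmentationParams | None = None
) -> pd.DataFrame:
    """Call hypomethylated regions from a per-CpG methylation track.

    Maximal runs of consecutive smoothed CpG values below ``alpha_meth``, with
    inter-CpG gaps at most ``max_gap`` and at least ``min_cpgs`` CpGs, are
    emitted as regions spanning the first to last CpG (half-open, end = last
    CpG + 2). Regions with >= ``umr_min_cpgs`` CpGs and raw mean fraction
    below ``umr_max_mean`` are classified UMR, the rest LMR.
    """
    params = params or SegmentationParams()
    records = []
    for contig, grp in track.groupby("contig", sort=True):
        grp = grp[(grp["coverage"] >= params.coverage_min) & grp["fraction"].notna()]
        if grp.empty:
            continue
        pos = grp["pos"].to_numpy()
        frac = grp["fraction"].to_numpy(dtype=float)
        smooth = _running_mean(frac, params.smooth_cpgs)
        below = smooth < params.alpha_meth
        run: list[int] = []
        runs: list[list[int]] = []
        for i in range(pos.size):
            if not below[i]:
                if run:
                    runs.append(run)
                run = []
                continue
            if run and pos[i] - pos[run[-1]] > params.max_gap:
                runs.append(run)
                run = []
            run.append(i)
        if run:
            runs.append(run)
        for run in runs:
            if len(run) < params.min_cpgs:
                continue
            mean = float(frac[run].mean())
            label = (
                "UMR"
                if len(run) >= params.umr_min_cpgs and mean < params.umr_max_mean
                else "LMR"
            )
            records.append(
                {
                    "contig": contig,
                    "start": int(pos[run[0]]),
                    "end": int(pos[run[-1]]) + 2,
                    "label": label,
                    "n_cpg": len(run),
                    "mean_meth": mean,
                }
            )
    if not records:
        return pd.DataFrame(
            columns=["contig", "start", "end", "label", "n_cpg", "mean_meth"]
        )
    out = make_region_set(records)
    return out.sort_values(["contig", "start"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Interval utilities
# ---------------------------------------------------------------------------


def _trees(regions: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for row in regions.itertuples(index=False):
        trees.setdefault(row.contig, IntervalTree()).addi(row.start, row.end)
    return trees


def _overlap_bases(trees: Mapping[str, IntervalTree], contig, start, end) -> int:
    tree = trees.get(contig)
    if tree is None:
        return 0
    merged = IntervalTree(tree.overlap(start, end))
    merged.merge_overlaps()
    return sum(min(iv.end, end) - max(iv.begin, start) for iv in merged)


def tissue_specific_regions(
    region_sets: Mapping[str, pd.DataFrame],
    target: str,
    max_other_overlap: float = 0.2,
) -> pd.DataFrame:
    """Regions of the target tissue group mostly absent from all other groups.

    A region is retained when the fraction of its bases covered by the merged
    regions of any other group is at most ``max_other_overlap``.
    """
    if target not in region_sets:
        raise ValueError(f"target group {target!r} not among region sets")
    if len(region_sets) < 2:
        raise ValueError("need at least two tissue groups")
    others = pd.concat(
        [df for name, df in region_sets.items() if name != target],
        ignore_index=True,
    )
    trees = _trees(others)
    tgt = region_sets[target]
    keep = []
    for row in tgt.itertuples(index=False):
        ov = _overlap_bases(trees, row.contig, row.start, row.end)
        keep.append(ov / (row.end - row.start) <= max_other_overlap)
    return tgt.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Enrichment statistics
# ---------------------------------------------------------------------------


def make_universe(
    genome: GenomeSequence | Mapping[str, int], unit: int = 1000
) -> pd.DataFrame:
    """Partition the genome into fixed-width units (last partial unit kept)."""
    lengths = genome.lengths if isinstance(genome, GenomeSequence) else dict(genome)
    rows = []
    for contig, L in lengths.items():
        starts = np.arange(0, L, unit)
        for s in starts:
            rows.append({"contig": contig, "start": int(s), "end": int(min(s + unit, L))})
    return pd.DataFrame(rows)


def region_overlap_odds(
    regions_a: pd.DataFrame,
    regions_b: pd.DataFrame,
    universe: pd.DataFrame,
) -> dict:
    """Odds ratio of unit-level co-membership in two region sets.

    Each universe unit is scored for any overlap with A and with B; the
    returned dict carries the 2x2 table, the odds ratio (Haldane-Anscombe 0.5
    correction when a cell is zero) and Fisher's exact p-value.
    """
    if universe.empty:
        raise ValueError("empty universe")
    trees_a, trees_b = _trees(regions_a), _trees(regions_b)
    in_a = np.zeros(len(universe), dtype=bool)
    in_b = np.zeros(len(universe), dtype=bool)
    for i, row in enumerate(universe.itertuples(index=False)):
        ta, tb = trees_a.get(row.contig), trees_b.get(row.contig)
        in_a[i] = bool(ta.overlap(row.start, row.end)) if ta is not None else False
        in_b[i] = bool(tb.overlap(row.start, row.end)) if tb is not None else False
    table = np.array(
        [
            [int((in_a & in_b).sum()), int((in_a & ~in_b).sum())],
            [int((~in_a & in_b).sum()), int((~in_a & ~in_b).sum())],
        ]
    )
    _, p = stats.fisher_exact(table)
    t = table.astype(float)
    if (t == 0).any():
        t = t + 0.5
    odds = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    return {"odds_ratio": float(odds), "pvalue": float(p), "table": table}


def contingency_enrichment(
    labels_a: pd.Series | np.ndarray, labels_b: pd.Series | np.ndarray
) -> pd.DataFrame:
    """Observed/expected enrichment of a two-way label contingency table.

    Returns a long table with one row per (a, b) cell: observed, expected
    (row x column margin under independence), O/E, the two-sided normal
    p-value of the adjusted standardized residual, and BH-adjusted q-values
    across cells.
    """
    obs = pd.crosstab(pd.Series(labels_a, name="a"), pd.Series(labels_b, name="b"))
    total = obs.values.sum()
    row = obs.sum(axis=1).to_numpy()[:, None]
    col = obs.sum(axis=0).to_numpy()[None, :]
    expected = row * col / total
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(expected > 0, obs.values / expected, np.nan)
        denom = np.sqrt(expected * (1 - row / total) * (1 - col / total))
        resid = np.where(denom > 0, (obs.values - expected) / denom, 0.0)
    pvals = 2 * stats.norm.sf(np.abs(resid))
    rows = []
    for i, a in enumerate(obs.index):
        for j, b in enumerate(obs.columns):
            rows.append(
                {
                    "a": a,
                    "b": b,
                    "observed": int(obs.values[i, j]),
                    "expected": float(expected[i, j]),
                    "oe": float(oe[i, j]),
                    "pvalue": float(pvals[i, j]),
                }
            )
    out = pd.DataFrame(rows)
    out["qvalue"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    return out


def upset_intersections(
    regions: pd.DataFrame, element_sets: Mapping[str, pd.DataFrame]
) -> pd.DataFrame:
    """Counts of regions by the exact subset of element sets they overlap.

    Each region is assigned to exactly one combination (the full set of
    elements it overlaps); the empty combination is the "no known element"
    class. Counts over all combinations sum to the number of regions.
    """
    trees = {name: _trees(df) for name, df in element_sets.items()}
    combos: dict[frozenset, int] = {}
    for row in regions.itertuples(index=False):
        members = frozenset(
            name
            for name, t in trees.items()
            if row.contig in t and t[row.contig].overlap(row.start, row.end)
        )
        combos[members] = combos.get(members, 0) + 1
    rows = [
        {"elements": "|".join(sorted(k)) if k else "(none)", "count": v}
        for k, v in combos.items()
    ]
    return (
        pd.DataFrame(rows, columns=["elements", "count"])
        .sort_values("count", ascending=False)
        .reset_index(drop=True)
    )


def promoter_windows(
    genes: pd.DataFrame, upstream: int = 1000, downstream: int = 2000
) -> pd.DataFrame:
    """Promoter-adjacent windows around each TSS (orientation-aware)."""
    rows = []
    for g in genes.to_dict("records"):
        if g["strand"] == "+":
            t = g["start"]
            start, end = t - upstream, t + downstream
        else:
            t = g["end"] - 1
            start, end = t - downstream + 1, t + upstream + 1
        rows.append(
            {
                "contig": g["contig"],
                "start": max(0, start),
                "end": end,
                "label": "promoter",
            }
        )
    return make_region_set(rows)


def subtract_elements(
    regions: pd.DataFrame, element_sets: Mapping[str, pd.DataFrame] | pd.DataFrame
) -> pd.DataFrame:
    """Remove regions overlapping any element (whole-region removal, no trim)."""
    if isinstance(element_sets, pd.DataFrame):
        element_sets = {"elements": element_sets}
    merged = pd.concat(element_sets.values(), ignore_index=True)
    trees = _trees(merged)
    keep = []
    for row in regions.itertuples(index=False):
        t = trees.get(row.contig)
        keep.append(not (t is not None and t.overlap(row.start, row.end)))
    return regions.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Region-rate contrasts
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class RateContrast:
    """Relative mutation rate of a region class versus its reference side."""

    rel_rate: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_mutations_in: int
    n_mutations_ref: int
    opportunity_in: float
    opportunity_ref: float
    model: str
    keys: dict = dataclasses.field(default_factory=dict)

    @property
    def depletion_pct(self) -> float:
        return 100.0 * (1.0 - self.rel_rate)


def _count_in_intervals(
    mutations: pd.DataFrame, intervals: pd.DataFrame
) -> np.ndarray:
    counts = np.zeros(len(intervals), dtype=np.int64)
    pos_by_contig = {
        c: np.sort(g["pos"].to_numpy()) for c, g in mutations.groupby("contig")
    }
    for i, row in enumerate(intervals.itertuples(index=False)):
        pos = pos_by_contig.get(row.contig)
        if pos is None:
            continue
        counts[i] = np.searchsorted(pos, row.end) - np.searchsorted(pos, row.start)
    return counts


def _pooled_w32(mutations: pd.DataFrame) -> np.ndarray:
    """Empirical 32-context distribution of a mutation catalog."""
    from .core_model import CONTEXT_INDEX

    counts = np.zeros(32)
    for ctx, n in mutations["context"].value_counts().items():
        counts[CONTEXT_INDEX[ctx]] += n
    if counts.sum() == 0:
        raise ValueError("no mutations with valid context")
    return counts / counts.sum()


def _rate_contrast_glm(
    y: np.ndarray, E: np.ndarray, is_in: np.ndarray, model: str = "nb"
) -> tuple[float, float, float, float, str]:
    keep = E > 0
    y, E, is_in = y[keep], E[keep], is_in[keep]
    X = np.column_stack([np.ones_like(E), is_in.astype(float)])
    fit = fit_count_glm(y, X, np.log(E), model=model)
    beta, se = fit.params[1], fit.bse[1]
    z = stats.norm.ppf(0.975)
    p = 2 * stats.norm.sf(abs(beta / se)) if se > 0 else np.nan
    return (
        float(np.exp(beta)),
        float(np.exp(beta - z * se)),
        float(np.exp(beta + z * se)),
        float(p),
        fit.model,
    )


def region_vs_flank_rate(
    mutations: pd.DataFrame,
    regions: pd.DataFrame,
    genome: GenomeSequence,
    flank_bp: int = 2000,
    w32: np.ndarray | None = None,
    model: str = "nb",
    keys: dict | None = None,
) -> RateContrast | None:
    """Relative mutation rate of regions versus their flanks.

    Observation unit is (region instance, side in {in, flank}); flanks are
    ``flank_bp`` on each side minus any overlap with other regions of the set.
    Offsets are trinucleotide-expected opportunities under ``w32`` (the pooled
    empirical context distribution of the catalog when not given). Returns
    None (flagged) when all counts are zero.
    """
    if w32 is None:
        w32 = _pooled_w32(mutations)
    lengths = genome.lengths
    region_trees = _trees(regions)

    obs_rows = []
    for row in regions.itertuples(index=False):
        L = lengths.get(row.contig)
        if L is None:
            continue
        obs_rows.append((row.contig, row.start, row.end, 1))
        for fs, fe in (
            (max(0, row.start - flank_bp), row.start),
            (row.end, min(L, row.end + flank_bp)),
        ):
            if fs >= fe:
                continue
            # subtract any overlap with other regions of the set
            tree = region_trees.get(row.contig)
            pieces = IntervalTree([Interval(fs, fe)])
            if tree is not None:
                for iv in tree.overlap(fs, fe):
                    pieces.chop(iv.begin, iv.end)
            for piece in sorted(pieces):
                obs_rows.append((row.contig, piece.begin, piece.end, 0))
    if not obs_rows:
        return None
    obs = pd.DataFrame(obs_rows, columns=["contig", "start", "end", "is_in"])
    y = _count_in_intervals(mutations, obs)
    if y.sum() == 0:
        return None
    ctx = np.zeros((len(obs), 32))
    for i, row in enumerate(obs.itertuples(index=False)):
        ctx[i] = trinucleotide_counts(genome, row.contig, row.start, row.end)
    E = compute_offsets(ctx, w32)
    rel, lo, hi, p, used_model = _rate_contrast_glm(
        y, E, obs["is_in"].to_numpy(), model
    )
    mask_in = obs["is_in"].to_numpy() == 1
    return RateContrast(
        rel_rate=rel,
        ci_low=lo,
        ci_high=hi,
        pvalue=p,
        n_mutations_in=int(y[mask_in].sum()),
        n_mutations_ref=int(y[~mask_in].sum()),
        opportunity_in=float(E[mask_in].sum()),
        opportunity_ref=float(E[~mask_in].sum()),
        model=used_model,
        keys=keys or {},
    )


def paired_locus_rate(
    mutations: pd.DataFrame,
    loci: pd.DataFrame,
    genome: GenomeSequence,
    reference_offset: int = 10_000,
    sample_groups: Mapping[str, str] | None = None,
    min_mutations: int = 20,
    w32: np.ndarray | None = None,
    model: str = "nb",
) -> pd.DataFrame:
    """Locus-versus-upstream-reference rate contrasts, one per stratum.

    Each locus is paired with a same-length reference window ending
    ``reference_offset`` bp upstream (orientation-aware; loci without strand
    are treated as '+'). One independent regression is fitted per combination
    of sample group, mutation signature and locus label; strata with fewer
    than ``min_mutations`` mutations are skipped and listed in
    ``attrs['skipped_strata']``. Loci whose reference window falls off the
    contig are dropped and counted in ``attrs['n_loci_dropped']``.
    """
    if w32 is None:
        w32 = _pooled_w32(mutations)
    lengths = genome.lengths
    pairs = []
    n_dropped = 0
    for row in loci.itertuples(index=False):
        L = row.end - row.start
        strand = getattr(row, "strand", "+") or "+"
        if strand == "+":
            ref_end = row.start - reference_offset
            ref_start = ref_end - L
        else:
            ref_start = row.end + reference_offset
            ref_end = ref_start + L
        contig_len = lengths.get(row.contig, 0)
        if ref_start < 0 or ref_end > contig_len:
            n_dropped += 1
            continue
        pairs.append(
            {
                "contig": row.contig,
                "start": row.start,
                "end": row.end,
                "ref_start": ref_start,
                "ref_end": ref_end,
                "label": row.label,
            }
        )
    pairs = pd.DataFrame(
        pairs, columns=["contig", "start", "end", "ref_start", "ref_end", "label"]
    )

    muts = mutations.copy()
    muts["group"] = (
        muts["sample_id"].map(sample_groups) if sample_groups else "all"
    )
    muts["signature"] = muts["signature"].fillna("unassigned")

    results = []
    skipped = []
    for (group, sig), sub in muts.groupby(["group", "signature"], dropna=False):
        for label, locus_sub in pairs.groupby("label"):
            intervals = pd.concat(
                [
                    locus_sub[["contig", "start", "end"]].assign(is_in=1),
                    locus_sub[["contig", "ref_start", "ref_end"]]
                    .rename(columns={"ref_start": "start", "ref_end": "end"})
                    .assign(is_in=0),
                ],
                ignore_index=True,
            )
            y = _count_in_intervals(sub, intervals)
            if y.sum() < min_mutations:
                skipped.append((group, sig, label, int(y.sum())))
                continue
            ctx = np.zeros((len(intervals), 32))
            for i, row in enumerate(intervals.itertuples(index=False)):
                ctx[i] = trinucleotide_counts(genome, row.contig, row.start, row.end)
            E = compute_offsets(ctx, w32)
            rel, lo, hi, p, used_model = _rate_contrast_glm(
                y, E, intervals["is_in"].to_numpy(), model
            )
            results.append(
                {
                    "group": group,
                    "signature": sig,
                    "locus_type": label,
                    "rel_rate": rel,
                    "ci_low": lo,
                    "ci_high": hi,
                    "pvalue": p,
                    "n_mutations": int(y.sum()),
                    "model": used_model,
                }
            )
    out = pd.DataFrame(
        results,
        columns=["group", "signature", "locus_type", "rel_rate", "ci_low",
                 "ci_high", "pvalue", "n_mutations", "model"],
    )
    out.attrs["skipped_strata"] = skipped
    out.attrs["n_loci_dropped"] = n_dropped
    return out
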