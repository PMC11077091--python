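"""Deterministic segmentation of genes into rate bins and methylation segments.

Genes are segmented, in transcription orientation, into:

* 250 bp mutation-rate bins covering an extended 5' window (2 kb upstream of
  the TSS through 4 kb into the gene), an extended 3' window (4 kb inside the
  TES through 2 kb downstream), a 2 kb central window around the gene
  midpoint, and a single 1 kb reference bin 4 kb downstream of the TES;
* 50 bp methylation segments covering TSS and TES windows that extend 3 kb
  outward and 5 kb inward (160 segments per window).

Bin ordinals ``k`` always increase in the direction of transcription; minus
strand genes are mirrored so that re-running on the reverse-complemented
genome reproduces the plus-strand case.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_model import GenomeSequence, trinucleotide_counts

BIN_COLUMNS = ["gene_id", "region", "k", "contig", "start", "end", "strand"]

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"
CENTRAL = "central"
REFERENCE = "reference"
TSS_WINDOW = "tss_window"
TES_WINDOW = "tes_window"


def _oriented_bins(
    gene_id: str,
    contig: str,
    strand: str,
    region: str,
    anchor_plus: int,
    span: tuple[int, int],
    width: int,
) -> list[dict]:
    """Bins of ``width`` bp covering ``anchor + span`` in transcription order.

    ``anchor_plus`` is the genomic anchor; ``span`` is (lo, hi) in oriented
    coordinates relative to the anchor (lo < hi, lo may be negative).
    """
    lo, hi = span
    n = (hi - lo) // width
    out = []
    for k in range(n):
        if strand == "+":
            start = anchor_plus + lo + k * width
            end = start + width
        else:
            end = anchor_plus - lo - k * width + 1
            start = end - width
        out.append(
            {
                "gene_id": gene_id,
                "region": region,
                "k": k,
                "contig": contig,
                "start": start,
                "end": end,
                "strand": strand,
            }
        )
    return out


def bin_gene_ends(
    genes: pd.DataFrame,
    genome: GenomeSequence | None = None,
    bin: int = 250,
    out5: int = 2000,
    in5: int = 4000,
    in3: int = 4000,
    out3: int = 2000,
    central: int = 1000,
    ref_offset: int = 4000,
    ref_len: int = 1000,
    min_gene_length: int = 10_000,
) -> pd.DataFrame:
    """Segment genes into oriented mutation-rate bins.

    With defaults, each gene yields 24 five-prime bins spanning
    [TSS-2000, TSS+4000), 24 three-prime bins spanning [TES-4000, TES+2000),
    8 central bins spanning midpoint +/- 1000, and one reference bin at
    [TES+4000, TES+5000), all in transcription orientation. Genes shorter than
    ``min_gene_length`` are excluded (so that inward windows cannot overlap
    within one gene); bins truncated by contig edges are dropped.
    """
    lengths = genome.lengths if genome is not None else {}
    records: list[dict] = []
    skipped: list[str] = []
    for g in genes.to_dict("records"):
        gene_len = g["end"] - g["start"]
        if gene_len < min_gene_length:
            skipped.append(g["gene_id"])
            continue
        strand = g["strand"]
        if strand == "+":
            tss_a, tes_a = g["start"], g["end"] - 1
        else:
            tss_a, tes_a = g["end"] - 1, g["start"]
        # rounded-down midpoint; on '-' the oriented midpoint base is mid-1,
        # which keeps the binning exactly mirror-symmetric between strands
        mid = (g["start"] + g["end"]) // 2
        if strand == "-":
            mid -= 1
        records += _oriented_bins(
            g["gene_id"], g["contig"], strand, FIVE_PRIME, tss_a, (-out5, in5), bin
        )
        records += _oriented_bins(
            g["gene_id"], g["contig"], strand, THREE_PRIME, tes_a, (-in3, out3), bin
        )
        records += _oriented_bins(
            g["gene_id"], g["contig"], strand, CENTRAL, mid, (-central, central), bin
        )
        records += _oriented_bins(
            g["gene_id"],
            g["contig"],
            strand,
            REFERENCE,
            tes_a,
            (ref_offset, ref_offset + ref_len),
            ref_len,
        )
    bins = pd.DataFrame(records, columns=BIN_COLUMNS)
    # drop bins truncated at contig edges
    keep = bins["start"] >= 0
    if lengths:
        contig_len = bins["contig"].map(lengths)
        keep &= bins["end"] <= contig_len
    bins = bins.loc[keep].reset_index(drop=True)
    bins.attrs["skipped_genes"] = skipped
    return bins


def filter_overlapping_bins(bins: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Drop bins overlapping bins of *other* genes in the same expression tertile.

    Cross-tertile overlaps are retained; both genes lose their overlapping
    bins.
    """
    if "expression_tertile" not in genes.columns:
        raise ValueError("genes need expression_tertile (assign_expression_tertiles)")
    tert = genes.set_index("gene_id")["expression_tertile"]
    bins = bins.copy()
    bins["_tertile"] = bins["gene_id"].map(tert)
    drop = np.zeros(len(bins), dtype=bool)
    for (_, _), grp in bins.groupby(["contig", "_tertile"], sort=False):
        idx = grp.index.to_numpy()
        order = np.argsort(grp["start"].to_numpy(), kind="mergesort")
        idx = idx[order]
        starts = bins.loc[idx, "start"].to_numpy()
        ends = bins.loc[idx, "end"].to_numpy()
        gids = bins.loc[idx, "gene_id"].to_numpy()
        # sweep: compare each bin with followers that start before it ends
        active: list[int] = []
        for j in range(len(idx)):
            active = [a for a in active if ends[a] > starts[j]]
            for a in active:
                if gids[a] != gids[j]:
                    drop[idx[a]] = True
                    drop[idx[j]] = True
            active.append(j)
    out = bins.loc[~drop].drop(columns="_tertile").reset_index(drop=True)
    out.attrs["n_dropped_overlap"] = int(drop.sum())
    return out


def bin_methylation_segments(
    genes: pd.DataFrame,
    genome: GenomeSequence | None = None,
    seg: int = 50,
    tss_in: int = 5000,
    tss_out: int = 3000,
    tes_in: int = 5000,
    tes_out: int = 3000,
) -> pd.DataFrame:
    """Oriented 50 bp methylation segments around TSS and TES.

    Defaults give 160 segments per window (3 kb outward + 5 kb inward), 320
    per gene. Overlapping gene instances are each kept independently.
    """
    lengths = genome.lengths if genome is not None else {}
    records: list[dict] = []
    for g in genes.to_dict("records"):
        strand = g["strand"]
        if strand == "+":
            tss_a, tes_a = g["start"], g["end"] - 1
        else:
            tss_a, tes_a = g["end"] - 1, g["start"]
        records += _oriented_bins(
            g["gene_id"], g["contig"], strand, TSS_WINDOW, tss_a, (-tss_out, tss_in), seg
        )
        records += _oriented_bins(
            g["gene_id"], g["contig"], strand, TES_WINDOW, tes_a, (-tes_in, tes_out), seg
        )
    segs = pd.DataFrame(records, columns=BIN_COLUMNS)
    keep = segs["start"] >= 0
    if lengths:
        keep &= segs["end"] <= segs["contig"].map(lengths)
    return segs.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Intersection of tracks with bins
# ---------------------------------------------------------------------------


def _positions_in_bins(
    bins: pd.DataFrame, pos_by_contig: dict[str, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """For each bin, the index range [lo, hi) into the sorted position array."""
    lo = np.zeros(len(bins), dtype=np.int64)
    hi = np.zeros(len(bins), dtype=np.int64)
    for contig, grp in bins.groupby("contig", sort=False):
        pos = pos_by_contig.get(contig, np.empty(0, dtype=np.int64))
        lo[grp.index] = np.searchsorted(pos, grp["start"].to_numpy(), side="left")
        hi[grp.index] = np.searchsorted(pos, grp["end"].to_numpy(), side="left")
    return lo, hi


def count_mutations_per_bin(
    mutations: pd.DataFrame, bins: pd.DataFrame, by_signature: bool = False
) -> pd.DataFrame:
    """Integer mutation counts per (gene, region, k), optionally per signature.

    A mutation falling into several (overlapping) bins is counted in each; for
    disjoint bins totals equal the number of mutations inside any bin.
    """
    bins = bins.reset_index(drop=True)
    out = bins[["gene_id", "region", "k", "contig", "start", "end", "strand"]].copy()
    if by_signature:
        sigs = sorted(mutations["signature"].dropna().unique())
        for sig in sigs:
            sub = mutations[mutations["signature"] == sig]
            pos_by_contig = {
                c: np.sort(g["pos"].to_numpy()) for c, g in sub.groupby("contig")
            }
            lo, hi = _positions_in_bins(out, pos_by_contig)
            out[f"n_{sig}"] = hi - lo
    else:
        pos_by_contig = {
            c: np.sort(g["pos"].to_numpy()) for c, g in mutations.groupby("contig")
        }
        lo, hi = _positions_in_bins(out, pos_by_contig)
        out["n"] = hi - lo
    return out


def mean_methylation_per_segment(
    track: pd.DataFrame,
    segments: pd.DataFrame,
    coverage_min: int = 5,
) -> pd.DataFrame:
    """Mean fraction over covered CpGs per segment; no CpG -> missing (NaN).

    Each covered CpG is weighted equally (not coverage-weighted); the coverage
    filter is applied first.
    """
    usable = track[(track["coverage"] >= coverage_min) & track["fraction"].notna()]
    segments = segments.reset_index(drop=True)
    out = segments[
        ["gene_id", "region", "k", "contig", "start", "end", "strand"]
    ].copy()
    means = np.full(len(segments), np.nan)
    for contig, grp in usable.groupby("contig", sort=False):
        pos = grp["pos"].to_numpy()
        frac = grp["fraction"].to_numpy()
        csum = np.concatenate([[0.0], np.cumsum(frac)])
        seg_c = segments[segments["contig"] == contig]
        lo = np.searchsorted(pos, seg_c["start"].to_numpy(), side="left")
        hi = np.searchsorted(pos, seg_c["end"].to_numpy(), side="left")
        n = hi - lo
        with np.errstate(invalid="ignore"):
            m = np.where(n > 0, (csum[hi] - csum[lo]) / np.maximum(n, 1), np.nan)
        means[seg_c.index] = m
    out["mean_fraction"] = means
    return out


def mean_signal_per_bin(
    signal: pd.DataFrame, bins: pd.DataFrame, value_col: str = "value"
) -> pd.DataFrame:
    """Mean of a generic per-position numeric track (contig, pos, value) per bin."""
    sig = signal.sort_values(["contig", "pos"], kind="mergesort")
    bins = bins.reset_index(drop=True)
    out = bins[["gene_id", "region", "k", "contig", "start", "end", "strand"]].copy()
    means = np.full(len(bins), np.nan)
    for contig, grp in sig.groupby("contig", sort=False):
        pos = grp["pos"].to_numpy()
        val = grp[value_col].to_numpy(dtype=float)
        csum = np.concatenate([[0.0], np.cumsum(val)])
        bin_c = bins[bins["contig"] == contig]
        lo = np.searchsorted(pos, bin_c["start"].to_numpy(), side="left")
        hi = np.searchsorted(pos, bin_c["end"].to_numpy(), side="left")
        n = hi - lo
        m = np.where(n > 0, (csum[hi] - csum[lo]) / np.maximum(n, 1), np.nan)
        means[bin_c.index] = m
    out["mean_value"] = means
    return out


def count_per_bin(items: pd.DataFrame, bins: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Dispatch on item type: mutations, methylation track, or numeric track."""
    cols = set(items.columns)
    if {"ref", "alt"} <= cols:
        return count_mutations_per_bin(items, bins, **kwargs)
    if {"fraction", "coverage"} <= cols:
        return mean_methylation_per_segment(items, bins, **kwargs)
    if {"pos", "value"} <= cols:
        return mean_signal_per_bin(items, bins, **kwargs)
    raise TypeError("unrecognized item table: expected mutations, methylation or a "
                    "(contig, pos, value) track")


def trinucleotide_counts_per_bin(
    genome: GenomeSequence, bins: pd.DataFrame
) -> np.ndarray:
    """Matrix (n_bins, 32) of collapsed trinucleotide counts per bin."""
    counts = np.zeros((len(bins), 32), dtype=np.int64)
    for i, row in enumerate(bins.itertuples(index=False)):
        counts[i] = trinucleotide_counts(genome, row.contig, row.start, row.end)
    return counts


def bins_to_bed(bins: pd.DataFrame, path) -> None:
    """Serialize bins as BED6 with name ``gene|region|k``."""
    with open(path, "w") as fh:
        for row in bins.itertuples(index=False):
            name = f"{row.gene_id}|{row.region}|{row.k}"
            fh.write(
                f"{row.contig}\t{row.start}\t{row.end}\t{name}\t0\t{row.strand}\n"
            )
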