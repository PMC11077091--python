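"""Core domain types, genomic context machinery and file IO.

Conventions used throughout the package:

* All coordinates are 0-based, half-open ``[start, end)``. BED files are read
  and written natively in this convention; mutation TSV input is declared
  1-based (the common convention of somatic variant callers) and converted on
  read.
* Trinucleotide contexts are strand-collapsed to a pyrimidine-centred
  representation: 32 contexts (5' base x {C,T} x 3' base) and 96 substitution
  classes (COSMIC-style, e.g. ``A[C>T]G``).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# ---------------------------------------------------------------------------
# Alphabet and context vocabularies
# ---------------------------------------------------------------------------

BASES = "ACGT"
_BASE_TO_INT = {"A": 0, "C": 1, "G": 2, "T": 3, "N": -1}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: the 32 pyrimidine-centred trinucleotide contexts, C-centred first
CONTEXTS_32: list[str] = [f"{l}{c}{r}" for c in "CT" for l in BASES for r in BASES]
CONTEXT_INDEX: dict[str, int] = {ctx: i for i, ctx in enumerate(CONTEXTS_32)}

#: substitution types in COSMIC order
SUBSTITUTIONS: list[str] = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]

#: the 96 substitution-in-context classes, COSMIC order
CLASSES_96: list[str] = [
    f"{l}[{sub}]{r}" for sub in SUBSTITUTIONS for l in BASES for r in BASES
]
CLASS_INDEX: dict[str, int] = {c: i for i, c in enumerate(CLASSES_96)}

#: map 96-class index -> 32-context index (drop the alt allele)
CLASS_TO_CONTEXT = np.array(
    [CONTEXT_INDEX[c[0] + c[2] + c[6]] for c in CLASSES_96], dtype=np.int64
)


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in reversed(seq))


def _seq_to_int(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    lut = np.full(256, -1, dtype=np.int8)
    for b, i in _BASE_TO_INT.items():
        lut[ord(b)] = i
    return lut[arr]


def encode_context_codes(seq: str) -> np.ndarray:
    """Per-position 32-context code for a DNA string.

    Returns an int array of ``len(seq)``; positions without a valid
    pyrimidine-centred trinucleotide (edges, or any N in the 3-mer) are -1.
    Purine-centred positions are collapsed to their reverse complement.
    """
    n = len(seq)
    codes = np.full(n, -1, dtype=np.int16)
    if n < 3:
        return codes
    arr = _seq_to_int(seq)
    left, centre, right = arr[:-2], arr[1:-1], arr[2:]
    valid = (left >= 0) & (centre >= 0) & (right >= 0)
    # pyrimidine centre: C=1, T=3
    is_pyr = (centre == 1) | (centre == 3)
    l = np.where(is_pyr, left, 3 - right)
    c = np.where(is_pyr, centre, 3 - centre)
    r = np.where(is_pyr, right, 3 - left)
    is_t = (c == 3).astype(np.int16)
    code = is_t * 16 + l.astype(np.int16) * 4 + r.astype(np.int16)
    codes[1:-1] = np.where(valid, code, -1)
    return codes


def substitution_class(left: str, ref: str, alt: str, right: str) -> str | None:
    """Collapsed 96-class label, or None if the 3-mer contains N."""
    tri = f"{left}{ref}{right}"
    if any(b not in BASES for b in tri) or alt not in BASES or ref == alt:
        return None
    if ref in "AG":  # purine-centred: collapse to the reverse complement strand
        tri = reverse_complement(tri)
        ref = _COMPLEMENT[ref]
        alt = _COMPLEMENT[alt]
    return f"{tri[0]}[{ref}>{alt}]{tri[2]}"


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class GenomeSequence:
    """Uppercase DNA sequences keyed by contig name (alphabet ACGTN)."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            up = seq.upper()
            if set(up) - set("ACGTN"):
                bad = sorted(set(up) - set("ACGTN"))
                raise ValueError(f"contig {name!r} has invalid characters: {bad}")
            self.contigs[name] = up

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.contigs.items()}

    def fetch(self, contig: str, start: int, end: int) -> str:
        seq = self.contigs[contig]
        if start < 0 or end > len(seq) or start >= end:
            raise ValueError(
                f"interval [{start},{end}) outside contig {contig!r} "
                f"of length {len(seq)}"
            )
        return seq[start:end]

    # cached per-contig context codes, built lazily (used heavily in binning)
    def context_codes(self, contig: str) -> np.ndarray:
        cache = getattr(self, "_code_cache", None)
        if cache is None:
            cache = {}
            object.__setattr__(self, "_code_cache", cache)
        if contig not in cache:
            cache[contig] = encode_context_codes(self.contigs[contig])
        return cache[contig]

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeSequence":
        contigs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        if not contigs:
            raise ValueError(f"no sequences found in {path}")
        return cls(contigs)

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.contigs.items()
        ]
        SeqIO.write(records, str(path), "fasta")


def trinucleotide_counts(
    genome: GenomeSequence, contig: str, start: int, end: int
) -> np.ndarray:
    """Counts of the 32 collapsed trinucleotide contexts in ``[start, end)``.

    Both strands are collapsed onto the pyrimidine-centred representation, so
    each position contributes at most one count. One base of flanking genome
    sequence is used at interval edges when available; positions whose 3-mer
    contains an N are skipped.
    """
    seq = genome.contigs.get(contig)
    if seq is None:
        raise ValueError(f"unknown contig {contig!r}")
    if start < 0 or end > len(seq) or start >= end:
        raise ValueError(
            f"interval [{start},{end}) outside contig {contig!r} "
            f"of length {len(seq)}"
        )
    codes = genome.context_codes(contig)[start:end]
    codes = codes[codes >= 0]
    return np.bincount(codes, minlength=32).astype(np.int64)


# ---------------------------------------------------------------------------
# Gene annotations
# ---------------------------------------------------------------------------

GENE_COLUMNS = ["gene_id", "contig", "start", "end", "strand", "expression"]


def make_gene_table(records: Iterable[Mapping]) -> pd.DataFrame:
    """Validate and normalize a gene annotation table.

    Required keys: gene_id, contig, start, end, strand; ``expression``
    defaults to 0. Expression tertiles can be added with
    :func:`assign_expression_tertiles`.
    """
    df = pd.DataFrame(list(records))
    missing = [c for c in GENE_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ValueError(f"gene table missing columns: {missing}")
    if "expression" not in df.columns:
        df["expression"] = 0.0
    if (df["start"] >= df["end"]).any():
        raise ValueError("gene with start >= end")
    if not df["strand"].isin(["+", "-"]).all():
        raise ValueError("strand must be '+' or '-'")
    if df["gene_id"].duplicated().any():
        raise ValueError("duplicate gene_id")
    return df.reset_index(drop=True)


def assign_expression_tertiles(genes: pd.DataFrame) -> pd.DataFrame:
    """Partition genes into three near-equal groups by expression (1=lowest)."""
    genes = genes.copy()
    ranks = genes["expression"].rank(method="first")
    genes["expression_tertile"] = pd.qcut(ranks, 3, labels=[1, 2, 3]).astype(int)
    return genes


def tss(gene: Mapping) -> int:
    """Transcription start site (0-based position of the first transcribed base)."""
    return int(gene["start"]) if gene["strand"] == "+" else int(gene["end"]) - 1


def tes(gene: Mapping) -> int:
    """Transcription end site (0-based position of the last transcribed base)."""
    return int(gene["end"]) - 1 if gene["strand"] == "+" else int(gene["start"])


# ---------------------------------------------------------------------------
# Mutations
# ---------------------------------------------------------------------------

MUTATION_COLUMNS = [
    "sample_id",
    "contig",
    "pos",
    "ref",
    "alt",
    "context",
    "class96",
    "signature",
]


def annotate_mutation_contexts(
    df: pd.DataFrame, genome: GenomeSequence, max_mismatch_frac: float = 0.10
) -> pd.DataFrame:
    """Validate refs against the genome and attach collapsed context classes.

    Rows whose ref base does not match the genome are dropped (counted in
    ``df.attrs['n_ref_mismatch']``); rows whose trinucleotide context contains
    an N are dropped too (``df.attrs['n_no_context']``). More than
    ``max_mismatch_frac`` mismatches aborts: that usually indicates a
    coordinate-convention error.
    """
    n_input = len(df)
    if n_input == 0:
        out = df.copy()
        for col in ("context", "class96"):
            out[col] = pd.Series(dtype=object)
        out.attrs["n_ref_mismatch"] = 0
        out.attrs["n_no_context"] = 0
        return out

    classes: list[str | None] = []
    mismatch = np.zeros(n_input, dtype=bool)
    for i, row in enumerate(df.itertuples(index=False)):
        seq = genome.contigs.get(row.contig)
        pos = int(row.pos)
        if seq is None or not (0 <= pos < len(seq)) or seq[pos] != row.ref:
            mismatch[i] = True
            classes.append(None)
            continue
        left = seq[pos - 1] if pos >= 1 else "N"
        right = seq[pos + 1] if pos + 1 < len(seq) else "N"
        classes.append(substitution_class(left, row.ref, row.alt, right))

    n_mismatch = int(mismatch.sum())
    if n_mismatch / n_input > max_mismatch_frac:
        raise ValueError(
            f"{n_mismatch}/{n_input} mutations have a ref base that does not "
            "match the genome; check the coordinate convention (input TSV is "
            "expected to be 1-based, VCF 1-based)"
        )
    out = df.copy()
    out["class96"] = classes
    keep = ~mismatch & out["class96"].notna()
    n_no_context = int((~mismatch).sum() - keep.sum())
    out = out.loc[keep].copy()
    out["context"] = out["class96"].map(lambda c: c[0] + c[2] + c[6])
    if "signature" not in out.columns:
        out["signature"] = pd.NA
    out = out.reset_index(drop=True)
    out.attrs["n_ref_mismatch"] = n_mismatch
    out.attrs["n_no_context"] = n_no_context
    return out


def read_mutations(
    path: str | Path,
    genome: GenomeSequence,
    fmt: str = "tsv",
    sample_id: str | None = None,
) -> pd.DataFrame:
    """Read somatic SNVs from a 1-based TSV or a VCF and annotate contexts.

    TSV columns (tab-separated, header): sample, chrom, pos (1-based), ref,
    alt and optionally signature.
    """
    path = Path(path)
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        if df.empty:
            df = pd.DataFrame(columns=["sample", "chrom", "pos", "ref", "alt"])
        required = ["sample", "chrom", "pos", "ref", "alt"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"mutation TSV missing columns: {missing}")
        out = pd.DataFrame(
            {
                "sample_id": df["sample"].astype(str),
                "contig": df["chrom"].astype(str),
                "pos": df["pos"].astype(int) - 1,  # 1-based TSV -> 0-based
                "ref": df["ref"].astype(str).str.upper(),
                "alt": df["alt"].astype(str).str.upper(),
            }
        )
        if "signature" in df.columns:
            out["signature"] = df["signature"]
    elif fmt == "vcf":
        from cyvcf2 import VCF

        sample = sample_id if sample_id is not None else path.stem
        rows = []
        for var in VCF(str(path)):
            if not var.is_snp:
                continue
            rows.append(
                {
                    "sample_id": sample,
                    "contig": var.CHROM,
                    "pos": var.POS - 1,
                    "ref": var.REF.upper(),
                    "alt": var.ALT[0].upper(),
                }
            )
        out = pd.DataFrame(
            rows, columns=["sample_id", "contig", "pos", "ref", "alt"]
        )
    else:
        raise ValueError(f"unknown mutation format {fmt!r}")
    return annotate_mutation_contexts(out, genome)


def write_mutations(df: pd.DataFrame, path: str | Path) -> None:
    """Write a mutation table to the 1-based TSV dialect read_mutations accepts."""
    out = pd.DataFrame(
        {
            "sample": df["sample_id"],
            "chrom": df["contig"],
            "pos": df["pos"] + 1,
            "ref": df["ref"],
            "alt": df["alt"],
        }
    )
    if "signature" in df.columns:
        out["signature"] = df["signature"]
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Signature catalog
# ---------------------------------------------------------------------------


class SignatureCatalog:
    """Mutational signature spectra over the 96 substitution classes.

    Stored as a DataFrame with the 96 class labels as index and one column
    per signature; every column is non-negative and sums to one.
    """

    def __init__(self, spectra: pd.DataFrame):
        spectra = spectra.reindex(CLASSES_96)
        if spectra.isna().any().any():
            raise ValueError("spectra must cover all 96 substitution classes")
        if (spectra.values < 0).any():
            raise ValueError("spectra must be non-negative")
        sums = spectra.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError(f"each spectrum must sum to 1; got {dict(sums)}")
        self.spectra = spectra.astype(float)

    @property
    def signatures(self) -> list[str]:
        return list(self.spectra.columns)

    def probs(self, signature: str) -> np.ndarray:
        """96-vector of class probabilities."""
        return self.spectra[signature].to_numpy()

    def context_marginal(self, signature: str) -> np.ndarray:
        """32-vector: per-context mass (three alt classes summed), renormalized."""
        w96 = self.probs(signature)
        w32 = np.zeros(32)
        np.add.at(w32, CLASS_TO_CONTEXT, w96)
        total = w32.sum()
        if total <= 0:
            raise ValueError(f"signature {signature!r} has zero total mass")
        return w32 / total

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SignatureCatalog":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        self.spectra.to_csv(path, sep="\t", index_label="class")


# ---------------------------------------------------------------------------
# Methylation track
# ---------------------------------------------------------------------------


def make_methylation_track(
    contig: Iterable[str],
    pos: Iterable[int],
    fraction: Iterable[float],
    coverage: Iterable[int],
) -> pd.DataFrame:
    """Per-CpG fractional methylation with read coverage, sorted per contig."""
    df = pd.DataFrame(
        {
            "contig": list(contig),
            "pos": np.asarray(list(pos), dtype=np.int64),
            "fraction": np.asarray(list(fraction), dtype=float),
            "coverage": np.asarray(list(coverage), dtype=np.int64),
        }
    )
    df = df.sort_values(["contig", "pos"], kind="mergesort").reset_index(drop=True)
    if df.duplicated(["contig", "pos"]).any():
        raise ValueError("duplicate CpG positions in methylation track")
    frac = df["fraction"]
    covered = df["coverage"] > 0
    if ((frac < 0) | (frac > 1)).loc[covered & frac.notna()].any():
        raise ValueError("methylation fractions must be within [0, 1]")
    return df


def read_methylation(path: str | Path) -> pd.DataFrame:
    """Read a bedGraph-like TSV: contig, start, end, fraction, coverage."""
    df = pd.read_csv(
        path,
        sep="\t",
        names=["contig", "start", "end", "fraction", "coverage"],
        dtype={"contig": str},
        comment="#",
    )
    return make_methylation_track(
        df["contig"], df["start"], df["fraction"], df["coverage"]
    )


def write_methylation(track: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "contig": track["contig"],
            "start": track["pos"],
            "end": track["pos"] + 1,
            "fraction": track["fraction"],
            "coverage": track["coverage"],
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# Region sets (BED6)
# ---------------------------------------------------------------------------

REGION_COLUMNS = ["contig", "start", "end", "label"]


def make_region_set(records: Iterable[Mapping]) -> pd.DataFrame:
    df = pd.DataFrame(list(records))
    if df.empty:
        return pd.DataFrame(columns=REGION_COLUMNS)
    missing = [c for c in REGION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"region set missing columns: {missing}")
    if (df["start"] >= df["end"]).any():
        raise ValueError("region with start >= end")
    if (df["label"].astype(str) == "").any():
        raise ValueError("empty region class label")
    return df.reset_index(drop=True)


def write_regions(regions: pd.DataFrame, path: str | Path) -> None:
    """Write regions as BED6 (name = class label, score = 0, strand = '.')."""
    with open(path, "w") as fh:
        for row in regions.itertuples(index=False):
            strand = getattr(row, "strand", ".") or "."
            fh.write(
                f"{row.contig}\t{row.start}\t{row.end}\t{row.label}\t0\t{strand}\n"
            )


def read_regions(path: str | Path, label: str | None = None) -> pd.DataFrame:
    """Read a BED file into a region set; header/track/browser lines skipped.

    If ``label`` is given it overrides the BED name column.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            name = fields[3] if len(fields) > 3 and fields[3] else "region"
            rec = {
                "contig": fields[0],
                "start": start,
                "end": end,
                "label": label if label is not None else name,
            }
            if len(fields) > 5:
                rec["strand"] = fields[5]
            records.append(rec)
    return make_region_set(records)
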