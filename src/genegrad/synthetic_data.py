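"""Synthetic cohorts with planted methylation archetypes and mutation effects.

The generator produces, deterministically under a seed:

* a genome of non-overlapping genes with CpG-island-bearing promoters,
* a WGBS-like methylome whose per-gene profile follows one of five archetypes
  (c1 fully methylated body, c2 narrow/shallow promoter dip, c3
  downstream-shifted dip, c4 wide symmetric dip, c5 low methylation across the
  whole body),
* somatic SNV catalogs whose per-site rates couple to local methylation:
  positively (fraction^kappa) for NCG>T deamination-type signatures and
  negatively (1 + gamma*(1 - fraction)) for APOBEC-type signatures, with
  optional planted 5' depletion windows and per-gene rate multipliers.

Ground truth (archetype labels, hypomethylated intervals, planted rates) is
returned alongside, so every downstream estimator can be validated against
planted effects.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_model import (
    BASES,
    CLASSES_96,
    CLASS_TO_CONTEXT,
    GenomeSequence,
    SignatureCatalog,
    assign_expression_tertiles,
    make_gene_table,
    make_methylation_track,
    tss,
)

# ---------------------------------------------------------------------------
# Archetype catalogue
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class ArchetypeProfile:
    """Parametric methylation profile around the TSS.

    The dip is a flat-bottomed trapezoid in transcription-oriented
    coordinates: full depth on ``[-up_halfwidth, down_halfwidth]`` relative to
    the TSS, ramping linearly to zero over ``ramp`` bp on both sides.
    """

    dip_depth: float = 0.0
    up_halfwidth: float = 0.0
    down_halfwidth: float = 0.0
    body_level: float = 0.8
    ramp: float = 300.0
    has_island: bool = True


DEFAULT_ARCHETYPES: dict[str, ArchetypeProfile] = {
    # fully methylated promoter and body, no CpG island
    "c1": ArchetypeProfile(dip_depth=0.0, has_island=False),
    # narrow, shallow promoter dip
    "c2": ArchetypeProfile(dip_depth=0.5, up_halfwidth=300, down_halfwidth=500),
    # dip shifted downstream into the gene body
    "c3": ArchetypeProfile(dip_depth=0.95, up_halfwidth=250, down_halfwidth=2000),
    # wide symmetric dip
    "c4": ArchetypeProfile(dip_depth=0.95, up_halfwidth=2000, down_halfwidth=2000),
    # low methylation across the whole gene body
    "c5": ArchetypeProfile(dip_depth=0.0, body_level=0.25),
}


def default_signature_catalog() -> SignatureCatalog:
    """Three stylized spectra: CpG-deamination, APOBEC-like and flat.

    Labels follow the field's SBS nomenclature for readability; the spectra
    are idealized, not COSMIC estimates: SBS1 puts all mass on N[C>T]G, SBS2
    on T[C>T/G]A|T, SBS5 is uniform.
    """
    spectra = pd.DataFrame(0.0, index=CLASSES_96, columns=["SBS1", "SBS2", "SBS5"])
    for l in BASES:
        spectra.loc[f"{l}[C>T]G", "SBS1"] = 0.25
    for sub in ("C>T", "C>G"):
        for r in ("A", "T"):
            spectra.loc[f"T[{sub}]{r}", "SBS2"] = 0.25
    spectra["SBS5"] = 1.0 / 96
    return SignatureCatalog(spectra)


# NCG>T substitution classes (deamination at methylated CpG)
NCG_T_CLASSES = np.array(
    [1 if (c[2] == "C" and c[6] == "G" and c[4] == "T") else 0 for c in CLASSES_96],
    dtype=bool,
)


# ---------------------------------------------------------------------------
# Configuration and truth containers
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class SimConfig:
    """Study conditions of the synthetic cohort; ``seed`` is mandatory."""

    seed: int
    n_genes: int = 200
    gene_length_min: int = 12_000
    gene_length_max: int = 20_000
    intergenic_spacing: int = 12_000
    margin: int = 6_000
    contig: str = "chr1"
    # CpG placement
    cpg_background_density: float = 0.01  # CpGs per bp outside islands
    island_window: tuple[int, int] = (-500, 1000)  # oriented, relative to TSS
    island_cpg_density: float = 0.10
    # methylome
    archetypes: Mapping[str, ArchetypeProfile] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_ARCHETYPES)
    )
    archetype_probs: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {k: 0.2 for k in "c1 c2 c3 c4 c5".split()}
    )
    background_methylation: float = 0.8
    meth_noise_sd: float = 0.05
    coverage_mean: float = 30.0
    umr_alpha: float = 0.5  # truth-recording threshold on the noise-free profile
    umr_min_cpgs: int = 4
    umr_class_min_cpgs: int = 30
    umr_class_max_mean: float = 0.1
    umr_max_gap: int = 1000
    # mutation model
    signatures: SignatureCatalog = dataclasses.field(
        default_factory=default_signature_catalog
    )
    meth_coupled_signatures: Sequence[str] = ("SBS1",)
    apobec_signatures: Sequence[str] = ("SBS2",)
    kappa_meth: float = 1.0
    gamma_apobec: float = 1.0
    depletion_d: float = 1.0  # planted 5' relative rate, d <= 1
    depletion_window: tuple[int, int] = (-2000, 4000)  # oriented, rel. TSS
    burden_multipliers: Mapping[str, float] | None = None  # gene_id -> factor
    n_samples: int = 20
    mutations_per_sample: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"SBS1": 400.0, "SBS2": 300.0, "SBS5": 300.0}
    )

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        probs = np.array(list(self.archetype_probs.values()), dtype=float)
        if (probs < 0).any() or (probs > 1).any():
            raise ValueError("archetype probabilities must lie in [0, 1]")
        if not np.isclose(probs.sum(), 1.0):
            raise ValueError("archetype probabilities must sum to 1")
        if not 0 < self.depletion_d <= 1:
            raise ValueError("planted depletion factor d must be in (0, 1]")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclasses.dataclass
class SimTruth:
    """Planted ground truth accumulated across the three generators."""

    gene_archetype: pd.Series | None = None
    expression_tertile: pd.Series | None = None
    umrs: pd.DataFrame | None = None
    burden_multiplier: pd.Series | None = None
    depletion_d: float = 1.0
    depletion_windows: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# Genome generator
# ---------------------------------------------------------------------------


def _oriented_window(gene: Mapping, rel: tuple[int, int]) -> tuple[int, int]:
    """Genomic [start, end) of an oriented window relative to the TSS."""
    t = tss(gene)
    if gene["strand"] == "+":
        return t + rel[0], t + rel[1]
    return t - rel[1] + 1, t - rel[0] + 1


def make_genome(
    config: SimConfig,
) -> tuple[GenomeSequence, pd.DataFrame, SimTruth]:
    """Generate the genome and gene annotations; deterministic under the seed."""
    rng = config.rng(0)
    lengths = rng.integers(
        config.gene_length_min, config.gene_length_max + 1, config.n_genes
    )
    total = config.margin * 2 + int(
        (lengths + config.intergenic_spacing).sum()
    )
    # background sequence, CpG-depleted to the configured density
    seq = rng.choice(
        np.frombuffer(b"ACGT", dtype=np.uint8), size=total, p=[0.3, 0.2, 0.2, 0.3]
    ).copy()
    is_c = seq[:-1] == ord("C")
    is_g = seq[1:] == ord("G")
    cg_pos = np.flatnonzero(is_c & is_g)
    p_keep = min(1.0, config.cpg_background_density / 0.04)
    destroy = cg_pos[rng.random(cg_pos.size) > p_keep]
    seq[destroy + 1] = rng.choice(
        np.frombuffer(b"AT", dtype=np.uint8), size=destroy.size
    )

    # gene placement
    starts = config.margin + np.concatenate(
        [[0], np.cumsum(lengths + config.intergenic_spacing)[:-1]]
    )
    strands = rng.choice(["+", "-"], size=config.n_genes)
    expression = rng.lognormal(mean=1.0, sigma=1.0, size=config.n_genes)
    labels = list(config.archetype_probs)
    archetypes = rng.choice(
        labels, size=config.n_genes, p=list(config.archetype_probs.values())
    )
    genes = make_gene_table(
        [
            {
                "gene_id": f"g{i:05d}",
                "contig": config.contig,
                "start": int(starts[i]),
                "end": int(starts[i] + lengths[i]),
                "strand": strands[i],
                "expression": float(expression[i]),
            }
            for i in range(config.n_genes)
        ]
    )
    genes = assign_expression_tertiles(genes)
    genes["archetype"] = archetypes

    # CpG islands at promoters of island-bearing archetypes
    for gene in genes.to_dict("records"):
        if not config.archetypes[gene["archetype"]].has_island:
            continue
        w0, w1 = _oriented_window(gene, config.island_window)
        w0, w1 = max(0, w0), min(total - 1, w1)
        n_cpg = int((w1 - w0) * config.island_cpg_density)
        if n_cpg <= 0:
            continue
        # spacing-2 grid keeps planted CpGs from clobbering each other
        grid = np.arange(w0, w1 - 1, 2)
        sites = rng.choice(grid, size=min(n_cpg, grid.size), replace=False)
        seq[sites] = ord("C")
        seq[sites + 1] = ord("G")

    genome = GenomeSequence({config.contig: seq.tobytes().decode("ascii")})
    truth = SimTruth(
        gene_archetype=genes.set_index("gene_id")["archetype"],
        expression_tertile=genes.set_index("gene_id")["expression_tertile"],
        depletion_d=config.depletion_d,
    )
    return genome, genes, truth


# ---------------------------------------------------------------------------
# Methylome generator
# ---------------------------------------------------------------------------


def _trapezoid(u: np.ndarray, lo: float, hi: float, ramp: float) -> np.ndarray:
    """Flat-top window: 1 on [lo, hi], linear ramp to 0 over ``ramp`` bp."""
    ramp = max(ramp, 1e-9)
    rising = np.clip((u - (lo - ramp)) / ramp, 0.0, 1.0)
    falling = np.clip(((hi + ramp) - u) / ramp, 0.0, 1.0)
    return np.minimum(rising, falling)


def methylation_profile(
    positions: np.ndarray, genes: pd.DataFrame, config: SimConfig
) -> np.ndarray:
    """Noise-free methylation level at sorted positions of one contig."""
    positions = np.asarray(positions)
    level = np.full(positions.shape, config.background_methylation, dtype=float)
    for gene in genes.to_dict("records"):
        arch = config.archetypes[gene["archetype"]]
        # gene-body level (c5 genes are lowly methylated across the body)
        if arch.body_level != config.background_methylation:
            lo = np.searchsorted(positions, int(gene["start"] - arch.ramp - 1))
            hi = np.searchsorted(positions, int(gene["end"] + arch.ramp + 1))
            body = _trapezoid(
                positions[lo:hi].astype(float),
                gene["start"],
                gene["end"] - 1,
                arch.ramp,
            )
            level[lo:hi] += body * (arch.body_level - config.background_methylation)
        if arch.dip_depth > 0:
            t = tss(gene)
            extent = int(max(arch.up_halfwidth, arch.down_halfwidth) + arch.ramp + 1)
            lo = np.searchsorted(positions, t - extent)
            hi = np.searchsorted(positions, t + extent)
            window = positions[lo:hi]
            u = (window - t) if gene["strand"] == "+" else (t - window)
            dip = arch.dip_depth * _trapezoid(
                u.astype(float), -arch.up_halfwidth, arch.down_halfwidth, arch.ramp
            )
            level[lo:hi] *= 1.0 - dip
    return np.clip(level, 0.0, 1.0)


def cpg_positions(genome: GenomeSequence, contig: str) -> np.ndarray:
    """0-based positions of the C of each CpG on the + strand."""
    arr = np.frombuffer(genome.contigs[contig].encode("ascii"), dtype=np.uint8)
    return np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))


def _truth_hypomethylated(
    positions: np.ndarray, profile: np.ndarray, config: SimConfig, contig: str
) -> pd.DataFrame:
    """Record planted hypomethylated intervals from the noise-free profile."""
    below = profile < config.umr_alpha
    records = []
    run: list[int] = []
    for i in np.flatnonzero(below):
        if run and positions[i] - positions[run[-1]] > config.umr_max_gap:
            records.append(run)
            run = []
        run.append(i)
    if run:
        records.append(run)
    out = []
    for run in records:
        if len(run) < config.umr_min_cpgs:
            continue
        mean = float(profile[run].mean())
        label = (
            "UMR"
            if len(run) >= config.umr_class_min_cpgs
            and mean < config.umr_class_max_mean
            else "LMR"
        )
        out.append(
            {
                "contig": contig,
                "start": int(positions[run[0]]),
                "end": int(positions[run[-1]]) + 2,
                "label": label,
                "n_cpg": len(run),
                "mean_meth": mean,
            }
        )
    return pd.DataFrame(
        out, columns=["contig", "start", "end", "label", "n_cpg", "mean_meth"]
    )


def make_methylome(
    genome: GenomeSequence,
    genes: pd.DataFrame,
    config: SimConfig,
    truth: SimTruth | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Per-CpG fractional methylation with coverage, plus truth intervals."""
    rng = config.rng(1)
    if truth is None:
        truth = SimTruth()
    frames = []
    umr_frames = []
    for contig in genome.contigs:
        pos = cpg_positions(genome, contig)
        contig_genes = genes[genes["contig"] == contig]
        profile = methylation_profile(pos, contig_genes, config)
        noisy = np.clip(
            profile + rng.normal(0.0, config.meth_noise_sd, pos.size), 0.0, 1.0
        )
        coverage = rng.poisson(config.coverage_mean, pos.size)
        noisy = np.where(coverage > 0, noisy, np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "contig": contig,
                    "pos": pos,
                    "fraction": noisy,
                    "coverage": coverage,
                }
            )
        )
        umr_frames.append(_truth_hypomethylated(pos, profile, config, contig))
    track = make_methylation_track(
        pd.concat(frames)["contig"],
        pd.concat(frames)["pos"],
        pd.concat(frames)["fraction"],
        pd.concat(frames)["coverage"],
    )
    truth.umrs = pd.concat(umr_frames, ignore_index=True)
    return track, truth


# ---------------------------------------------------------------------------
# Mutation generator
# ---------------------------------------------------------------------------

# per-context class index lookup: context code -> its three 96-class indices
_CONTEXT_CLASSES = np.zeros((32, 3), dtype=np.int64)
for _code in range(32):
    _CONTEXT_CLASSES[_code] = np.flatnonzero(CLASS_TO_CONTEXT == _code)


def _site_weights(
    codes: np.ndarray,
    meth: np.ndarray,
    signature: str,
    config: SimConfig,
) -> np.ndarray:
    """Unnormalized per-position sampling weights for one signature."""
    w96 = config.signatures.probs(signature)
    coupled = signature in config.meth_coupled_signatures
    w32_plain = np.zeros(32)
    w32_coupled = np.zeros(32)
    mask = NCG_T_CLASSES & coupled
    np.add.at(w32_plain, CLASS_TO_CONTEXT[~mask], w96[~mask])
    if coupled:
        np.add.at(w32_coupled, CLASS_TO_CONTEXT[mask], w96[mask])
    valid = codes >= 0
    weights = np.zeros(codes.shape, dtype=float)
    weights[valid] = w32_plain[codes[valid]]
    if coupled and w32_coupled.any():
        weights[valid] += w32_coupled[codes[valid]] * np.power(
            meth[valid], config.kappa_meth
        )
    if signature in config.apobec_signatures:
        weights[valid] *= 1.0 + config.gamma_apobec * (1.0 - meth[valid])
    return weights


def _positional_modifiers(
    n: int, genes: pd.DataFrame, config: SimConfig
) -> tuple[np.ndarray, pd.DataFrame]:
    """Planted positional factor per position: 5' depletion and gene multipliers."""
    mod = np.ones(n, dtype=float)
    windows = []
    if config.depletion_d < 1.0:
        for gene in genes.to_dict("records"):
            w0, w1 = _oriented_window(gene, config.depletion_window)
            w0, w1 = max(0, w0), min(n, w1)
            mod[w0:w1] *= config.depletion_d
            windows.append(
                {
                    "gene_id": gene["gene_id"],
                    "contig": gene["contig"],
                    "start": w0,
                    "end": w1,
                }
            )
    if config.burden_multipliers:
        by_id = genes.set_index("gene_id")
        for gid, factor in config.burden_multipliers.items():
            g = by_id.loc[gid]
            mod[int(g["start"]): int(g["end"])] *= float(factor)
    return mod, pd.DataFrame(windows, columns=["gene_id", "contig", "start", "end"])


def make_mutations(
    genome: GenomeSequence,
    genes: pd.DataFrame,
    config: SimConfig,
    truth: SimTruth | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Sample signature-labelled SNVs with methylation-coupled site rates.

    Site rates follow ``w(context) * m(site)`` where m couples to the
    noise-free methylation profile as described in the module docstring. At
    most one mutation is kept per (sample, site), matching SNV-call semantics.
    """
    rng = config.rng(2)
    if truth is None:
        truth = SimTruth()
    if truth.gene_archetype is None:
        truth.gene_archetype = genes.set_index("gene_id").get("archetype")
    records = []
    for contig, seq in genome.contigs.items():
        codes = genome.context_codes(contig)
        n = len(seq)
        contig_genes = genes[genes["contig"] == contig]
        meth = methylation_profile(np.arange(n), contig_genes, config)
        posmod, windows = _positional_modifiers(n, contig_genes, config)
        truth.depletion_windows = windows
        seq_arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        for sig in config.signatures.signatures:
            mean = config.mutations_per_sample.get(sig, 0.0)
            if mean <= 0:
                continue
            weights = _site_weights(codes, meth, sig, config) * posmod
            total = weights.sum()
            if total <= 0:
                if config.signatures.context_marginal(sig) is not None and mean > 0:
                    # spectrum has no mass on available contexts at current
                    # methylation: legitimate only when coupling zeroes it
                    w32 = config.signatures.context_marginal(sig)
                    avail = np.bincount(codes[codes >= 0], minlength=32) > 0
                    if not (w32[avail] > 0).any():
                        raise ValueError(
                            f"signature {sig!r} has zero spectrum mass on the "
                            "contexts available in the genome"
                        )
                continue
            cum = np.cumsum(weights)
            cum /= cum[-1]
            for s in range(config.n_samples):
                n_mut = rng.poisson(mean)
                if n_mut == 0:
                    continue
                sites = np.searchsorted(cum, rng.random(n_mut), side="right")
                sites = np.unique(sites)  # at most one mutation per (sample, site)
                ctx = codes[sites]
                cls_idx = _CONTEXT_CLASSES[ctx]  # (n, 3)
                w96 = config.signatures.probs(sig)
                masses = w96[cls_idx].astype(float)
                if sig in config.meth_coupled_signatures:
                    coupled = NCG_T_CLASSES[cls_idx]
                    factor = np.power(meth[sites], config.kappa_meth)
                    masses = np.where(coupled, masses * factor[:, None], masses)
                row_sums = masses.sum(axis=1, keepdims=True)
                keep = row_sums[:, 0] > 0
                sites, ctx, cls_idx, masses, row_sums = (
                    sites[keep],
                    ctx[keep],
                    cls_idx[keep],
                    masses[keep],
                    row_sums[keep],
                )
                probs = masses / row_sums
                u = rng.random(sites.size)
                choice = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
                choice = np.clip(choice, 0, 2)
                classes = cls_idx[np.arange(sites.size), choice]
                for site, cls in zip(sites, classes):
                    label = CLASSES_96[cls]
                    ref = chr(seq_arr[site])
                    pyr_ref, pyr_alt = label[2], label[4]
                    if ref in "CT":
                        alt = pyr_alt
                    else:
                        alt = {"A": "T", "C": "G", "G": "C", "T": "A"}[pyr_alt]
                    records.append(
                        {
                            "sample_id": f"s{s:03d}",
                            "contig": contig,
                            "pos": int(site),
                            "ref": ref,
                            "alt": alt,
                            "context": label[0] + label[2] + label[6],
                            "class96": label,
                            "signature": sig,
                        }
                    )
    mutations = pd.DataFrame(
        records,
        columns=[
            "sample_id",
            "contig",
            "pos",
            "ref",
            "alt",
            "context",
            "class96",
            "signature",
        ],
    )
    # at most one record per (sample, site), across signatures too
    mutations = (
        mutations.drop_duplicates(["sample_id", "contig", "pos"])
        .sort_values(["contig", "pos", "sample_id"], kind="mergesort")
        .reset_index(drop=True)
    )
    return mutations, truth


@dataclasses.dataclass
class Cohort:
    """A complete simulated study: inputs plus planted truth."""

    config: SimConfig
    genome: GenomeSequence
    genes: pd.DataFrame
    methylome: pd.DataFrame
    mutations: pd.DataFrame
    truth: SimTruth

    def exposures(self) -> pd.DataFrame:
        """Expected mutation counts per (sample, signature)."""
        samples = [f"s{i:03d}" for i in range(self.config.n_samples)]
        return pd.DataFrame(
            {
                sig: [self.config.mutations_per_sample.get(sig, 0.0)] * len(samples)
                for sig in self.config.signatures.signatures
            },
            index=samples,
        )


def simulate_cohort(config: SimConfig) -> Cohort:
    """Run all three generators in order and bundle the outputs."""
    genome, genes, truth = make_genome(config)
    methylome, truth = make_methylome(genome, genes, config, truth)
    mutations, truth = make_mutations(genome, genes, config, truth)
    truth.burden_multiplier = pd.Series(
        {g: 1.0 for g in genes["gene_id"]}, name="burden_multiplier"
    )
    if config.burden_multipliers:
        for gid, factor in config.burden_multipliers.items():
            truth.burden_multiplier[gid] = factor
    return Cohort(config, genome, genes, methylome, mutations, truth)


# ---------------------------------------------------------------------------
# Gene-level burden generator (for the selection-baseline stage)
# ---------------------------------------------------------------------------


def make_gene_burden(
    seed: int,
    n_genes: int = 2500,
    n_covariates: int = 3,
    covariate_effects: Sequence[float] = (0.3, -0.2, 0.1),
    group_effects: Mapping[str, float] | None = None,
    driver_frac: float = 0.05,
    driver_multiplier: float = 1.0,
    base_rate_per_bp: float = 0.02,  # ~30 mutations/gene: cohort-scale counts
    dispersion_alpha: float = 0.05,
    group_probs: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Per-gene mutation burdens from a known NB generating model.

    Emulates a cohort-level exome burden table: log-normal gene lengths,
    Dirichlet trinucleotide compositions, numeric epigenomic covariates that
    truly modulate the rate (mimicking replication-time-like covariates),
    methylation-group labels with optional planted multipliers, and held-out
    driver genes with a planted burden excess.
    """
    rng = np.random.default_rng([int(seed), 99])
    groups = list((group_probs or {k: 0.2 for k in "c1 c2 c3 c4 c5".split()}))
    gp = np.array(list((group_probs or {k: 0.2 for k in groups}).values()))
    gp = gp / gp.sum()
    length = np.exp(rng.normal(np.log(1500), 0.5, n_genes)).astype(int) + 200
    tri = rng.dirichlet(np.full(32, 5.0), size=n_genes)
    covs = rng.normal(0.0, 1.0, size=(n_genes, n_covariates))
    labels = rng.choice(groups, size=n_genes, p=gp)
    is_driver = np.zeros(n_genes, dtype=bool)
    n_driver = int(round(driver_frac * n_genes))
    if n_driver:
        is_driver[rng.choice(n_genes, n_driver, replace=False)] = True

    eta = np.log(base_rate_per_bp * length)
    for k, gamma in enumerate(covariate_effects[:n_covariates]):
        eta = eta + gamma * covs[:, k]
    if group_effects:
        for g, mult in group_effects.items():
            eta = eta + np.where(labels == g, np.log(mult), 0.0)
    if driver_multiplier != 1.0:
        eta = eta + np.where(is_driver, np.log(driver_multiplier), 0.0)
    mu = np.exp(eta)
    if dispersion_alpha > 0:
        lam = mu * rng.gamma(1.0 / dispersion_alpha, dispersion_alpha, n_genes)
    else:
        lam = mu
    y = rng.poisson(lam)

    features = pd.DataFrame(
        {
            "gene_id": [f"g{i:05d}" for i in range(n_genes)],
            "y": y,
            "length": length,
            "group": labels,
            "is_cancer_gene": is_driver,
        }
    )
    for i in range(32):
        features[f"tri_{i:02d}"] = tri[:, i]
    for k in range(n_covariates):
        features[f"cov_{k}"] = covs[:, k]
    features.attrs["true_mu"] = mu
    return features
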