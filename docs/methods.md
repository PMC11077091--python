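# Methods

## Coordinates, contexts and conventions

All coordinates are 0-based half-open internally; BED is native, mutation TSVs
are declared 1-based (the common caller convention) and converted on read.
Trinucleotide contexts are strand-collapsed onto the pyrimidine-centred
representation: 32 contexts and 96 substitution classes in COSMIC order.
Context assignment is an involution under reverse complement (property-tested).
Interval-edge 3-mers borrow one base of flanking genome where available, so a
partition of a contig into bins counts every interior position exactly once;
positions whose 3-mer contains an N carry no context and are excluded from
both opportunity counts and mutation tables.

## Bin-level rate model

Genes ≥ 10 kb are segmented, in transcription orientation, into 24 five-prime
250 bp bins over [TSS−2 kb, TSS+4 kb), 24 three-prime bins over
[TES−4 kb, TES+2 kb), 8 central bins over midpoint ± 1 kb, and a single 1 kb
reference bin at [TES+4 kb, TES+5 kb). The 10 kb minimum keeps the two inward
windows disjoint within a gene; on the minus strand the central anchor is the
oriented midpoint base (mid−1), which makes the segmentation exactly
mirror-symmetric. Bins overlapping bins of *other* genes in the same
expression tertile are removed from both genes; cross-tertile overlaps are
kept because tertiles are analyzed as separate sets.

For one analysis set the counts y<sub>g,b</sub> follow a negative-binomial GLM
with log link,

    log mu_{g,b} = alpha + beta_b + log E_{g,b},

one observation per (gene, bin position), bin position coded as a factor with
the reference bin as baseline, and offset E<sub>g,b</sub> = Σ<sub>t</sub>
n<sub>g,b,t</sub> w<sub>t</sub>, where w is the signature's spectrum summed to
its 32-context marginal and renormalized. Using (gene, bin) observations
rather than gene-aggregated bins lets the NB dispersion absorb gene-level rate
heterogeneity. The NB2 dispersion α (variance μ + αμ²) is profiled: we
alternate a GLM fit at fixed α with a bounded one-dimensional ML update of α
given the fitted means, preferring the Poisson boundary when it is at least as
likely; a failed NB fit falls back to Poisson and is flagged. Intervals are
Wald 95% CIs; no multiple-testing correction is applied to per-bin β — the
output of interest is the profile, and calibration is asserted on synthetic
nulls instead (the null suite requires the per-bin false-positive rate at
p<0.05 to sit in [3%, 7%]). Multiplying all context counts by a constant
shifts only α (asserted to 1e−8), and the NB fit on Poisson data reproduces
the ratio-of-sums estimator (the Poisson MLE for this design) to within 1%.

## Factorization

The per-set β profiles (missing bins imputed as 0 = "no deviation from
reference", with a mask recorded) are centred by column — never
variance-scaled — and decomposed by SVD. Component signs are fixed so each
component's largest-|weight| entry is positive, making loadings reproducible.
The sparse variant maximizes u′Xv − λ|v|₁ by alternating soft-thresholded
power iterations with deflation between components: at λ = 0 this is the
power method and agrees with the plain PCA loadings to 1e−6 (asserted), and
the number of exactly-zero loading entries is monotone in λ. This
implementation was chosen over dictionary-learning sparse PCA precisely
because the λ→0 limit must coincide with the unpenalized factorization.

Confounder control refits the same observations with a per-(gene, bin)
covariate appended and reports likelihood-ratio tests of the bin-factor term
in both models; a gradient fully explained by the covariate loses bin-factor
significance in the adjusted fit. When the covariate is exactly collinear
with the bin factor the likelihoods remain well-defined (pinv fitting) but
only the sign of γ is identified.

## Methylation profiles and gene groups

TSS and TES windows extend 3 kb outward and 5 kb inward, tiled with 50 bp
segments (160 + 160 per gene, each gene instance independent). Segment values
are unweighted means over CpGs with coverage ≥ 5; a segment without covered
CpGs is missing, not zero. Rows with more than `max_missing` missing segments
are dropped and remaining gaps filled by row-local linear interpolation with
flanking fill. The function default is 0.3, but study-scale runs pass 0.8: at
human-like CpG density (~1 per 100 bp) most 50 bp segments outside islands
contain no CpG at all, so a 30% cut would discard nearly every gene; with
interpolation the retained rows are smooth enough for factorization.

The matrix is factorized with unscaled PCA (mePC1 ≈ whole-body methylation
level, mePC2 ≈ TSS-proximal dip, mePC3 ≈ upstream/downstream shift on the
synthetic archetypes) and the first three mePCs are clustered with k-medoids
(Euclidean distance, alternating assignment/medoid updates, 10 restarts, best
cost kept). k = 5 by default with an optional silhouette report over k = 2–7.
Group labels are renamed deterministically by *descending* group-mean
whole-gene methylation (ties by ascending dip width), so c1 is the
most-methylated group and c5 the hypomethylated-body group — matching the
archetype semantics users expect; any label-invariant comparison (ARI) is
unaffected by this choice.

Per-group gradients are summarized by the per-segment median with the exact
binomial order-statistic CI: bounds are the j-th and (n+1−j)-th order
statistics with j the largest rank whose two-sided coverage under
Binomial(n, ½) reaches 95%; when n is too small for any interior pair to reach
95% (n ≤ 5) the interval clamps to [min, max].

## UMR/LMR segmentation

The caller is deliberately simple and deterministic rather than an HMM:
coverage-filtered (≥ 5 reads) per-CpG fractions are smoothed with a 3-CpG
running mean; maximal runs of smoothed values < α<sub>meth</sub> (default
0.5) with inter-CpG gaps ≤ 1 kb and ≥ 4 CpGs become regions spanning first to
last CpG (end = last CpG + 2). Regions with ≥ 30 CpGs and raw mean fraction
< 0.1 are UMRs, the rest LMRs. Partially-methylated-domain masking is out of
scope. The caller is validated against planted truth (base-pair Jaccard
≥ 0.9, 100% class agreement at noise σ = 0.05) and total called bases are
monotone in α<sub>meth</sub>. Tissue-specific sets keep regions with ≤ 20%
of their bases covered by any other tissue group's merged regions — a
pragmatic rule, surfaced as a parameter.

Region-rate contrasts use the same NB offset machinery with an in-vs-flank
indicator: flanks are 2 kb per side minus overlap with other regions of the
set, offsets are trinucleotide-expected opportunities under the signature's
context marginal (or the catalog's pooled empirical context distribution when
no signature is specified), and depletion % = 100·(1 − exp(β)). Paired-locus
contrasts compare each locus against a same-length window ending 10 kb
upstream (orientation-aware, off-contig references dropped and counted), one
independent regression per (sample group × signature × locus type) stratum,
which holds the broader replication-timing domain approximately fixed.

Overlap statistics: odds ratios are computed on a fixed-width unit universe
(default 1 kb; membership = any overlap) with Haldane–Anscombe 0.5 correction
for zero cells and Fisher's exact p; contingency enrichment reports O/E with
adjusted standardized-residual p-values, BH-corrected across cells; upset
counts use exact-subset semantics so the combinations partition the region
set.

## Selection baseline

Per-gene burdens are modelled as NB with log(gene length) offset; covariates
are the 32 normalized trinucleotide fractions (the first dropped as reference
to break the sum-to-one collinearity), generic numeric epigenomic covariates,
and — in the methylation variant — treatment-coded group labels. Known cancer
genes are excluded from all fitting and scored out of model. Cross-validation
is stratified over non-cancer genes with fold assignments shared across the
three variants within a run; RMSE is computed on raw counts per fold and
averaged within runs; the group-term LRT is evaluated on every fold's
training fit (runs × folds p-values), and the shuffled variant re-permutes
the label multiset once per run, preserving class imbalance. Excess burden is
100·(y − ŷ)/ŷ with out-of-fold (for held-out drivers: cross-fold mean)
predictions.

## Synthetic cohorts: what they emulate and what they do not

`make_genome` packs non-overlapping genes (lengths uniform 12–20 kb,
spacing 12 kb, random strand, log-normal expression split into tertiles) into
a single contig with background CpG density 0.01/bp and, for island-bearing
archetypes, a 10× CpG-enriched window over [TSS−0.5 kb, TSS+1 kb).
`make_methylome` draws per-CpG fractions from archetype profiles — flat-top
trapezoid dips with 300 bp linear ramps; c1 no dip, c2 shallow/narrow
(depth 0.5, −0.3/+0.5 kb), c3 downstream-shifted (depth 0.95, −0.25/+2 kb),
c4 wide symmetric (depth 0.95, ±2 kb), c5 constant low body (0.25) — plus
truncated-Gaussian noise (σ = 0.05 default) and Poisson(30) coverage. Dip
depth 0.95 over a 0.8 background gives a floor of 0.04, so planted regions
genuinely satisfy the UMR definition (mean < 0.1). `make_mutations` samples
sites in proportion to spectrum mass times a methylation modifier evaluated
on the noise-free profile — fraction^κ (κ = 1) for the NCG>T classes of
coupled signatures, 1 + γ(1 − fraction) (γ = 1) for APOBEC-type — times
planted positional factors (5′ windows, gene multipliers), then draws the
substitution class conditionally; at most one mutation per (sample, site).
The three bundled spectra are idealized (SBS1-like: all mass on N[C>T]G;
SBS2-like: T[C>T/G]A|T; SBS5-like: flat), not COSMIC estimates.

The gene-burden generator emulates a cohort-scale exome table directly at the
count level: NB burdens (Gamma-mixed Poisson, α = 0.02) around
log-length-offset means with truly informative numeric covariates, planted
group multipliers and held-out drivers. The default rate (0.02/bp, ≈ 30–40
mutations per gene) represents cohort-aggregated counts, which is what makes
a ±10-point band around a planted +45% driver excess resolvable with ~150
driver genes.

Not emulated: chromosome-scale replication-timing structure, indels and copy
number, realistic COSMIC spectra, PMDs, sequence-dependent coverage bias, and
inter-sample heterogeneity of exposures. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated generative
assumptions, not performance on real tumor data.

## Study sizes and numerical choices

Study-scale experiments (the `study` module, used by the analysis drivers and
the acceptance script) run at: 200 analysis sets for null calibration
(count-level Poisson draws from the package-computed opportunities — exactly
the marginal law of uniform-rate site sampling), 2000 genes / ~2×10⁴
mutations for depletion recovery, 1000 genes for clustering, 200 genes for
region calling, 100 replicate catalogs for CI coverage, and 3000 genes × 15
runs × 5 folds for selection. At the depletion-recovery scale a single bin's
exp(β) carries ~12% standard error (shared reference-bin noise dominates), so
recovery of the planted 0.5 is assessed on the pooled (geometric-mean)
5′-window estimate, while out-of-window bins are checked per-bin for 95% CI
coverage of 1.0. Seeds propagate through `numpy.random.default_rng` with
fixed stream offsets per stage; every generator and every clustering restart
is deterministic under the configured seed.
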