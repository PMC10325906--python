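# Methods

`epiferro` implements the computational core of an iron-dependent
epigenetic-reprogramming analysis in differentiating adipocytes: screens for
coordinated CpG demethylation at promoters and putative enhancers between
whole-genome bisulfite sequencing (WGBS) timepoints, soft clustering of
temporal ChIP-seq signal around transcription start sites (TSSs),
aggregation of chromatin-signal and methylation change around differentially
methylated regions (DMRs), and a handful of closed-form assay
quantifications. This note records the models, the parameters that matter,
the numerical choices, and what the synthetic-data generator does and does
not emulate.

## Coordinate and file conventions

All coordinates are 0-based half-open; a CpG cytosine at position *p* is the
interval [*p*, *p*+1). Chromosome names are matched as exact strings and
sorting is lexicographic chromosome then numeric position, so outputs are
deterministic across platforms. Methylomes travel as per-CpG bedGraph: the
canonical `counts6` dialect carries `chrom start end meth% n_meth n_unmeth`
(coverage = n_meth + n_unmeth); a `level4` dialect without counts is
accepted for I/O but rejected by any depth-aware operation, because the
screens are defined on read depth. Duplicate CpG records with identical
values collapse silently; conflicting duplicates are an error (safer than
last-wins). Each record is treated as an independent cytosine; whether the
two strands of a CpG dyad were collapsed upstream is a property of the input
track, not of this package.

## Demethylation screen

Given a baseline and a later methylome, CpGs with coverage outside
[`min_cov`, `max_cov`] = [5, 1000] (closed bounds) in **either** track are
discarded, and the per-CpG change Δ = meth_later − meth_base (percentage
points) is computed on the joint survivors. Filtering is joint so that every
Δ is defined on depth-reliable values at both ends; the alternative
(per-track qualification) would let a CpG's change rest on an unreliable
baseline. A region — a gene's pooled strand-aware upstream windows
([t − 1000, t) on plus, [t + 1, t + 1001) on minus, one per TSS, TSS base
excluded on both strands) or an enhancer window — is a hit when at least
`min_cpgs` = 3 of its CpGs satisfy Δ < −`drop` = −50 strictly. "More than a
50 % reduction" is read as an absolute drop of more than 50 percentage
points, consistent with the change being computed by subtraction of levels;
a relative reading (Δ/meth_base) is available behind the `relative` flag
rather than guessed silently. Both thresholds are strict/closed exactly:
coverage 5 and 1000 pass, 4 and 1001 do not; Δ = −50.0 never qualifies. A
CpG lying in windows of several genes counts for each gene, but only once
per gene even when that gene's windows overlap.

Contrasting the hit sets of the untreated (DFO(−)) and iron-chelated
(DFO(+)) differentiation arms partitions regions into A-only / B-only /
shared; the A-only set is the iron-dependent demethylated compartment.

## Enhancer construction

Per-timepoint peak sets are merged (bedtools-`merge` semantics; book-ended
intervals merge by default, configurable because peak callers differ),
merged peaks overlapping any pre-induction peak by ≥ 1 bp are removed
(`intersect -v` semantics; book-ended contact is not overlap), and each
survivor's floor midpoint ± 500 bp becomes a putative
differentiation-specific enhancer window. Subtraction runs at the peak
level, before centering — the prose source is ambiguous on the order, and
peak-level subtraction matches the operation's signature on peaks. Windows
clipped at chromosome ends keep their true length, which is what enters any
length normalisation. Even-width midpoints use floor, the common toolkit
convention.

## TSS signal quantification and fuzzy clustering

ChIP read counts over each gene's TSS ± 5 kb regions (windows of one gene
merged when they overlap; genes never merge with each other) are normalised
as counts-per-million per sample, then per kilobase of the gene's merged
window length, averaged across replicates, filtered by coefficient of
variation (population sd/mean < 0.2 removed, on the linear scale), log2(x+1)
transformed and row z-scored (population sd; zero-variance rows dropped with
a warning).

Clustering is fuzzy c-means minimising J = Σᵢₖ uᵢₖᵐ dᵢₖ² with Euclidean d
and fuzzifier m = 2 by default (m is a knob; data-driven fuzzifier
estimation is out of scope). Updates alternate centroids
vₖ = Σᵢ uᵢₖᵐ xᵢ / Σᵢ uᵢₖᵐ and memberships
uᵢₖ = 1 / Σⱼ (dᵢₖ/dᵢⱼ)^(2/(m−1)); a point coinciding with centroids splits
its membership equally among the coincident ones. Initialisation is a
seeded random membership matrix with normalised rows; iteration stops when
the largest membership change falls below `tol` = 1e−6 or after `max_iter` =
300 rounds, and the objective is recorded each iteration (it is
non-increasing, asserted in tests). Because the objective is multimodal —
temporal profiles on the z-score circle can trap single runs in merged-
centroid optima — the CLI and pipeline run `n_init` = 10 seeded restarts and
keep the lowest-objective fit; the library default stays at one run so a
single seed reproduces one deterministic trajectory.

Cluster count is a user decision informed by the Dmin diagnostic: for each
candidate c the model is fitted `repeats` = 3 times with deterministically
derived seeds and the mean minimum pairwise centroid distance is tabulated.
A sharp Dmin decay flags over-clustering; the tool never picks c itself.
Hard labels are argmax membership, ties to the lowest cluster index, and are
1-based.

## DMR-anchored aggregation

Binned coverage tracks (fixed genome binning; this package consumes
pre-binned bedGraph, with read extension belonging to track construction
upstream) are scaled so each track totals one million, subtracted per bin
(later − Day 0), and sampled in 10-bp bins across ± 3 kb of each DMR's floor
midpoint; the profile is the per-offset mean over anchors. Anchors whose
window leaves the chromosome are skipped and counted; an optional per-anchor
skip-zeros rule excludes anchors sampling an all-zero window. Methylation
change is aggregated by pooling per-CpG Δ into offset bins across all
anchors (CpGs are sparse, so per-anchor averaging would be dominated by
empty anchors); bins with no CpG are reported as missing (NaN), never zero —
ChIP bins without signal are genuine zeros, methylation bins without CpGs
are absent measurements. The pipeline uses 100-bp bins for the methylation
profile (`meth_bin`) for the same sparsity reason. Duplicate anchors leave
the curve unchanged (equal reweighting), asserted in tests.

## Assay formulas

All closed forms are pure functions: HTRF demethylase activity
DF% = ((665/620)₊ / (665/620)₋ − 1) × 100; lysosomal flux = level under
bafilomycin A1 − vehicle level (negative flux reported and flagged, not
clipped — it is meaningful assay noise); treatment delta = post − pre; ChIP
%input = 100 · IP / (input / input_fraction), with the input dilution
fraction a required explicit argument (no hidden default); bisulfite-clone
summaries as percent methylated clones per CpG and percent methylated calls
overall (complete matrices only; alignment QC is out of scope); pixel
colocalization as the Pearson coefficient over a masked (cytoplasmic) pixel
set, undefined and rejected for constant channels.

## Synthetic-data generator

The generator emits every input the pipeline consumes, with a ground-truth
manifest, under one seed (per-stage RNG streams derived from it, so the
output tree is byte-identical across runs). The emulated design: two
chromosomes of 2 Mb; 200 genes in fixed 20-kb slots (20 % with a second TSS
2–5 kb downstream, both strands); CpGs at exponential spacing with 100-bp
mean; per-CpG coverage from a negative binomial (mean 30, dispersion 5) with
a 0.2 % fraction pushed to 1200–2000× so both depth bounds are exercised;
baseline methylation from Beta(8, 2) × 100 (high-methylation genome);
per-timepoint level noise of 3 points; 20 planted genes whose promoter CpGs
drop 60 points at Day 8 in the untreated arm only; 150 peaks (30 %
induced-only, absent from the Day-0 set); ChIP counts for three conditions ×
two replicates following 7 evenly spaced temporal prototypes on the z-score
circle (log2 amplitude 1–1.5, replicate noise 0.15 on the log2 scale, 10 %
of genes flat so the CV filter has work to do); and 40 DMRs of 200–600 bp on
chromosome 1 where the untreated Day-2 coverage track loses a cusp-shaped
60 % of signal (decay length 150 bp) and the untreated Day-8 methylome loses
40 points. Gene, peak and DMR zones occupy disjoint bands within each slot
so planted signals never collide.

Planted promoters are drawn among genes whose upstream window carries at
least 8 CpGs, their window CpGs get coverage clamped to 50–200× and
baselines of at least effect + 15 points. This emulates the compartment the
screen targets — CpG-dense promoters measured at replicate-merged depth —
and guarantees that the planted condition (a realisable 60-point drop at ≥ 3
well-covered CpGs) actually holds in every emitted dataset rather than only
in expectation.

What the generator does **not** emulate, and hence what passing tests do not
show about real data: no read-level or bisulfite-conversion error model
(counts are drawn binomially from the true level); coverage is independent
per CpG, with no positional autocorrelation or mappability structure;
methylomes have no partially methylated domains or CpG-island shores; ChIP
coverage tracks are expected-value tracks (smooth background × dip factor +
low-amplitude white noise), not read-sampled pileups, which is the
resolution at which a 10-bp-binned aggregation argmin is meaningful; and
there are no batch or replicate effects beyond i.i.d. noise. Recovery
results on this generator validate the algebra and thresholds of the
pipeline, not its behaviour under real-data artefacts.

## Problem sizes and determinism

Default problem sizes (2 × 2 Mb genome, ~40 k CpGs per methylome, 200 genes,
200 k track bins) were chosen so a full generate-plus-pipeline run completes
in a few seconds while every mechanism — depth filtering at both bounds,
multi-TSS merging, clipping, induced-only peaks, flat-gene CV removal, dip
recovery — is exercised. Every random draw descends from a single seed; the
pipeline refuses to overwrite a non-empty output directory and writes a
resolved copy of its configuration, a funnel log (no timestamps, so output
trees are byte-comparable) and a machine-readable summary.

## Known limitations

The screen does not test statistical significance of methylation change —
DMR calling belongs to dedicated callers and DMRs are consumed, not
computed. Fuzzy c-means restarts reduce but do not eliminate sensitivity to
initialisation; the Dmin table is a diagnostic, not a model-selection
criterion with guarantees. bigWig tracks, BAM/FASTQ input, and GTF/GFF
annotation are out of scope; the plain TSV gene table is the annotation
contract.
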