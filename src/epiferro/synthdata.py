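"""Seeded synthetic-data generator emulating the study's data structure.

The generator emits every input the pipeline consumes — a gene annotation,
per-condition WGBS methylomes, per-timepoint peak sets, a TSS +/-5 kb ChIP
count table, binned ChIP coverage tracks and a DMR anchor set — together
with a ground-truth manifest, so every stage is testable without any
download.

The emulated design follows the study layout: preadipocytes differentiated
with (``DFOplus``, iron-chelated) or without (``DFOminus``, untreated) an
iron chelator; methylomes at Day 0 and Day 8; H3K27ac-style peak sets at
Day 0 / Day 2 / Day 8 with an induced-only fraction; H3K9me2-style ChIP
counts at Day 0 and Day 2 under both arms with two replicates; and a set of
differentially methylated regions where the untreated Day-2 histone track
loses signal and the untreated Day-8 methylome loses methylation.

Planted promoter demethylation is applied on the same strand-aware upstream
windows the screen uses (one shared window definition), restricted to the
untreated arm.  Coverage is sampled per CpG independently from a negative
binomial — adequate for exercising the depth filter, with no positional
autocorrelation — and a small fraction of sites is pushed below the lower
and above the upper depth bound on purpose.

ChIP coverage tracks are expected-coverage tracks (smooth background times
a dip factor, plus low-amplitude white noise), not read-sampled counts;
read-level simulation is out of scope.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import regions
from .aggregate import BinnedTrack, write_binned_bedgraph
from .genomio import (
    GeneModel,
    GenomicInterval,
    MethylomeTrack,
    SignalMatrix,
    write_chrom_sizes,
    write_count_table,
    write_genes,
    write_intervals_bed,
    write_methylome_bedgraph,
)

__all__ = ["SimConfig", "TruthManifest", "make_annotation", "simulate_methylomes",
           "simulate_peaks", "simulate_chip", "simulate_chip_tracks",
           "simulate_all"]


@dataclass
class SimConfig:
    """All knobs of the generator.  Defaults encode the emulated study
    design at desk scale; a fixed seed yields byte-identical output trees."""

    # genome / annotation
    n_chroms: int = 2
    chrom_length: int = 2_000_000
    n_genes: int = 200
    multi_tss_fraction: float = 0.2

    # WGBS methylomes
    cpg_spacing: float = 100.0            # mean CpG gap in bp
    coverage_mean: float = 30.0           # negative-binomial mean read depth
    coverage_dispersion: float = 5.0      # negative-binomial size parameter
    high_cov_fraction: float = 0.002      # sites pushed above the upper bound
    high_cov_range: tuple[int, int] = (1200, 2000)
    meth_beta: tuple[float, float] = (8.0, 2.0)   # high-methylation baseline
    noise_sd: float = 3.0                 # per-timepoint level noise, points
    n_planted: int = 20
    effect_points: float = 60.0           # planted promoter drop, points
    planted_condition: str = "DFOminus"
    planted_min_cpgs: int = 8             # eligibility: CpG-dense promoters
    planted_cov_range: tuple[int, int] = (50, 200)  # replicate-merged depth
    upstream_size: int = 1000

    # peak sets
    n_peaks: int = 150
    induced_fraction: float = 0.3
    peak_width: tuple[int, int] = (200, 800)
    peak_timepoints: tuple[str, ...] = ("Day0", "Day2", "Day8")
    preinduction_timepoint: str = "Day0"

    # ChIP counts and temporal prototypes
    chip_conditions: tuple[str, ...] = ("Day0", "Day2_DFOminus", "Day2_DFOplus")
    n_replicates: int = 2
    n_prototypes: int = 7
    flat_fraction: float = 0.1            # low-CV genes removed by the filter
    amp_range: tuple[float, float] = (1.0, 1.5)     # log2 amplitude
    base_log2_range: tuple[float, float] = (5.0, 9.0)
    chip_noise_sd: float = 0.15           # log2-scale replicate noise
    tss_flank: int = 5000

    # DMRs and binned tracks
    n_dmrs: int = 40
    dmr_width: tuple[int, int] = (200, 600)
    dip_depth: float = 0.6                # fractional signal loss at center
    dip_tau: float = 150.0                # cusp decay length, bp
    dmr_meth_effect: float = 40.0         # Day-8 methylation drop in DMRs
    track_bin: int = 10
    track_chrom_index: int = 0            # tracks cover this chromosome only
    track_noise_sd: float = 0.02

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chroms < 1 or self.n_genes < 1:
            raise ValueError("need at least one chromosome and one gene")
        if not 0 <= self.n_planted <= self.n_genes:
            raise ValueError("n_planted outside [0, n_genes]")
        if not 0 <= self.effect_points <= 100:
            raise ValueError("effect size must be in [0, 100] points")
        if not 0 <= self.dmr_meth_effect <= 100:
            raise ValueError("DMR methylation effect must be in [0, 100]")
        if self.seed < 0:
            raise ValueError("seed must be >= 0")

    # deterministic per-stage RNG streams, independent of call order
    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stage])

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(d)
        for f in dataclasses.fields(cls):
            if f.name in kwargs and isinstance(f.default, tuple):
                kwargs[f.name] = tuple(kwargs[f.name])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return {k: (list(v) if isinstance(v, tuple) else v) for k, v in out.items()}


@dataclass
class TruthManifest:
    """Ground truth of one generated dataset."""

    planted_genes: dict[str, list[str]]
    effect_points: float
    induced_peaks: list[tuple[str, int, int]]
    cluster_labels: dict[str, int]        # 0 = flat (below the CV filter)
    dmrs: list[tuple[str, int, int]]
    dip_depth: float
    dmr_meth_effect: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "planted_genes": self.planted_genes,
            "effect_points": self.effect_points,
            "induced_peaks": [list(p) for p in self.induced_peaks],
            "cluster_labels": self.cluster_labels,
            "dmrs": [list(d) for d in self.dmrs],
            "dip_depth": self.dip_depth,
            "dmr_meth_effect": self.dmr_meth_effect,
            "seed": self.seed,
        }

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        with open(path, "rt", encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            planted_genes={k: list(v) for k, v in d["planted_genes"].items()},
            effect_points=d["effect_points"],
            induced_peaks=[tuple(p) for p in d["induced_peaks"]],
            cluster_labels={k: int(v) for k, v in d["cluster_labels"].items()},
            dmrs=[tuple(x) for x in d["dmrs"]],
            dip_depth=d["dip_depth"],
            dmr_meth_effect=d["dmr_meth_effect"],
            seed=d["seed"],
        )


# ---------------------------------------------------------------------------
# genome layout helpers
# ---------------------------------------------------------------------------

# within each per-gene slot: the gene body/TSS zone, the peak zone and the
# DMR zone are disjoint bands so planted signals never collide
_TSS_JITTER = (6000, 9000)
_TSS2_OFFSET = (2000, 5000)
_PEAK_BAND = (15500, 16800)
_DMR_BAND = (17800, 19000)
_MIN_SLOT = 20_000


def _layout(config: SimConfig) -> tuple[int, int]:
    genes_per_chrom = math.ceil(config.n_genes / config.n_chroms)
    slot = config.chrom_length // genes_per_chrom
    if slot < _MIN_SLOT:
        raise ValueError(
            f"{config.n_genes} genes do not fit: need >= {_MIN_SLOT} bp per "
            f"gene, have {slot}"
        )
    return genes_per_chrom, slot


def _chrom_name(i: int) -> str:
    return f"chr{i + 1}"


def make_annotation(config: SimConfig) -> tuple[list[GeneModel], dict[str, int]]:
    """Deterministic gene placement: one gene per fixed-length slot, both
    strands represented, a configurable fraction with a second TSS 2–5 kb
    downstream of the first."""
    rng = config.rng(1)
    genes_per_chrom, slot = _layout(config)
    sizes = {_chrom_name(i): config.chrom_length for i in range(config.n_chroms)}
    width = len(str(config.n_genes))
    genes: list[GeneModel] = []
    for g in range(config.n_genes):
        chrom = _chrom_name(g // genes_per_chrom)
        slot_start = (g % genes_per_chrom) * slot
        tss1 = slot_start + int(rng.integers(_TSS_JITTER[0], _TSS_JITTER[1] + 1))
        tss = [tss1]
        if rng.random() < config.multi_tss_fraction:
            tss.append(tss1 + int(rng.integers(_TSS2_OFFSET[0], _TSS2_OFFSET[1] + 1)))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"gene_{g + 1:0{width}d}", chrom, strand, tuple(tss)))
    return genes, sizes


def _sorted_window_index(windows: Sequence[GenomicInterval]
                         ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append((w.start, w.end))
    out = {}
    for chrom, spans in by_chrom.items():
        spans.sort()
        out[chrom] = (np.array([s for s, _ in spans], dtype=np.int64),
                      np.array([e for _, e in spans], dtype=np.int64))
    return out


def _in_windows(chrom: str, pos: np.ndarray,
                index: Mapping[str, tuple[np.ndarray, np.ndarray]]) -> np.ndarray:
    """Membership mask for positions against disjoint sorted windows."""
    entry = index.get(chrom)
    if entry is None:
        return np.zeros(len(pos), dtype=bool)
    starts, ends = entry
    i = np.searchsorted(starts, pos, side="right") - 1
    ok = i >= 0
    mask = np.zeros(len(pos), dtype=bool)
    mask[ok] = pos[ok] < ends[i[ok]]
    return mask


# ---------------------------------------------------------------------------
# WGBS methylomes
# ---------------------------------------------------------------------------


def simulate_methylomes(config: SimConfig, genes: Sequence[GeneModel],
                        chrom_sizes: Mapping[str, int],
                        dmrs: Sequence[GenomicInterval] | None = None,
                        ) -> tuple[dict[str, MethylomeTrack], list[str]]:
    """Generate the Day-0 baseline methylome and Day-8 methylomes for the
    untreated and iron-chelated arms.

    Returns ``(tracks, planted_gene_ids)`` where ``tracks`` maps
    ``Day0 / Day8_DFOminus / Day8_DFOplus`` to methylome tracks.  Promoter
    demethylation of ``effect_points`` is planted in the untreated Day-8
    arm only, on the strand-aware upstream windows of ``n_planted`` genes;
    a ``dmr_meth_effect`` drop is planted across the supplied DMR spans in
    the same arm.

    Planted genes are drawn among promoters carrying at least
    ``planted_min_cpgs`` CpGs (the CpG-dense promoter compartment where
    coordinated demethylation is observed); their window CpGs get
    replicate-merged-grade coverage (``planted_cov_range``) and a baseline
    high enough that the planted drop is realisable.
    """
    rng = config.rng(2)
    # CpG positions first, so planted genes can be chosen among
    # sufficiently CpG-dense promoters
    positions: dict[str, np.ndarray] = {}
    for chrom in sorted(chrom_sizes):
        length = chrom_sizes[chrom]
        n_est = int(length / config.cpg_spacing * 1.2) + 100
        gaps = np.floor(rng.exponential(config.cpg_spacing, size=n_est)).astype(np.int64) + 1
        pos = 50 + np.cumsum(gaps)
        positions[chrom] = pos[pos < length]

    all_windows = regions.promoter_windows(genes, config.upstream_size, chrom_sizes)
    cpgs_per_gene: dict[str, int] = {}
    for w in all_windows.windows:
        pos = positions.get(w.chrom)
        n_in = 0 if pos is None else int(
            np.searchsorted(pos, w.end) - np.searchsorted(pos, w.start))
        cpgs_per_gene[w.name] = cpgs_per_gene.get(w.name, 0) + n_in
    eligible = sorted(g for g, n_in in cpgs_per_gene.items()
                      if n_in >= config.planted_min_cpgs)
    if len(eligible) < config.n_planted:
        raise ValueError(
            f"only {len(eligible)} promoters carry >= {config.planted_min_cpgs} "
            f"CpGs; cannot plant {config.n_planted} genes"
        )
    planted_ids = sorted(
        rng.choice(eligible, size=config.n_planted, replace=False).tolist()
    )
    planted = [g for g in genes if g.gene_id in set(planted_ids)]
    planted_windows = regions.promoter_windows(
        planted, config.upstream_size, chrom_sizes
    ).windows
    win_index = _sorted_window_index(planted_windows)
    dmr_index = _sorted_window_index(dmrs or [])

    labels = ["Day0", "Day8_DFOminus", "Day8_DFOplus"]
    per_label: dict[str, dict[str, list]] = {
        lab: {"chrom": [], "pos": [], "n_meth": [], "n_unmeth": []} for lab in labels
    }
    for chrom in sorted(chrom_sizes):
        pos = positions[chrom]
        n = len(pos)
        base = rng.beta(*config.meth_beta, size=n) * 100.0
        in_planted = _in_windows(chrom, pos, win_index)
        in_dmr = _in_windows(chrom, pos, dmr_index)
        # the planted drop must be realisable from the baseline
        base[in_planted] = np.maximum(
            base[in_planted], min(config.effect_points + 15.0, 100.0))
        for lab in labels:
            level = base + rng.normal(0.0, config.noise_sd, size=n)
            if lab == "Day8_DFOminus":
                level = level - config.effect_points * in_planted
                level = level - config.dmr_meth_effect * in_dmr
            level = np.clip(level, 0.0, 100.0)
            cov = rng.negative_binomial(
                config.coverage_dispersion,
                config.coverage_dispersion / (config.coverage_dispersion + config.coverage_mean),
                size=n,
            ).astype(np.int64)
            cov = np.maximum(cov, 1)
            high = rng.random(n) < config.high_cov_fraction
            cov[high] = rng.integers(*config.high_cov_range, size=int(high.sum()),
                                     endpoint=True)
            # planted promoter CpGs carry replicate-merged-grade depth
            cov[in_planted] = np.clip(cov[in_planted], *config.planted_cov_range)
            n_meth = rng.binomial(cov, level / 100.0)
            d = per_label[lab]
            d["chrom"].extend([chrom] * n)
            d["pos"].extend(pos.tolist())
            d["n_meth"].extend(n_meth.tolist())
            d["n_unmeth"].extend((cov - n_meth).tolist())
    tracks = {}
    for lab in labels:
        d = per_label[lab]
        n_meth = np.asarray(d["n_meth"], dtype=np.int64)
        cov = n_meth + np.asarray(d["n_unmeth"], dtype=np.int64)
        meth = 100.0 * n_meth / cov
        tracks[lab] = MethylomeTrack.from_arrays(
            lab, d["chrom"], d["pos"], meth, d["n_meth"], d["n_unmeth"]
        )
    return tracks, planted_ids


# ---------------------------------------------------------------------------
# peaks and DMRs
# ---------------------------------------------------------------------------


def simulate_peaks(config: SimConfig
                   ) -> tuple[dict[str, list[GenomicInterval]], list[GenomicInterval]]:
    """Per-timepoint peak sets: baseline peaks present at every timepoint,
    induced-only peaks absent before induction.  Returns
    ``(peaks_by_timepoint, induced_peaks)``."""
    rng = config.rng(3)
    genes_per_chrom, slot = _layout(config)
    total_slots = config.n_genes
    if config.n_peaks > total_slots:
        raise ValueError("n_peaks exceeds available slots")
    chosen = np.sort(rng.choice(total_slots, size=config.n_peaks, replace=False))
    n_induced = int(round(config.induced_fraction * config.n_peaks))
    induced_idx = set(
        rng.choice(config.n_peaks, size=n_induced, replace=False).tolist()
    )
    width_digits = len(str(config.n_peaks))
    peaks: list[GenomicInterval] = []
    induced: list[GenomicInterval] = []
    for rank, s in enumerate(chosen.tolist()):
        chrom = _chrom_name(s // genes_per_chrom)
        slot_start = (s % genes_per_chrom) * slot
        center = slot_start + int(rng.integers(_PEAK_BAND[0], _PEAK_BAND[1] + 1))
        w = int(rng.integers(config.peak_width[0], config.peak_width[1] + 1))
        iv = GenomicInterval(chrom, center - w // 2, center - w // 2 + w,
                             name=f"peak_{rank + 1:0{width_digits}d}")
        peaks.append(iv)
        if rank in induced_idx:
            induced.append(iv)
    induced_set = {(p.chrom, p.start, p.end) for p in induced}
    by_tp: dict[str, list[GenomicInterval]] = {}
    for tp in config.peak_timepoints:
        pre = tp == config.preinduction_timepoint
        by_tp[tp] = [
            p for p in peaks if not (pre and (p.chrom, p.start, p.end) in induced_set)
        ]
    return by_tp, induced


def simulate_dmrs(config: SimConfig) -> list[GenomicInterval]:
    """DMR anchor intervals on the track chromosome, one per chosen slot,
    placed in a band disjoint from genes and peaks."""
    rng = config.rng(6)
    genes_per_chrom, slot = _layout(config)
    if config.n_dmrs > genes_per_chrom:
        raise ValueError("n_dmrs exceeds slots on the track chromosome")
    chrom = _chrom_name(config.track_chrom_index)
    chosen = np.sort(rng.choice(genes_per_chrom, size=config.n_dmrs, replace=False))
    width_digits = len(str(config.n_dmrs))
    out = []
    for rank, s in enumerate(chosen.tolist()):
        slot_start = s * slot
        center = slot_start + int(rng.integers(_DMR_BAND[0], _DMR_BAND[1] + 1))
        w = int(rng.integers(config.dmr_width[0], config.dmr_width[1] + 1))
        out.append(GenomicInterval(chrom, center - w // 2, center - w // 2 + w,
                                   name=f"dmr_{rank + 1:0{width_digits}d}"))
    return out


# ---------------------------------------------------------------------------
# ChIP counts and tracks
# ---------------------------------------------------------------------------


def _prototypes(n_prototypes: int, n_conditions: int) -> np.ndarray:
    """Temporal prototype patterns: unit-variance, zero-mean profiles evenly
    spread on the circle of z-scored vectors."""
    if n_conditions < 3:
        raise ValueError("prototype construction needs >= 3 conditions")
    # orthonormal basis of the zero-mean subspace (first two Helmert vectors)
    basis = np.zeros((2, n_conditions))
    basis[0, 0], basis[0, 1] = 1.0, -1.0
    basis[0] /= np.linalg.norm(basis[0])
    basis[1, 0] = basis[1, 1] = 1.0
    basis[1, 2] = -2.0
    basis[1] /= np.linalg.norm(basis[1])
    thetas = 2 * np.pi * np.arange(n_prototypes) / n_prototypes + 0.15
    protos = np.sqrt(n_conditions) * (
        np.cos(thetas)[:, None] * basis[0] + np.sin(thetas)[:, None] * basis[1]
    )
    return protos


def simulate_chip(config: SimConfig, genes: Sequence[GeneModel],
                  chrom_sizes: Mapping[str, int]
                  ) -> tuple[SignalMatrix, dict[str, int], dict[str, int]]:
    """Per-gene ChIP read counts over merged TSS +/-5 kb regions.

    Each gene follows one of ``n_prototypes`` temporal patterns across the
    conditions (log2-scale amplitude drawn from ``amp_range``) with
    multiplicative replicate noise; a ``flat_fraction`` of genes carries no
    pattern and is meant to fall below the CV filter.  Expected counts scale
    with the gene's merged region length.  Returns
    ``(count_matrix, true_labels, merged_lengths)``.
    """
    rng = config.rng(4)
    windowset = regions.tss5kb_windowsets(genes, config.tss_flank, True, chrom_sizes)
    lengths = windowset.lengths_by_source()
    n = len(genes)
    n_flat = int(round(config.flat_fraction * n))
    order = rng.permutation(n)
    flat_set = set(order[:n_flat].tolist())
    protos = _prototypes(config.n_prototypes, len(config.chip_conditions))
    labels: dict[str, int] = {}
    col_ids = [
        f"{cond}_rep{r + 1}"
        for cond in config.chip_conditions
        for r in range(config.n_replicates)
    ]
    values = np.zeros((n, len(col_ids)))
    patterned_rank = 0
    for i, gene in enumerate(genes):
        if i in flat_set:
            k = 0
            pattern = np.zeros(len(config.chip_conditions))
            amp = 0.0
        else:
            k = patterned_rank % config.n_prototypes + 1
            patterned_rank += 1
            pattern = protos[k - 1]
            amp = float(rng.uniform(*config.amp_range))
        labels[gene.gene_id] = k
        base = float(rng.uniform(*config.base_log2_range))
        mean_log2 = base + amp * pattern
        length_factor = lengths[gene.gene_id] / (2.0 * config.tss_flank)
        col = 0
        for j in range(len(config.chip_conditions)):
            for _ in range(config.n_replicates):
                eps = rng.normal(0.0, config.chip_noise_sd)
                values[i, col] = max(
                    round(2.0 ** (mean_log2[j] + eps) * length_factor), 0
                )
                col += 1
    matrix = SignalMatrix(values, [g.gene_id for g in genes], col_ids, "raw")
    return matrix, labels, lengths


def simulate_chip_tracks(config: SimConfig,
                         dmrs: Sequence[GenomicInterval]
                         ) -> dict[str, BinnedTrack]:
    """Binned ChIP coverage tracks on the track chromosome.

    All samples share a smooth sinusoidal background with independent white
    noise; the untreated Day-2 sample additionally loses a cusp-shaped
    fraction of signal (depth ``dip_depth``, decay length ``dip_tau``)
    centered on every DMR.
    """
    rng = config.rng(5)
    chrom = _chrom_name(config.track_chrom_index)
    n_bins = config.chrom_length // config.track_bin
    x = (np.arange(n_bins) + 0.5) * config.track_bin
    background = 1.0 + 0.3 * np.sin(2 * np.pi * x / 50_000.0)
    dip = np.zeros(n_bins)
    for d in dmrs:
        if d.chrom != chrom:
            continue
        dip += config.dip_depth * np.exp(-np.abs(x - d.center) / config.dip_tau)
    dip = np.minimum(dip, config.dip_depth)
    tracks = {}
    for sample in config.chip_conditions:
        factor = (1.0 - dip) if sample == "Day2_DFOminus" else 1.0
        vals = background * factor + rng.normal(0.0, config.track_noise_sd, n_bins)
        tracks[sample] = BinnedTrack({chrom: np.maximum(vals, 0.0)},
                                     config.track_bin, "raw")
    return tracks


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------


def simulate_all(config: SimConfig, outdir) -> TruthManifest:
    """Generate and write the complete input tree the pipeline expects.

    Layout::

        outdir/
          genes.tsv  chrom_sizes.tsv  dmrs.bed  truth.json
          methylomes/{Day0,Day8_DFOminus,Day8_DFOplus}.bedgraph
          peaks/peaks_<timepoint>.bed
          chip/{counts_tss5kb.tsv,lengths.tsv}
          tracks/chip_<sample>.bedgraph
    """
    outdir = Path(outdir)
    for sub in ("methylomes", "peaks", "chip", "tracks"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)

    genes, chrom_sizes = make_annotation(config)
    write_genes(genes, outdir / "genes.tsv")
    write_chrom_sizes(chrom_sizes, outdir / "chrom_sizes.tsv")

    dmrs = simulate_dmrs(config)
    write_intervals_bed(dmrs, outdir / "dmrs.bed")

    meth_tracks, planted_ids = simulate_methylomes(config, genes, chrom_sizes, dmrs)
    for lab, track in meth_tracks.items():
        write_methylome_bedgraph(track, outdir / "methylomes" / f"{lab}.bedgraph")

    peaks_by_tp, induced = simulate_peaks(config)
    for tp, ivs in peaks_by_tp.items():
        write_intervals_bed(ivs, outdir / "peaks" / f"peaks_{tp}.bed")

    counts, labels, lengths = simulate_chip(config, genes, chrom_sizes)
    write_count_table(counts, outdir / "chip" / "counts_tss5kb.tsv",
                      id_header="gene_id")
    with open(outdir / "chip" / "lengths.tsv", "wt", encoding="utf-8",
              newline="\n") as fh:
        fh.write("gene_id\tlength\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{lengths[g.gene_id]}\n")

    chip_tracks = simulate_chip_tracks(config, dmrs)
    for sample, track in chip_tracks.items():
        write_binned_bedgraph(track, outdir / "tracks" / f"chip_{sample}.bedgraph")

    manifest = TruthManifest(
        planted_genes={config.planted_condition: planted_ids},
        effect_points=config.effect_points,
        induced_peaks=[(p.chrom, p.start, p.end) for p in induced],
        cluster_labels=labels,
        dmrs=[(d.chrom, d.start, d.end) for d in dmrs],
        dip_depth=config.dip_depth,
        dmr_meth_effect=config.dmr_meth_effect,
        seed=config.seed,
    )
    with open(outdir / "truth.json", "wt", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(outdir / "sim_config.yaml", "wt", encoding="utf-8", newline="\n") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return manifest
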