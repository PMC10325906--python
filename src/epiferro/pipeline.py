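"""End-to-end pipeline: screens, enhancer construction, temporal clustering
and DMR aggregation on one dataset directory.

The pipeline consumes the directory layout written by
:func:`epiferro.synthdata.simulate_all` (or any directory with the same
file contracts), executes the stages in dependency order, and writes
per-stage TSV outputs plus a machine-readable ``summary.json``, a resolved
copy of the configuration, and a log.  Outputs are deterministic: the same
configuration and inputs yield byte-identical output trees, and a run
refuses to overwrite a non-empty output directory.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import aggregate as agg
from . import chipcluster as cc
from . import methscreen as ms
from . import regions
from .genomio import (
    read_chrom_sizes,
    read_count_table,
    read_genes,
    read_intervals_bed,
    read_methylome_bedgraph,
    write_intervals_bed,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name and file context."""


@dataclass
class RunConfig:
    """All numeric knobs of the pipeline; defaults are the study's stated
    parameters."""

    min_cov: int = 5
    max_cov: int = 1000
    drop_gt: float = 50.0
    min_cpgs: int = 3
    upstream: int = 1000
    enhancer_flank: int = 500
    tss_flank: int = 5000
    aggregate_flank: int = 3000
    aggregate_bin: int = 10
    meth_bin: int = 100  # coarser bins for sparse per-CpG deltas
    clusters: int = 7
    fuzzifier: float = 2.0
    n_init: int = 10
    cv_min: float = 0.2
    seed: int = 0
    base_label: str = "Day0"
    later_labels: tuple[str, str] = ("Day8_DFOminus", "Day8_DFOplus")
    preinduction_timepoint: str = "Day0"
    chip_day0: str = "Day0"
    chip_later: str = "Day2_DFOminus"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise PipelineError(f"stage {stage!r}: required input {path} is missing")
    return path


def run_pipeline(data_dir, out_dir, config: RunConfig | None = None) -> dict:
    """Run every stage on ``data_dir``; write outputs into ``out_dir``.

    Returns the summary dictionary that is also written to
    ``summary.json``.
    """
    config = config or RunConfig()
    data_dir = Path(data_dir)
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()):
        raise PipelineError(f"output directory {out_dir} is not empty; "
                            "pipeline outputs are write-once")
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    summary: dict = {}

    # ---------------- annotation ----------------
    stage = "annotation"
    genes = read_genes(_require(data_dir / "genes.tsv", stage))
    chrom_sizes = read_chrom_sizes(_require(data_dir / "chrom_sizes.tsv", stage))
    log(f"annotation: {len(genes)} genes on {len(chrom_sizes)} chromosomes")

    # ---------------- promoter screens ----------------
    stage = "screen-tss"
    try:
        base = read_methylome_bedgraph(
            _require(data_dir / "methylomes" / f"{config.base_label}.bedgraph", stage)
        )
        windows = regions.promoter_windows(genes, config.upstream, chrom_sizes)
        hits_by_arm: dict[str, list[ms.ScreenHit]] = {}
        for later_label in config.later_labels:
            later = read_methylome_bedgraph(
                _require(data_dir / "methylomes" / f"{later_label}.bedgraph", stage)
            )
            deltas = ms.methylation_delta(base, later, config.min_cov, config.max_cov)
            hits = ms.screen_windows(windows, deltas, config.drop_gt, config.min_cpgs)
            hits_by_arm[later_label] = hits
            ms.write_hits_tsv(hits, out_dir / f"hits_tss_{later_label}.tsv")
            log(
                f"screen-tss {later_label}: {len(base)} CpGs at {config.base_label}, "
                f"{len(later)} at {later_label}, {len(deltas)} jointly covered, "
                f"{len(hits)} hit genes"
            )
            summary[f"tss_hits_{later_label}"] = len(hits)
    except (OSError, ValueError) as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # ---------------- condition contrast ----------------
    stage = "contrast"
    arm_a, arm_b = config.later_labels
    contrast = ms.condition_contrast(
        hits_by_arm[arm_a], hits_by_arm[arm_b], arm_a, arm_b
    )
    ms.write_contrast_tsv(contrast, out_dir / "contrast_tss.tsv")
    summary["contrast"] = {
        f"only_{arm_a}": len(contrast.only_in_a),
        f"only_{arm_b}": len(contrast.only_in_b),
        "shared": len(contrast.shared),
    }
    log(
        f"contrast: only {arm_a} {len(contrast.only_in_a)}, "
        f"only {arm_b} {len(contrast.only_in_b)}, shared {len(contrast.shared)}"
    )

    # ---------------- enhancer construction + screen ----------------
    stage = "screen-enhancers"
    try:
        peak_files = sorted((data_dir / "peaks").glob("peaks_*.bed"))
        if not peak_files:
            raise PipelineError(f"stage {stage!r}: no peak files in {data_dir / 'peaks'}")
        peaks_by_tp = {
            p.stem.removeprefix("peaks_"): read_intervals_bed(p) for p in peak_files
        }
        pre = peaks_by_tp.get(config.preinduction_timepoint, [])
        all_enh, diff_enh = regions.putative_enhancers(
            peaks_by_tp, pre, config.enhancer_flank,
            chrom_sizes=chrom_sizes,
        )
        write_intervals_bed(diff_enh.windows, out_dir / "enhancers_diffspec.bed")
        summary["enhancers_all"] = len(all_enh)
        summary["enhancers_diffspec"] = len(diff_enh)
        log(f"enhancers: {len(all_enh)} merged-peak windows, "
            f"{len(diff_enh)} differentiation-specific")
        for later_label in config.later_labels:
            later = read_methylome_bedgraph(
                data_dir / "methylomes" / f"{later_label}.bedgraph"
            )
            deltas = ms.methylation_delta(base, later, config.min_cov, config.max_cov)
            ehits = ms.screen_windows(diff_enh, deltas, config.drop_gt, config.min_cpgs)
            ms.write_hits_tsv(ehits, out_dir / f"hits_enhancer_{later_label}.tsv")
            summary[f"enhancer_hits_{later_label}"] = len(ehits)
            log(f"screen-enhancers {later_label}: {len(ehits)} hit enhancers")
    except (OSError, ValueError) as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # ---------------- temporal clustering ----------------
    stage = "cluster-tss"
    try:
        counts = read_count_table(_require(data_dir / "chip" / "counts_tss5kb.tsv", stage))
        lengths = regions.tss5kb_windowsets(
            genes, config.tss_flank, True, chrom_sizes
        ).lengths_by_source()
        mat = cc.cpm_normalize(counts)
        mat = cc.length_normalize(mat, lengths)
        mat = cc.mean_over_replicates(mat)
        mat = cc.cv_filter(mat, config.cv_min)
        zmat = cc.log2_zscore(mat)
        model = cc.fuzzy_cmeans(
            zmat, config.clusters, m=config.fuzzifier, seed=config.seed,
            n_init=config.n_init,
        )
        hard = cc.hard_assign(model)
        with open(out_dir / "cluster_labels.tsv", "wt", encoding="utf-8",
                  newline="\n") as fh:
            fh.write("gene_id\tcluster\tmax_membership\n")
            for rid, lab, mem in zip(zmat.row_ids, hard, model.membership):
                fh.write(f"{rid}\t{int(lab)}\t{mem.max():.6f}\n")
        np.savetxt(out_dir / "cluster_centroids.tsv", model.centroids,
                   delimiter="\t", fmt="%.6f",
                   header="\t".join(zmat.col_ids), comments="")
        sizes = {int(k): int(v) for k, v in
                 zip(*np.unique(hard, return_counts=True))}
        summary["cluster_sizes"] = {str(k): sizes.get(k, 0)
                                    for k in range(1, config.clusters + 1)}
        summary["clustered_genes"] = len(zmat.row_ids)
        summary["cv_filtered_out"] = len(counts.row_ids) - len(zmat.row_ids)
        summary["dmin"] = round(model.dmin, 6)
        log(f"cluster-tss: {len(zmat.row_ids)} genes clustered into "
            f"{config.clusters} clusters (Dmin {model.dmin:.4f}); "
            f"{summary['cv_filtered_out']} genes below CV {config.cv_min}")
    except (OSError, ValueError) as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # ---------------- DMR aggregation ----------------
    stage = "aggregate-dmr"
    try:
        dmrs = read_intervals_bed(_require(data_dir / "dmrs.bed", stage))
        t0 = agg.read_binned_bedgraph(
            _require(data_dir / "tracks" / f"chip_{config.chip_day0}.bedgraph", stage)
        )
        t_later = agg.read_binned_bedgraph(
            _require(data_dir / "tracks" / f"chip_{config.chip_later}.bedgraph", stage)
        )
        delta_track = agg.signal_change(agg.cpm_binned(t_later), agg.cpm_binned(t0))
        chip_profile = agg.profile_around_anchors(
            delta_track, dmrs, config.aggregate_flank, config.aggregate_bin
        )
        chip_profile.write_tsv(out_dir / "profile_chip_dmr.tsv")
        min_i = int(np.nanargmin(chip_profile.values))
        summary["chip_profile_min_offset"] = int(chip_profile.offsets[min_i])
        summary["chip_profile_min_value"] = round(float(chip_profile.values[min_i]), 6)
        summary["chip_profile_anchors_used"] = chip_profile.n_anchors_used

        later_a = read_methylome_bedgraph(
            data_dir / "methylomes" / f"{config.later_labels[0]}.bedgraph"
        )
        deltas_a = ms.methylation_delta(base, later_a, config.min_cov, config.max_cov)
        meth_profile = agg.methylation_profile(
            deltas_a, dmrs, config.aggregate_flank, config.meth_bin
        )
        meth_profile.write_tsv(out_dir / "profile_meth_dmr.tsv")
        central = meth_profile.values[np.abs(meth_profile.offsets) < 300]
        with np.errstate(invalid="ignore"):
            summary["meth_profile_central_mean"] = (
                round(float(np.nanmean(central)), 6)
                if np.isfinite(central).any() else None
            )
        log(f"aggregate-dmr: {len(dmrs)} anchors; ChIP dip "
            f"{summary['chip_profile_min_value']} at offset "
            f"{summary['chip_profile_min_offset']} bp")
    except (OSError, ValueError) as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # ---------------- provenance ----------------
    with open(out_dir / "summary.json", "wt", encoding="utf-8", newline="\n") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out_dir / "resolved_config.yaml", "wt", encoding="utf-8",
              newline="\n") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    with open(out_dir / "pipeline.log", "wt", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return summary
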