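"""Interval algebra for the pipeline's window constructions.

Implements the strand-aware TSS-upstream promoter windows, bedtools-style
peak merging, peak-center enhancer windows, pre-induction peak subtraction
(differentiation-specific enhancers), and the merged TSS +/-5 kb regions used
for ChIP signal quantification.

All windows are half-open and clipped to ``[0, chromosome length)`` when a
chromosome-size table is supplied.  Clipped windows shorter than their
nominal size are retained; their true length is what enters any length
normalisation downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .genomio import GeneModel, GenomicInterval

__all__ = [
    "WindowSet",
    "upstream_window",
    "promoter_windows",
    "merge_intervals",
    "center_window",
    "differentiation_specific",
    "tss5kb_regions",
    "tss5kb_windowsets",
    "putative_enhancers",
]

logger = logging.getLogger(__name__)

PROVENANCES = ("promoter", "enhancer_all", "enhancer_diffspec", "tss5kb")


@dataclass
class WindowSet:
    """A labelled collection of windows, each carrying its source id in
    ``name`` (gene id for promoter / tss5kb windows, peak id for enhancers)."""

    windows: list[GenomicInterval]
    provenance: str

    def __post_init__(self) -> None:
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        for w in self.windows:
            if not w.name:
                raise ValueError("every window needs a non-empty source id")

    def __len__(self) -> int:
        return len(self.windows)

    def source_ids(self) -> list[str]:
        """Distinct source ids, in first-appearance order."""
        seen: dict[str, None] = {}
        for w in self.windows:
            seen.setdefault(w.name, None)  # type: ignore[arg-type]
        return list(seen)

    def lengths_by_source(self) -> dict[str, int]:
        """Total window length per source id (merged length when the set was
        built with merging)."""
        out: dict[str, int] = {}
        for w in self.windows:
            out[w.name] = out.get(w.name, 0) + len(w)  # type: ignore[index]
        return out


def _clip(chrom: str, start: int, end: int,
          chrom_sizes: Mapping[str, int] | None) -> tuple[int, int]:
    start = max(start, 0)
    if chrom_sizes is not None and chrom in chrom_sizes:
        end = min(end, chrom_sizes[chrom])
    return start, end


def upstream_window(gene: GeneModel, size: int = 1000,
                    chrom_sizes: Mapping[str, int] | None = None
                    ) -> list[GenomicInterval]:
    """One promoter window per TSS: the ``size`` bases 5'-upstream of the TSS.

    Plus strand: ``[t - size, t)``; minus strand: ``[t + 1, t + 1 + size)``.
    The TSS base itself is excluded on both strands.  Windows are clipped to
    the chromosome; a window that vanishes entirely is dropped (logged).
    """
    if size < 1:
        raise ValueError("window size must be >= 1")
    out: list[GenomicInterval] = []
    for t in gene.tss_list:
        if gene.strand == "+":
            start, end = t - size, t
        else:
            start, end = t + 1, t + 1 + size
        start, end = _clip(gene.chrom, start, end, chrom_sizes)
        if start >= end:
            logger.info(
                "gene %s: upstream window of TSS %d lies outside %s; skipped",
                gene.gene_id, t, gene.chrom,
            )
            continue
        out.append(GenomicInterval(gene.chrom, start, end,
                                   gene.strand, name=gene.gene_id))
    return out


def promoter_windows(genes: Iterable[GeneModel], size: int = 1000,
                     chrom_sizes: Mapping[str, int] | None = None) -> WindowSet:
    """Promoter windows for a whole annotation, labelled by gene id."""
    windows: list[GenomicInterval] = []
    for g in genes:
        windows.extend(upstream_window(g, size, chrom_sizes))
    return WindowSet(windows, "promoter")


def merge_intervals(intervals: Iterable[GenomicInterval],
                    merge_book_ended: bool = True) -> list[GenomicInterval]:
    """Union overlapping intervals per chromosome (bedtools ``merge``).

    Intervals sharing >= 1 base always merge; book-ended intervals
    (``[a, b)`` and ``[b, c)``) merge iff ``merge_book_ended`` (the default
    mirrors ``bedtools merge`` at distance 0).  Names of merged inputs are
    joined with commas; strand and score are dropped.  Output is sorted by
    (chrom, start) and pairwise disjoint.
    """
    ivs = sorted(intervals, key=lambda v: (v.chrom, v.start, v.end))
    out: list[GenomicInterval] = []
    cur: list = []  # [chrom, start, end, names]
    for iv in ivs:
        if cur and iv.chrom == cur[0] and (
            iv.start < cur[2] or (merge_book_ended and iv.start == cur[2])
        ):
            cur[2] = max(cur[2], iv.end)
            if iv.name is not None:
                cur[3].append(iv.name)
        else:
            if cur:
                out.append(_finish_merged(cur))
            cur = [iv.chrom, iv.start, iv.end,
                   [iv.name] if iv.name is not None else []]
    if cur:
        out.append(_finish_merged(cur))
    return out


def _finish_merged(cur: list) -> GenomicInterval:
    name = ",".join(cur[3]) if cur[3] else None
    return GenomicInterval(cur[0], cur[1], cur[2], name=name)


def center_window(interval: GenomicInterval, flank: int = 500,
                  chrom_sizes: Mapping[str, int] | None = None) -> GenomicInterval:
    """The ``[c - flank, c + flank)`` window around the interval's floor
    midpoint ``c``, clipped to the chromosome; carries the source interval's
    name."""
    if flank < 1:
        raise ValueError("flank must be >= 1")
    c = interval.center
    start, end = _clip(interval.chrom, c - flank, c + flank, chrom_sizes)
    return GenomicInterval(interval.chrom, start, end, name=interval.name)


def differentiation_specific(peaks: Sequence[GenomicInterval],
                             preinduction_peaks: Sequence[GenomicInterval]
                             ) -> list[GenomicInterval]:
    """Peaks with zero overlap against every pre-induction peak.

    Mirrors ``bedtools intersect -v``: any overlap of >= 1 base removes a
    peak; book-ended contact does not.  Input order is preserved.
    """
    by_chrom: dict[str, tuple[list[int], list[int]]] = {}
    grouped: dict[str, list[tuple[int, int]]] = {}
    for b in preinduction_peaks:
        grouped.setdefault(b.chrom, []).append((b.start, b.end))
    for chrom, spans in grouped.items():
        spans.sort()
        starts = [s for s, _ in spans]
        # prefix running max of ends: a span listed earlier may reach past
        # its successors, so overlap checks need the cumulative reach
        reach: list[int] = []
        hi = 0
        for _, e in spans:
            hi = max(hi, e)
            reach.append(hi)
        by_chrom[chrom] = (starts, reach)
    out: list[GenomicInterval] = []
    for p in peaks:
        if not _any_overlap(p.start, p.end, by_chrom.get(p.chrom)):
            out.append(p)
    return out


def _any_overlap(start: int, end: int,
                 spans: tuple[list[int], list[int]] | None) -> bool:
    if spans is None:
        return False
    import bisect
    starts, reach = spans
    # i = number of spans starting before `end`
    i = bisect.bisect_left(starts, end)
    return i > 0 and reach[i - 1] > start


def tss5kb_regions(gene: GeneModel, flank: int = 5000, merge: bool = True,
                   chrom_sizes: Mapping[str, int] | None = None) -> WindowSet:
    """The ``[t - flank, t + flank)`` window around each TSS of one gene,
    strand-independent, clipped.

    With ``merge`` (the default), overlapping windows of the same gene are
    merged so a gene with clustered TSSs contributes disjoint regions whose
    total length feeds length normalisation.  Without it, one window per TSS
    is kept even when windows overlap.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    windows: list[GenomicInterval] = []
    for t in gene.tss_list:
        start, end = _clip(gene.chrom, t - flank, t + flank, chrom_sizes)
        if start >= end:
            logger.info("gene %s: TSS +/-%d window of %d outside %s; skipped",
                        gene.gene_id, flank, t, gene.chrom)
            continue
        windows.append(GenomicInterval(gene.chrom, start, end, name=gene.gene_id))
    if merge:
        merged = merge_intervals(windows)
        windows = [
            GenomicInterval(w.chrom, w.start, w.end, name=gene.gene_id)
            for w in merged
        ]
    return WindowSet(windows, "tss5kb")


def tss5kb_windowsets(genes: Iterable[GeneModel], flank: int = 5000,
                      merge: bool = True,
                      chrom_sizes: Mapping[str, int] | None = None) -> WindowSet:
    """Per-gene TSS +/-flank windows for a whole annotation.  Windows of
    different genes are never merged with each other."""
    windows: list[GenomicInterval] = []
    for g in genes:
        windows.extend(tss5kb_regions(g, flank, merge, chrom_sizes).windows)
    return WindowSet(windows, "tss5kb")


def putative_enhancers(peaks_by_timepoint: Mapping[str, Sequence[GenomicInterval]],
                       preinduction_peaks: Sequence[GenomicInterval],
                       flank: int = 500,
                       merge_book_ended: bool = True,
                       chrom_sizes: Mapping[str, int] | None = None
                       ) -> tuple[WindowSet, WindowSet]:
    """Build putative-enhancer windows from per-timepoint peak sets.

    Peaks across all timepoints are merged; merged peaks overlapping any
    pre-induction peak are discarded; the survivors' centers +/- ``flank``
    become the differentiation-specific enhancer windows.  Returns
    ``(all_enhancers, differentiation_specific_enhancers)`` — the first set
    keeps every merged peak's center window, the second only the
    differentiation-specific ones.  Windows are labelled ``enh_<i>`` by the
    merged peak's rank.
    """
    all_peaks: list[GenomicInterval] = []
    for tp in sorted(peaks_by_timepoint):
        all_peaks.extend(peaks_by_timepoint[tp])
    merged = merge_intervals(all_peaks, merge_book_ended=merge_book_ended)
    width = len(str(max(len(merged), 1)))
    merged = [
        GenomicInterval(p.chrom, p.start, p.end, name=f"enh_{i:0{width}d}")
        for i, p in enumerate(merged, start=1)
    ]
    specific = differentiation_specific(merged, preinduction_peaks)
    all_windows = [center_window(p, flank, chrom_sizes) for p in merged]
    spec_windows = [center_window(p, flank, chrom_sizes) for p in specific]
    return (
        WindowSet(all_windows, "enhancer_all"),
        WindowSet(spec_windows, "enhancer_diffspec"),
    )
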