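"""DMR-anchored aggregation profiles.

Builds the average signal-change curve around a set of anchor intervals
(differentially methylated regions): per-bin CPM-normalised ChIP coverage is
subtracted between a later timepoint and Day 0, then sampled in fixed-width
bins across ``[center - flank, center + flank)`` of every anchor and
averaged per offset.  A parallel routine aggregates per-CpG methylation
change around the same anchors.

Missing-versus-zero semantics differ by data type and are deliberate:
ChIP coverage bins with no signal are genuine zeros, whereas offset bins
containing no CpG have no methylation measurement and are reported as
missing (NaN), never as zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genomio import FormatError, GenomicInterval, _data_lines
from .methscreen import DeltaTrack

__all__ = [
    "BinnedTrack",
    "ProfileCurve",
    "read_binned_bedgraph",
    "write_binned_bedgraph",
    "cpm_binned",
    "signal_change",
    "profile_around_anchors",
    "methylation_profile",
]

logger = logging.getLogger(__name__)


@dataclass
class BinnedTrack:
    """Per-chromosome arrays of signal on a fixed genome binning.

    ``values[chrom][k]`` covers bases ``[k * bin_size, (k + 1) * bin_size)``.
    ``norm`` tags the scale: ``raw`` coverage, ``cpm`` (track total scaled to
    one million), or ``delta`` (difference of two CPM tracks).
    """

    values: dict[str, np.ndarray]
    bin_size: int
    norm: str = "raw"

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        if self.norm not in ("raw", "cpm", "delta"):
            raise ValueError(f"unknown normalisation tag {self.norm!r}")
        self.values = {c: np.asarray(v, dtype=float) for c, v in self.values.items()}

    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def chrom_length(self, chrom: str) -> int:
        return len(self.values[chrom]) * self.bin_size


@dataclass
class ProfileCurve:
    """Mean signal per offset bin around a set of anchors.

    ``offsets`` are bin centers relative to the anchor center, symmetric
    around zero; ``values`` may contain NaN where no measurement fell into a
    bin (methylation mode).  ``n_per_offset`` counts contributing anchors
    (ChIP mode) or CpGs (methylation mode) per bin.
    """

    offsets: np.ndarray
    values: np.ndarray
    n_anchors_used: int
    n_anchors_skipped: int
    n_per_offset: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"offset": self.offsets.astype(int), "mean": self.values})
        if self.n_per_offset is not None:
            df["n"] = self.n_per_offset.astype(int)
        return df

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA",
                               float_format="%.6g", lineterminator="\n")


# ---------------------------------------------------------------------------
# I/O and normalisation
# ---------------------------------------------------------------------------


def read_binned_bedgraph(path, bin_size: int | None = None,
                         norm: str = "raw") -> BinnedTrack:
    """Read a fixed-bin bedGraph coverage track.

    Every record must start on a bin boundary and span exactly one bin (the
    last bin of a chromosome may be shorter).  ``bin_size`` is inferred from
    the first record when not given.  Bins absent from the file are zero.
    """
    path = Path(path)
    per_chrom: dict[str, dict[int, float]] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) < 4:
            raise FormatError("binned bedGraph needs 4 columns", path, lineno)
        try:
            start, end = int(fields[1]), int(fields[2])
            value = float(fields[3])
        except ValueError:
            raise FormatError("malformed numeric field", path, lineno) from None
        if start >= end:
            raise FormatError(f"invalid interval [{start}, {end})", path, lineno)
        if bin_size is None:
            bin_size = end - start
        if start % bin_size != 0 or end - start > bin_size:
            raise FormatError(
                f"record [{start}, {end}) off the {bin_size}-bp binning",
                path, lineno,
            )
        bins = per_chrom.setdefault(fields[0], {})
        idx = start // bin_size
        if idx in bins:
            raise FormatError(f"duplicate bin at {fields[0]}:{start}", path, lineno)
        bins[idx] = value
    if bin_size is None:
        raise FormatError("empty binned bedGraph", path)
    values = {}
    for chrom, bins in per_chrom.items():
        arr = np.zeros(max(bins) + 1, dtype=float)
        arr[list(bins)] = list(bins.values())
        values[chrom] = arr
    return BinnedTrack(values, bin_size, norm)


def write_binned_bedgraph(track: BinnedTrack, path) -> None:
    bs = track.bin_size
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        for chrom in sorted(track.values):
            arr = track.values[chrom]
            for k, v in enumerate(arr):
                fh.write(f"{chrom}\t{k * bs}\t{(k + 1) * bs}\t{v:.6f}\n")


def cpm_binned(track: BinnedTrack) -> BinnedTrack:
    """Scale the whole track so its genome-wide total equals one million."""
    total = track.total()
    if total <= 0:
        raise ValueError("cannot CPM-normalise a track with non-positive total")
    return BinnedTrack(
        {c: v * 1e6 / total for c, v in track.values.items()},
        track.bin_size, "cpm",
    )


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


def signal_change(track_t: BinnedTrack, track_0: BinnedTrack) -> BinnedTrack:
    """Per-bin difference ``track_t - track_0`` of two CPM tracks on the
    same binning and chromosome set."""
    if track_t.bin_size != track_0.bin_size:
        raise ValueError("binning mismatch between tracks")
    if set(track_t.values) != set(track_0.values):
        raise ValueError("chromosome sets differ between tracks")
    for tr in (track_t, track_0):
        if tr.norm != "cpm":
            raise ValueError("signal_change expects CPM-normalised tracks")
    out: dict[str, np.ndarray] = {}
    for chrom, vt in track_t.values.items():
        v0 = track_0.values[chrom]
        if len(vt) != len(v0):
            raise ValueError(f"binning mismatch on {chrom}")
        out[chrom] = vt - v0
    return BinnedTrack(out, track_t.bin_size, "delta")


def _offsets(flank: int, bin_size: int) -> np.ndarray:
    n_bins = 2 * flank // bin_size
    return -flank + (np.arange(n_bins) + 0.5) * bin_size


def profile_around_anchors(track: BinnedTrack, anchors: Sequence[GenomicInterval],
                           flank: int = 3000, bin_size: int = 10,
                           skip_zero_anchors: bool = False) -> ProfileCurve:
    """Average the track in ``bin_size`` bins across ``[c - flank, c + flank)``
    of every anchor center ``c`` (floor midpoint).

    Anchors whose window extends beyond the chromosome (or whose chromosome
    is absent from the track) are skipped and counted.  With
    ``skip_zero_anchors``, anchors sampling an all-zero window are excluded
    from the average as well (the per-anchor reading of a skip-zeros rule).
    """
    if not anchors:
        raise ValueError("no anchors given")
    if flank % bin_size != 0:
        raise ValueError("flank must be divisible by bin_size")
    n_bins = 2 * flank // bin_size
    rows: list[np.ndarray] = []
    skipped = 0
    for a in anchors:
        arr = track.values.get(a.chrom)
        if arr is None:
            skipped += 1
            continue
        c = a.center
        lo, hi = c - flank, c + flank
        if lo < 0 or hi > len(arr) * track.bin_size:
            skipped += 1
            continue
        base_positions = lo + np.arange(2 * flank)
        sampled = arr[base_positions // track.bin_size]
        binned = sampled.reshape(n_bins, bin_size).mean(axis=1)
        if skip_zero_anchors and not np.any(binned):
            skipped += 1
            continue
        rows.append(binned)
    if not rows:
        raise ValueError("zero usable anchors for aggregation")
    stack = np.vstack(rows)
    return ProfileCurve(
        offsets=_offsets(flank, bin_size),
        values=stack.mean(axis=0),
        n_anchors_used=len(rows),
        n_anchors_skipped=skipped,
        n_per_offset=np.full(n_bins, len(rows)),
    )


def methylation_profile(delta: DeltaTrack, anchors: Sequence[GenomicInterval],
                        flank: int = 3000, bin_size: int = 10) -> ProfileCurve:
    """Mean per-CpG methylation change per offset bin around the anchors.

    CpG deltas from all anchors are pooled per offset bin; a bin with no CpG
    is missing (NaN), not zero.  Anchors contributing no CpG within the
    flank still count as used; an all-empty result is returned with a
    warning rather than as an error.
    """
    if not anchors:
        raise ValueError("no anchors given")
    if flank % bin_size != 0:
        raise ValueError("flank must be divisible by bin_size")
    n_bins = 2 * flank // bin_size
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in delta.df.groupby("chrom", sort=False):
        by_chrom[chrom] = (
            sub["pos"].to_numpy(dtype=np.int64),
            sub["delta"].to_numpy(dtype=float),
        )
    n_contributing = 0
    for a in anchors:
        entry = by_chrom.get(a.chrom)
        if entry is None:
            continue
        pos, dvals = entry
        c = a.center
        lo_i = np.searchsorted(pos, c - flank, side="left")
        hi_i = np.searchsorted(pos, c + flank, side="left")
        if hi_i > lo_i:
            n_contributing += 1
        idx = (pos[lo_i:hi_i] - (c - flank)) // bin_size
        np.add.at(sums, idx, dvals[lo_i:hi_i])
        np.add.at(counts, idx, 1)
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    if counts.sum() == 0:
        logger.warning("no CpG fell within +/-%d bp of any anchor", flank)
    return ProfileCurve(
        offsets=_offsets(flank, bin_size),
        values=values,
        n_anchors_used=n_contributing,
        n_anchors_skipped=len(anchors) - n_contributing,
        n_per_offset=counts,
    )
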