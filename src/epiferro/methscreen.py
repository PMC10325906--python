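"""CpG demethylation screens on WGBS methylomes.

The screen asks, per promoter or enhancer window set: which regions contain
at least ``min_sites`` CpGs whose methylation level dropped by more than
``drop_gt`` percentage points between a baseline and a later timepoint,
after discarding CpGs with unreliable read depth (outside
``[min_cov, max_cov]``) in *either* timepoint?  Contrasting the hit sets of
an untreated and an iron-chelated differentiation arm isolates the
iron-dependent demethylated regions.

Thresholds are strict at both ends: a CpG whose level fell by exactly
``drop_gt`` points never qualifies, and coverage bounds are closed
(coverage 5 and 1000 pass at the defaults; 4 and 1001 do not).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genomio import GenomicInterval, MethylomeTrack
from .regions import WindowSet

__all__ = [
    "DeltaTrack",
    "ScreenHit",
    "ScreenContrast",
    "coverage_filter",
    "methylation_delta",
    "screen_windows",
    "condition_contrast",
    "write_hits_tsv",
    "write_contrast_tsv",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_COV = 5
DEFAULT_MAX_COV = 1000
DEFAULT_DROP_GT = 50.0
DEFAULT_MIN_SITES = 3


@dataclass
class DeltaTrack:
    """Per-CpG methylation change between two timepoints.

    Holds only CpGs that passed the coverage filter in *both* tracks.
    ``delta`` is ``meth_later - meth_base`` in percentage points, so
    demethylation is negative.  Backed by a DataFrame with columns
    ``chrom, pos, meth_base, meth_later, delta`` sorted by (chrom, pos).
    """

    df: pd.DataFrame = field(repr=False)
    base_label: str = "base"
    later_label: str = "later"

    COLUMNS = ("chrom", "pos", "meth_base", "meth_later", "delta")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"DeltaTrack frame missing columns {missing}")
        if len(self.df):
            d = self.df["delta"].to_numpy()
            if (d < -100).any() or (d > 100).any():
                raise ValueError("delta outside [-100, 100]")

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class ScreenHit:
    """One region passing the screen: its qualifying CpGs and windows."""

    region_id: str
    windows: list[GenomicInterval]
    n_qualifying: int
    qualifying_sites: list[tuple[str, int, float]]  # (chrom, pos, delta)


@dataclass
class ScreenContrast:
    """Venn partition of two screens' hit-region ids."""

    only_in_a: set[str]
    only_in_b: set[str]
    shared: set[str]
    label_a: str
    label_b: str


def coverage_filter(track: MethylomeTrack, min_cov: int = DEFAULT_MIN_COV,
                    max_cov: int = DEFAULT_MAX_COV) -> MethylomeTrack:
    """Keep CpGs with ``min_cov <= coverage <= max_cov`` (closed bounds)."""
    if min_cov < 0 or max_cov < min_cov:
        raise ValueError("need 0 <= min_cov <= max_cov")
    df = track.df
    cov = df["coverage"]
    if cov.isna().any():
        row = df.loc[cov.isna()].iloc[0]
        raise ValueError(
            f"track {track.label!r}: site {row['chrom']}:{int(row['pos'])} has "
            "no coverage; depth-aware screens need the counts6 dialect"
        )
    kept = df.loc[(cov >= min_cov) & (cov <= max_cov)].reset_index(drop=True)
    return MethylomeTrack(track.label, kept)


def methylation_delta(base: MethylomeTrack, later: MethylomeTrack,
                      min_cov: int = DEFAULT_MIN_COV,
                      max_cov: int = DEFAULT_MAX_COV) -> DeltaTrack:
    """Per-CpG change ``later - base`` over CpGs passing the coverage filter
    in both tracks (joint filtering)."""
    b = coverage_filter(base, min_cov, max_cov).df
    l = coverage_filter(later, min_cov, max_cov).df
    merged = b.merge(l, on=["chrom", "pos"], suffixes=("_base", "_later"))
    if merged.empty:
        logger.warning(
            "no CpGs shared between %s and %s after coverage filtering",
            base.label, later.label,
        )
    out = pd.DataFrame(
        {
            "chrom": merged["chrom"],
            "pos": merged["pos"],
            "meth_base": merged["meth_base"],
            "meth_later": merged["meth_later"],
            "delta": merged["meth_later"] - merged["meth_base"],
        }
    ).sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return DeltaTrack(out, base.label, later.label)


def screen_windows(windows: WindowSet, deltas: DeltaTrack,
                   drop_gt: float = DEFAULT_DROP_GT,
                   min_sites: int = DEFAULT_MIN_SITES,
                   relative: bool = False) -> list[ScreenHit]:
    """Identify regions with >= ``min_sites`` CpGs losing more than
    ``drop_gt`` of methylation.

    A CpG qualifies for a region iff it lies in any of the region's windows
    and its drop exceeds the threshold strictly.  With ``relative=False``
    (default, matching the subtraction-of-levels reading) the drop is in
    percentage points: ``delta < -drop_gt``.  With ``relative=True`` the drop
    is relative to the baseline level: ``delta / meth_base * 100 < -drop_gt``
    (CpGs with a zero baseline never qualify).  A CpG inside windows of
    several regions counts for each of them, but only once per region.
    """
    if min_sites < 1:
        raise ValueError("min_sites must be >= 1")
    df = deltas.df
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy(dtype=np.int64)
        delta = sub["delta"].to_numpy(dtype=float)
        if relative:
            base = sub["meth_base"].to_numpy(dtype=float)
            with np.errstate(divide="ignore", invalid="ignore"):
                drop = np.where(base > 0, delta / base * 100.0, np.nan)
            qual = np.where(np.isnan(drop), False, drop < -drop_gt)
        else:
            qual = delta < -drop_gt
        by_chrom[chrom] = (pos, delta, qual)

    regions: dict[str, dict] = {}
    for w in windows.windows:
        info = regions.setdefault(
            w.name, {"windows": [], "sites": {}}  # type: ignore[arg-type]
        )
        info["windows"].append(w)
        entry = by_chrom.get(w.chrom)
        if entry is None:
            continue
        pos, delta, qual = entry
        lo = np.searchsorted(pos, w.start, side="left")
        hi = np.searchsorted(pos, w.end, side="left")
        for i in range(lo, hi):
            if qual[i]:
                info["sites"][(w.chrom, int(pos[i]))] = float(delta[i])

    hits: list[ScreenHit] = []
    for region_id, info in regions.items():
        sites = sorted(info["sites"].items())
        if len(sites) >= min_sites:
            hits.append(
                ScreenHit(
                    region_id=region_id,
                    windows=info["windows"],
                    n_qualifying=len(sites),
                    qualifying_sites=[(c, p, d) for (c, p), d in sites],
                )
            )
    hits.sort(key=lambda h: h.region_id)
    return hits


def condition_contrast(hits_a: Sequence[ScreenHit], hits_b: Sequence[ScreenHit],
                       label_a: str = "A", label_b: str = "B") -> ScreenContrast:
    """Partition hit-region ids of two screens into A-only / B-only / shared.

    When A is the untreated arm and B the iron-chelated one, the A-only set
    is the iron-dependent demethylated regions.  Both screens must have been
    run against the same annotation with the same parameters.
    """
    a = {h.region_id for h in hits_a}
    b = {h.region_id for h in hits_b}
    return ScreenContrast(
        only_in_a=a - b,
        only_in_b=b - a,
        shared=a & b,
        label_a=label_a,
        label_b=label_b,
    )


def write_hits_tsv(hits: Sequence[ScreenHit], path) -> None:
    """Emit hits: region id, qualifying-CpG count, windows, and each
    qualifying position with its delta."""
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        fh.write("region_id\tn_qualifying\twindows\tqualifying_sites\n")
        for h in hits:
            wins = ",".join(f"{w.chrom}:{w.start}-{w.end}" for w in h.windows)
            sites = ",".join(
                f"{c}:{p}:{d:.6g}" for c, p, d in h.qualifying_sites
            )
            fh.write(f"{h.region_id}\t{h.n_qualifying}\t{wins}\t{sites}\n")


def write_contrast_tsv(contrast: ScreenContrast, path) -> None:
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        fh.write("region_id\tmembership\n")
        rows = (
            [(r, f"only_{contrast.label_a}") for r in sorted(contrast.only_in_a)]
            + [(r, f"only_{contrast.label_b}") for r in sorted(contrast.only_in_b)]
            + [(r, "shared") for r in sorted(contrast.shared)]
        )
        for region_id, member in rows:
            fh.write(f"{region_id}\t{member}\n")
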