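"""Readers, writers and core coordinate types for the genomic file formats
the pipeline touches.

Conventions
-----------
* All coordinates are **0-based, half-open** throughout the package; a single
  CpG cytosine at position ``p`` corresponds to the interval ``[p, p + 1)``.
* Chromosome names are compared by exact string match; no ``chr`` prefix
  normalisation is performed.
* Sort order everywhere is lexicographic chromosome, then numeric position,
  which is deterministic across platforms.
* All emitted files are tab-separated with LF line endings and no quoting.

Two bedGraph dialects are supported for per-CpG methylation tracks:

``counts6``
    ``chrom  start  end  meth%  n_meth  n_unmeth`` — the canonical internal
    dialect; read depth (coverage) is ``n_meth + n_unmeth``.  The coverage
    screens require this dialect.
``level4``
    ``chrom  start  end  meth%`` — methylation level only, coverage
    undefined.  Accepted for I/O; operations that need depth reject such
    tracks with a clear error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "CpGSite",
    "GenomicInterval",
    "GeneModel",
    "MethylomeTrack",
    "SignalMatrix",
    "read_methylome_bedgraph",
    "write_methylome_bedgraph",
    "read_intervals_bed",
    "write_intervals_bed",
    "read_genes",
    "write_genes",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_count_table",
    "write_count_table",
]

STRANDS = ("+", "-", ".")

_HEADER_PREFIXES = ("track", "browser", "#")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""

    def __init__(self, message: str, path: object = None, line: int | None = None):
        ctx = ""
        if path is not None:
            ctx += f"{path}"
        if line is not None:
            ctx += f":{line}"
        super().__init__(f"{ctx}: {message}" if ctx else message)
        self.path = path
        self.line = line


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CpGSite:
    """One cytosine record of a WGBS methylome.

    ``meth`` is the methylation level in percent (0–100).  When methylated /
    unmethylated read counts are available, ``coverage`` is their sum;
    otherwise an explicit ``depth`` may be given; otherwise coverage is
    undefined (``None``).
    """

    chrom: str
    pos: int
    meth: float
    n_meth: int | None = None
    n_unmeth: int | None = None
    depth: int | None = None

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative position {self.pos}")
        if not 0.0 <= self.meth <= 100.0:
            raise ValueError(f"methylation level {self.meth} outside [0, 100]")
        if (self.n_meth is None) != (self.n_unmeth is None):
            raise ValueError("n_meth and n_unmeth must be given together")
        if self.n_meth is not None:
            if self.n_meth < 0 or self.n_unmeth < 0:  # type: ignore[operator]
                raise ValueError("read counts must be >= 0")
            cov = self.n_meth + self.n_unmeth  # type: ignore[operator]
            if cov > 0 and abs(self.meth - 100.0 * self.n_meth / cov) > 0.5:
                raise ValueError(
                    f"{self.chrom}:{self.pos}: meth {self.meth} inconsistent "
                    f"with counts {self.n_meth}/{self.n_unmeth}"
                )
        if self.depth is not None and self.depth < 0:
            raise ValueError("depth must be >= 0")

    @property
    def coverage(self) -> int | None:
        if self.n_meth is not None:
            return self.n_meth + self.n_unmeth  # type: ignore[operator]
        return self.depth


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic window ``[start, end)`` with optional annotation."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 base (book-ended is False)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    @property
    def center(self) -> int:
        """Floor midpoint, the convention used for all anchor centering."""
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand and one or more transcription start sites."""

    gene_id: str
    chrom: str
    strand: str
    tss_list: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not self.tss_list:
            raise ValueError(f"gene {self.gene_id}: empty TSS list")
        if any(t < 0 for t in self.tss_list):
            raise ValueError(f"gene {self.gene_id}: negative TSS coordinate")


@dataclass
class MethylomeTrack:
    """One WGBS sample / replicate merge: CpG sites sorted by (chrom, pos).

    Backed by a :class:`pandas.DataFrame` with columns ``chrom`` (str),
    ``pos`` (int), ``meth`` (float percent), ``n_meth``, ``n_unmeth`` and
    ``coverage`` (float, NaN when undefined).
    """

    label: str
    df: pd.DataFrame = field(repr=False)

    COLUMNS = ("chrom", "pos", "meth", "n_meth", "n_unmeth", "coverage")

    @classmethod
    def from_sites(cls, label: str, sites: Iterable[CpGSite]) -> "MethylomeTrack":
        rows = [
            (
                s.chrom,
                s.pos,
                s.meth,
                np.nan if s.n_meth is None else s.n_meth,
                np.nan if s.n_unmeth is None else s.n_unmeth,
                np.nan if s.coverage is None else s.coverage,
            )
            for s in sites
        ]
        df = pd.DataFrame(rows, columns=list(cls.COLUMNS))
        if df.empty:
            df = _empty_track_frame()
        return cls(label, _canonicalize_track_frame(df, source=label))

    @classmethod
    def from_arrays(
        cls,
        label: str,
        chrom: Sequence[str],
        pos: Sequence[int],
        meth: Sequence[float],
        n_meth: Sequence[int] | None = None,
        n_unmeth: Sequence[int] | None = None,
    ) -> "MethylomeTrack":
        n = len(pos)
        df = pd.DataFrame(
            {
                "chrom": np.asarray(chrom, dtype=object),
                "pos": np.asarray(pos, dtype=np.int64),
                "meth": np.asarray(meth, dtype=float),
                "n_meth": np.full(n, np.nan) if n_meth is None else np.asarray(n_meth, dtype=float),
                "n_unmeth": np.full(n, np.nan) if n_unmeth is None else np.asarray(n_unmeth, dtype=float),
            }
        )
        df["coverage"] = df["n_meth"] + df["n_unmeth"]
        return cls(label, _canonicalize_track_frame(df, source=label))

    def __len__(self) -> int:
        return len(self.df)

    @property
    def has_coverage(self) -> bool:
        """True iff every site carries a defined read depth."""
        return bool(self.df["coverage"].notna().all()) if len(self.df) else True

    def sites(self) -> Iterator[CpGSite]:
        for row in self.df.itertuples(index=False):
            n_meth = None if math.isnan(row.n_meth) else int(row.n_meth)
            n_unmeth = None if math.isnan(row.n_unmeth) else int(row.n_unmeth)
            depth = None
            if n_meth is None and not math.isnan(row.coverage):
                depth = int(row.coverage)
            yield CpGSite(row.chrom, int(row.pos), float(row.meth), n_meth, n_unmeth, depth)


@dataclass
class SignalMatrix:
    """Regions/genes x samples matrix of (possibly normalised) signal.

    ``stage`` tracks where in the normalisation chain the values sit:
    ``raw`` -> ``cpm`` -> ``length_cpm`` -> (``log2``) -> ``zscore``.
    """

    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("SignalMatrix values must be 2-D")
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match labels "
                f"({len(self.row_ids)} x {len(self.col_ids)})"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)

    def with_values(self, values: np.ndarray, stage: str,
                    row_ids: list[str] | None = None,
                    col_ids: list[str] | None = None) -> "SignalMatrix":
        return SignalMatrix(
            values,
            list(self.row_ids) if row_ids is None else list(row_ids),
            list(self.col_ids) if col_ids is None else list(col_ids),
            stage,
        )


def _empty_track_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=object),
            "pos": pd.Series(dtype=np.int64),
            "meth": pd.Series(dtype=float),
            "n_meth": pd.Series(dtype=float),
            "n_unmeth": pd.Series(dtype=float),
            "coverage": pd.Series(dtype=float),
        }
    )


def _canonicalize_track_frame(df: pd.DataFrame, source: object = None) -> pd.DataFrame:
    """Sort by (chrom, pos), collapse identical duplicates, reject conflicts."""
    if df.empty:
        return _empty_track_frame()
    bad = (df["meth"] < 0) | (df["meth"] > 100)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise FormatError(
            f"methylation level {df['meth'].iloc[i]} outside [0, 100] at "
            f"{df['chrom'].iloc[i]}:{df['pos'].iloc[i]}",
            path=source,
        )
    df = df.drop_duplicates().sort_values(["chrom", "pos"], kind="mergesort")
    dup = df.duplicated(subset=["chrom", "pos"], keep=False)
    if dup.any():
        row = df.loc[dup].iloc[0]
        raise FormatError(
            f"conflicting duplicate records at {row['chrom']}:{int(row['pos'])}",
            path=source,
        )
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# bedGraph methylome I/O
# ---------------------------------------------------------------------------


def _data_lines(path: Path) -> Iterator[tuple[int, list[str]]]:
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if any(line.startswith(p) for p in _HEADER_PREFIXES):
                continue
            yield lineno, line.split("\t")


def read_methylome_bedgraph(path, dialect: str = "counts6",
                            label: str | None = None) -> MethylomeTrack:
    """Read a per-CpG methylation bedGraph.

    Records spanning more than one base are rejected: a methylome track is a
    collection of single cytosines.  Track/browser/# header lines are
    skipped.  Duplicate records with identical values are collapsed;
    conflicting duplicates are an error.
    """
    if dialect not in ("counts6", "level4"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    want = 6 if dialect == "counts6" else 4
    chroms: list[str] = []
    poss: list[int] = []
    meths: list[float] = []
    nms: list[float] = []
    nus: list[float] = []
    for lineno, fields in _data_lines(path):
        if len(fields) < want:
            raise FormatError(
                f"expected >= {want} tab-separated columns, got {len(fields)}",
                path, lineno,
            )
        try:
            start = int(fields[1])
            end = int(fields[2])
            meth = float(fields[3])
        except ValueError as exc:
            raise FormatError(f"malformed numeric field ({exc})", path, lineno) from None
        if end != start + 1:
            raise FormatError(
                f"record spans {end - start} bp; per-CpG tracks must be 1 bp",
                path, lineno,
            )
        if not 0.0 <= meth <= 100.0:
            raise FormatError(f"methylation level {meth} outside [0, 100]", path, lineno)
        if dialect == "counts6":
            try:
                n_meth = int(fields[4])
                n_unmeth = int(fields[5])
            except ValueError as exc:
                raise FormatError(f"malformed count field ({exc})", path, lineno) from None
            if n_meth < 0 or n_unmeth < 0:
                raise FormatError("negative read count", path, lineno)
            cov = n_meth + n_unmeth
            if cov > 0 and abs(meth - 100.0 * n_meth / cov) > 0.5:
                raise FormatError(
                    f"meth% {meth} inconsistent with counts {n_meth}/{n_unmeth}",
                    path, lineno,
                )
            nms.append(n_meth)
            nus.append(n_unmeth)
        else:
            nms.append(np.nan)
            nus.append(np.nan)
        chroms.append(fields[0])
        poss.append(start)
        meths.append(meth)
    df = pd.DataFrame(
        {
            "chrom": np.asarray(chroms, dtype=object),
            "pos": np.asarray(poss, dtype=np.int64),
            "meth": np.asarray(meths, dtype=float),
            "n_meth": np.asarray(nms, dtype=float),
            "n_unmeth": np.asarray(nus, dtype=float),
        }
    )
    df["coverage"] = df["n_meth"] + df["n_unmeth"]
    if df.empty:
        df = _empty_track_frame()
    return MethylomeTrack(label or path.stem, _canonicalize_track_frame(df, source=path))


def write_methylome_bedgraph(track: MethylomeTrack, path, dialect: str = "counts6") -> None:
    """Write a methylome track; output is byte-stable and round-trips through
    :func:`read_methylome_bedgraph` (methylation levels are written with six
    decimals)."""
    if dialect not in ("counts6", "level4"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = track.df
    if dialect == "counts6" and len(df) and not (
        df["n_meth"].notna().all() and df["n_unmeth"].notna().all()
    ):
        raise ValueError(
            f"track {track.label!r} lacks read counts; cannot write counts6 dialect"
        )
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        for row in df.itertuples(index=False):
            pos = int(row.pos)
            if dialect == "counts6":
                fh.write(
                    f"{row.chrom}\t{pos}\t{pos + 1}\t{row.meth:.6f}\t"
                    f"{int(row.n_meth)}\t{int(row.n_unmeth)}\n"
                )
            else:
                fh.write(f"{row.chrom}\t{pos}\t{pos + 1}\t{row.meth:.6f}\n")


# ---------------------------------------------------------------------------
# BED interval I/O
# ---------------------------------------------------------------------------


def read_intervals_bed(path) -> list[GenomicInterval]:
    """Read BED3+ intervals: optional name (col 4), score (col 5), strand (col 6)."""
    path = Path(path)
    out: list[GenomicInterval] = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise FormatError("BED line has fewer than 3 columns", path, lineno)
        try:
            start = int(fields[1])
            end = int(fields[2])
        except ValueError:
            raise FormatError("non-integer coordinates", path, lineno) from None
        if start < 0 or start >= end:
            raise FormatError(f"invalid interval [{start}, {end})", path, lineno)
        name = fields[3] if len(fields) > 3 and fields[3] != "." else None
        score = None
        if len(fields) > 4 and fields[4] != ".":
            try:
                score = float(fields[4])
            except ValueError:
                raise FormatError(f"non-numeric score {fields[4]!r}", path, lineno) from None
        strand = fields[5] if len(fields) > 5 else "."
        if strand not in STRANDS:
            raise FormatError(f"invalid strand {strand!r}", path, lineno)
        out.append(GenomicInterval(fields[0], start, end, strand, name, score))
    return out


def write_intervals_bed(intervals: Sequence[GenomicInterval], path) -> None:
    """Write intervals as BED; column count adapts to the richest record
    (BED3 if no annotation, BED6 if any strand is set)."""
    ncols = 3
    for iv in intervals:
        if iv.strand != ".":
            ncols = max(ncols, 6)
        elif iv.score is not None:
            ncols = max(ncols, 5)
        elif iv.name is not None:
            ncols = max(ncols, 4)
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if ncols >= 4:
                fields.append(iv.name if iv.name is not None else ".")
            if ncols >= 5:
                fields.append("." if iv.score is None else _fmt_score(iv.score))
            if ncols >= 6:
                fields.append(iv.strand)
            fh.write("\t".join(fields) + "\n")


def _fmt_score(score: float) -> str:
    if float(score).is_integer():
        return str(int(score))
    return repr(float(score))


# ---------------------------------------------------------------------------
# Gene annotation, chromosome sizes and count tables
# ---------------------------------------------------------------------------


def read_genes(path) -> list[GeneModel]:
    """Read the gene annotation table:
    ``gene_id  chrom  strand  tss1,tss2,...`` (tab-separated)."""
    path = Path(path)
    genes: list[GeneModel] = []
    seen: set[str] = set()
    for lineno, fields in _data_lines(path):
        if len(fields) < 4:
            raise FormatError("gene row needs 4 columns", path, lineno)
        gene_id, chrom, strand, tss_field = fields[:4]
        if gene_id in seen:
            raise FormatError(f"duplicate gene id {gene_id!r}", path, lineno)
        seen.add(gene_id)
        if strand not in ("+", "-"):
            raise FormatError(f"strand must be + or -, got {strand!r}", path, lineno)
        parts = [p for p in tss_field.split(",") if p != ""]
        if not parts:
            raise FormatError(f"gene {gene_id}: empty TSS list", path, lineno)
        try:
            tss = tuple(int(p) for p in parts)
        except ValueError:
            raise FormatError(f"non-integer TSS in {tss_field!r}", path, lineno) from None
        genes.append(GeneModel(gene_id, chrom, strand, tss))
    return genes


def write_genes(genes: Sequence[GeneModel], path) -> None:
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.strand}\t"
                + ",".join(str(t) for t in g.tss_list)
                + "\n"
            )


def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    path = Path(path)
    for lineno, fields in _data_lines(path):
        if len(fields) < 2:
            raise FormatError("chromosome-size row needs 2 columns", path, lineno)
        try:
            size = int(fields[1])
        except ValueError:
            raise FormatError("non-integer chromosome size", path, lineno) from None
        if size <= 0:
            raise FormatError("chromosome size must be positive", path, lineno)
        if fields[0] in sizes:
            raise FormatError(f"duplicate chromosome {fields[0]!r}", path, lineno)
        sizes[fields[0]] = size
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path) -> None:
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")


def read_count_table(path) -> SignalMatrix:
    """Read a region/gene x sample table of raw integer read counts.

    First row: sample names (the first cell names the id column and is
    ignored); first column: region/gene ids.  File order of both axes is
    preserved.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    except Exception as exc:  # pandas raises a zoo of parse errors
        raise FormatError(f"cannot parse count table ({exc})", path) from None
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicated row id {dup!r}", path)
    if df.columns.has_duplicates:
        raise FormatError("duplicated sample name in header", path)
    values = df.to_numpy()
    if values.size and not np.issubdtype(values.dtype, np.number):
        raise FormatError("non-numeric count in table", path)
    if values.size:
        if not np.all(np.isfinite(values)):
            raise FormatError("non-finite count in table", path)
        if (values < 0).any():
            raise FormatError("negative count in table", path)
        if not np.allclose(values, np.round(values)):
            raise FormatError("non-integer count in table", path)
    return SignalMatrix(
        values.astype(float),
        [str(i) for i in df.index],
        [str(c) for c in df.columns],
        stage="raw",
    )


def write_count_table(matrix: SignalMatrix, path, id_header: str = "region_id") -> None:
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        fh.write(id_header + "\t" + "\t".join(matrix.col_ids) + "\n")
        for rid, row in zip(matrix.row_ids, matrix.values):
            if matrix.stage == "raw":
                cells = "\t".join(str(int(round(v))) for v in row)
            else:
                cells = "\t".join(f"{v:.6g}" for v in row)
            fh.write(f"{rid}\t{cells}\n")
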