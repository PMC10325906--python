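"""Independent brute-force oracles used across the test suite.

Everything here is written as plain loops, deliberately ignorant of the
package's vectorised implementations, so the two routes stay independent.
"""

from __future__ import annotations

import hashlib
import math
from pathlib import Path

import numpy as np


def brute_screen(windows, deltas_df, drop_gt: float, min_sites: int,
                 ) -> dict[str, set]:
    """Loop over every CpG x window pair; return {region_id: qualifying set}
    restricted to regions reaching min_sites."""
    per_region: dict[str, set] = {}
    for w in windows:
        per_region.setdefault(w.name, set())
        for row in deltas_df.itertuples(index=False):
            if (row.chrom == w.chrom and w.start <= row.pos < w.end
                    and row.delta < -drop_gt):
                per_region[w.name].add((row.chrom, int(row.pos)))
    return {r: s for r, s in per_region.items() if len(s) >= min_sites}


def _pair_mergeable(a, b, book_ended: bool) -> bool:
    if a[0] != b[0]:
        return False
    if a[1] < b[2] and b[1] < a[2]:
        return True
    return book_ended and (a[2] == b[1] or b[2] == a[1])


def brute_merge(intervals, book_ended: bool = True) -> list[tuple[str, int, int]]:
    """Repeated pairwise union until a fixed point."""
    items = [(iv.chrom, iv.start, iv.end) for iv in intervals]
    changed = True
    while changed:
        changed = False
        out: list[tuple[str, int, int]] = []
        for it in items:
            placed = False
            for i, o in enumerate(out):
                if _pair_mergeable(it, o, book_ended):
                    out[i] = (o[0], min(o[1], it[1]), max(o[2], it[2]))
                    placed = True
                    changed = True
                    break
            if not placed:
                out.append(it)
        items = out
    return sorted(items)


def brute_diffspec(peaks, baseline) -> list:
    """All-pairs overlap scan (>= 1 shared base removes a peak)."""
    kept = []
    for p in peaks:
        hit = False
        for b in baseline:
            if p.chrom == b.chrom and p.start < b.end and b.start < p.end:
                hit = True
                break
        if not hit:
            kept.append(p)
    return kept


def naive_fcm(x: np.ndarray, c: int, m: float, seed: int,
              tol: float = 1e-9, max_iter: int = 1000):
    """Plain-loop fuzzy c-means with the same random-membership init
    convention (rows of a seeded uniform matrix, normalised)."""
    rng = np.random.default_rng(seed)
    n, p = x.shape
    u = rng.random((n, c))
    for i in range(n):
        u[i] = u[i] / u[i].sum()
    for _ in range(max_iter):
        v = np.zeros((c, p))
        for k in range(c):
            num = np.zeros(p)
            den = 0.0
            for i in range(n):
                w = u[i, k] ** m
                num = num + w * x[i]
                den += w
            v[k] = num / den
        d = np.zeros((n, c))
        for i in range(n):
            for k in range(c):
                d[i, k] = math.sqrt(sum((x[i, j] - v[k, j]) ** 2 for j in range(p)))
        u_new = np.zeros((n, c))
        for i in range(n):
            zeros = [k for k in range(c) if d[i, k] == 0.0]
            if zeros:
                for k in zeros:
                    u_new[i, k] = 1.0 / len(zeros)
            else:
                for k in range(c):
                    s = 0.0
                    for j in range(c):
                        s += (d[i, k] / d[i, j]) ** (2.0 / (m - 1.0))
                    u_new[i, k] = 1.0 / s
        shift = max(abs(u_new[i, k] - u[i, k]) for i in range(n) for k in range(c))
        u = u_new
        if shift < tol:
            break
    return v, u


def brute_dmin(centroids: np.ndarray) -> float:
    best = math.inf
    c = len(centroids)
    for i in range(c):
        for j in range(i + 1, c):
            d = math.sqrt(sum((centroids[i, k] - centroids[j, k]) ** 2
                              for k in range(centroids.shape[1])))
            best = min(best, d)
    return best


def naive_chip_profile(track, anchors, flank: int, bin_size: int):
    """Per-anchor loop-and-average of a binned track."""
    curves = []
    skipped = 0
    for a in anchors:
        arr = track.values.get(a.chrom)
        c = (a.start + a.end) // 2
        if arr is None or c - flank < 0 or c + flank > len(arr) * track.bin_size:
            skipped += 1
            continue
        vals = []
        for b in range(2 * flank // bin_size):
            s = c - flank + b * bin_size
            tot = 0.0
            for off in range(bin_size):
                tot += arr[(s + off) // track.bin_size]
            vals.append(tot / bin_size)
        curves.append(vals)
    return np.asarray(curves).mean(axis=0), len(curves), skipped


def naive_meth_profile(deltas_df, anchors, flank: int, bin_size: int):
    """Pool CpG deltas per offset bin with explicit loops; NaN where empty."""
    n_bins = 2 * flank // bin_size
    buckets: list[list[float]] = [[] for _ in range(n_bins)]
    for a in anchors:
        c = (a.start + a.end) // 2
        for row in deltas_df.itertuples(index=False):
            if row.chrom == a.chrom and c - flank <= row.pos < c + flank:
                buckets[(row.pos - (c - flank)) // bin_size].append(row.delta)
    return np.array([np.mean(b) if b else np.nan for b in buckets])


def pearson_sum_formula(a, b) -> float:
    n = len(a)
    sa = sum(a)
    sb = sum(b)
    sab = sum(x * y for x, y in zip(a, b))
    saa = sum(x * x for x in a)
    sbb = sum(y * y for y in b)
    num = n * sab - sa * sb
    den = math.sqrt(n * saa - sa * sa) * math.sqrt(n * sbb - sb * sb)
    return num / den


def tree_hash(directory) -> str:
    """SHA-256 over relative paths and file bytes of a directory tree."""
    h = hashlib.sha256()
    root = Path(directory)
    for f in sorted(root.rglob("*")):
        if f.is_file():
            h.update(str(f.relative_to(root)).encode())
            h.update(f.read_bytes())
    return h.hexdigest()
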