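"""TSS-proximal ChIP-signal quantification and fuzzy c-means temporal
clustering.

The quantification chain mirrors the standard count-matrix workflow:
raw counts -> CPM (per-sample counts per million) -> per-kilobase length
normalisation over each gene's merged TSS +/-5 kb regions -> replicate
averaging -> coefficient-of-variation filter on the linear scale ->
log2(x + 1) -> per-row z-scores.  The z-scored matrix feeds a soft
(fuzzy c-means) clustering of temporal profiles; the minimum pairwise
centroid distance (Dmin) across a range of cluster counts serves as the
cluster-number diagnostic, with the final count an explicit user choice.

Fuzzy c-means minimises ``J = sum_ik u_ik^m d_ik^2`` by alternating

* centroids   ``v_k = sum_i u_ik^m x_i / sum_i u_ik^m``
* memberships ``u_ik = 1 / sum_j (d_ik / d_ij)^(2/(m-1))``

with Euclidean distances ``d_ik = ||x_i - v_k||`` and fuzzifier ``m > 1``.
A point coinciding with one or more centroids gets its membership split
equally among the coincident centroids.  Initialisation draws a random
membership matrix (rows normalised) from a seeded generator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .genomio import SignalMatrix

__all__ = [
    "ClusterModel",
    "cpm_normalize",
    "length_normalize",
    "mean_over_replicates",
    "group_replicates",
    "cv_filter",
    "log2_zscore",
    "fuzzy_cmeans",
    "dmin_curve",
    "hard_assign",
]

logger = logging.getLogger(__name__)

_MEMBERSHIP_TOL = 1e-9


@dataclass
class ClusterModel:
    """A fitted fuzzy c-means model."""

    c: int
    m: float
    centroids: np.ndarray          # c x p
    membership: np.ndarray         # n x c, rows sum to 1
    objective_trace: list[float]   # J after each iteration
    seed: int | None
    converged: bool
    row_ids: list[str] = field(default_factory=list)

    @property
    def dmin(self) -> float:
        """Minimum pairwise Euclidean distance between centroids
        (``inf`` for a single-cluster model)."""
        if self.c < 2:
            return float("inf")
        d = cdist(self.centroids, self.centroids)
        iu = np.triu_indices(self.c, k=1)
        return float(d[iu].min())

    @property
    def objective(self) -> float:
        return self.objective_trace[-1]


# ---------------------------------------------------------------------------
# Normalisation chain
# ---------------------------------------------------------------------------


def cpm_normalize(matrix: SignalMatrix) -> SignalMatrix:
    """Counts per million: ``x_ij * 1e6 / colsum_j``."""
    if matrix.stage != "raw":
        raise ValueError(f"cpm_normalize expects raw counts, got stage {matrix.stage!r}")
    totals = matrix.values.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"sample {matrix.col_ids[zero[0]]!r} has zero total counts"
        )
    return matrix.with_values(matrix.values * 1e6 / totals, "cpm")


def length_normalize(matrix: SignalMatrix, lengths: Mapping[str, int] | Sequence[float]
                     ) -> SignalMatrix:
    """Per-kilobase scaling: ``x / (length_bp / 1000)`` with each row's
    merged-window length in bases."""
    if matrix.stage != "cpm":
        raise ValueError(f"length_normalize expects cpm, got stage {matrix.stage!r}")
    if isinstance(lengths, Mapping):
        missing = [r for r in matrix.row_ids if r not in lengths]
        if missing:
            raise ValueError(f"no length for row(s) {missing[:3]}")
        lens = np.array([lengths[r] for r in matrix.row_ids], dtype=float)
    else:
        lens = np.asarray(lengths, dtype=float)
        if lens.shape != (len(matrix.row_ids),):
            raise ValueError("lengths must align with matrix rows")
    if (lens <= 0).any():
        raise ValueError("all lengths must be > 0")
    return matrix.with_values(matrix.values / (lens[:, None] / 1000.0), "length_cpm")


def group_replicates(col_ids: Sequence[str]) -> dict[str, list[str]]:
    """Infer replicate groups from sample names of the form
    ``<condition>_rep<i>`` (anything without the suffix is its own group).
    Group order follows first appearance."""
    groups: dict[str, list[str]] = {}
    for cid in col_ids:
        stem = cid
        if "_rep" in cid:
            stem = cid[: cid.rindex("_rep")]
        groups.setdefault(stem, []).append(cid)
    return groups


def mean_over_replicates(matrix: SignalMatrix,
                         groups: Mapping[str, Sequence[str]] | None = None
                         ) -> SignalMatrix:
    """Average replicate columns; clustering consumes the per-condition mean."""
    if groups is None:
        groups = group_replicates(matrix.col_ids)
    col_index = {c: j for j, c in enumerate(matrix.col_ids)}
    cols = []
    names = []
    for name, members in groups.items():
        idx = [col_index[m] for m in members]
        cols.append(matrix.values[:, idx].mean(axis=1))
        names.append(name)
    return matrix.with_values(np.column_stack(cols), matrix.stage, col_ids=names)


def cv_filter(matrix: SignalMatrix, cv_min: float = 0.2) -> SignalMatrix:
    """Drop rows whose coefficient of variation (sd/mean, population sd) is
    below ``cv_min``; rows with zero mean are dropped too.  Must run on the
    linear (pre-log) scale."""
    if matrix.stage in ("log2", "zscore"):
        raise ValueError("cv_filter must run on linear-scale values")
    mean = matrix.values.mean(axis=1)
    sd = matrix.values.std(axis=1, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    keep = np.where(np.isnan(cv), False, cv >= cv_min)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("cv_filter: removed %d of %d rows (CV < %g or zero mean)",
                    dropped, len(keep), cv_min)
    return matrix.with_values(
        matrix.values[keep], matrix.stage,
        row_ids=[r for r, k in zip(matrix.row_ids, keep) if k],
    )


def log2_zscore(matrix: SignalMatrix, pseudocount: float = 1.0) -> SignalMatrix:
    """``x -> log2(x + pseudocount)`` then per-row z-scores
    ``(x - rowmean) / rowsd`` (population sd).  Zero-variance rows cannot be
    z-scored and are dropped with a warning."""
    if (matrix.values < 0).any():
        raise ValueError("log2_zscore expects non-negative values")
    logged = np.log2(matrix.values + pseudocount)
    mean = logged.mean(axis=1, keepdims=True)
    sd = logged.std(axis=1, ddof=0, keepdims=True)
    keep = sd[:, 0] > 0
    if not keep.all():
        logger.warning("log2_zscore: dropping %d zero-variance row(s)",
                       int((~keep).sum()))
    z = (logged[keep] - mean[keep]) / sd[keep]
    return matrix.with_values(
        z, "zscore", row_ids=[r for r, k in zip(matrix.row_ids, keep) if k]
    )


# ---------------------------------------------------------------------------
# Fuzzy c-means
# ---------------------------------------------------------------------------


def _fcm_membership(dist: np.ndarray, m: float) -> np.ndarray:
    """Membership update from an n x c distance matrix; exact-hit rows get
    equal split among their zero-distance centroids."""
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = dist ** (-2.0 / (m - 1.0))
        u = inv / inv.sum(axis=1, keepdims=True)
    zero_rows = (dist == 0).any(axis=1)
    if zero_rows.any():
        hits = dist[zero_rows] == 0
        u[zero_rows] = hits / hits.sum(axis=1, keepdims=True)
    return u


def _fcm_single(x: np.ndarray, c: int, m: float, rng: np.random.Generator,
                tol: float, max_iter: int) -> tuple[np.ndarray, np.ndarray, list[float], bool]:
    n = x.shape[0]
    u = rng.random((n, c))
    u /= u.sum(axis=1, keepdims=True)
    trace: list[float] = []
    converged = False
    centroids = np.empty((c, x.shape[1]))
    for _ in range(max_iter):
        um = u ** m
        centroids = (um.T @ x) / um.sum(axis=0)[:, None]
        dist = cdist(x, centroids)
        u_new = _fcm_membership(dist, m)
        trace.append(float(((u_new ** m) * dist ** 2).sum()))
        shift = float(np.abs(u_new - u).max())
        u = u_new
        if shift < tol:
            converged = True
            break
    return centroids, u, trace, converged


def fuzzy_cmeans(matrix: SignalMatrix | np.ndarray, c: int, m: float = 2.0,
                 seed: int | None = None, tol: float = 1e-6,
                 max_iter: int = 300, n_init: int = 1) -> ClusterModel:
    """Fit fuzzy c-means on the rows of ``matrix``.

    ``n_init`` independent random-membership starts are run (seeds derived
    from ``seed``) and the fit with the lowest final objective is kept; the
    default of 1 reproduces a single seeded run exactly.  Stops when the
    largest membership change falls below ``tol`` or after ``max_iter``
    alternating updates.
    """
    if isinstance(matrix, SignalMatrix):
        x = matrix.values
        row_ids = list(matrix.row_ids)
    else:
        x = np.asarray(matrix, dtype=float)
        row_ids = []
    if x.ndim != 2:
        raise ValueError("input must be 2-D")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in clustering input")
    n = x.shape[0]
    if c < 1:
        raise ValueError("c must be >= 1")
    if c > n:
        raise ValueError(f"c = {c} exceeds the number of rows ({n})")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    if n_init < 1:
        raise ValueError("n_init must be >= 1")

    if n_init == 1:
        rngs = [np.random.default_rng(seed)]
    else:
        rngs = [np.random.default_rng(child)
                for child in np.random.SeedSequence(seed).spawn(n_init)]
    best: tuple | None = None
    for rng in rngs:
        fit = _fcm_single(x, c, m, rng, tol, max_iter)
        if best is None or fit[2][-1] < best[2][-1]:
            best = fit
    centroids, u, trace, converged = best  # type: ignore[misc]
    if not converged:
        logger.warning("fuzzy_cmeans: not converged after %d iterations", max_iter)
    return ClusterModel(
        c=c, m=m, centroids=centroids, membership=u,
        objective_trace=trace, seed=seed, converged=converged,
        row_ids=row_ids,
    )


def dmin_curve(matrix: SignalMatrix | np.ndarray, c_range: Sequence[int],
               m: float = 2.0, repeats: int = 3, seed: int | None = None,
               tol: float = 1e-6, max_iter: int = 300
               ) -> list[tuple[int, float]]:
    """Mean minimum centroid distance per candidate cluster count.

    For each ``c`` the model is fitted ``repeats`` times with seeds derived
    deterministically from ``seed``; the reported Dmin is the mean over
    repeats.  The curve is a diagnostic — a sharp decay of Dmin flags
    over-clustering — and the final cluster count remains a user decision.
    """
    n = (matrix.values if isinstance(matrix, SignalMatrix) else np.asarray(matrix)).shape[0]
    out: list[tuple[int, float]] = []
    for c in c_range:
        if not 2 <= c <= n:
            raise ValueError(f"cluster count {c} outside [2, {n}]")
        dmins = []
        for r in range(repeats):
            child = int(np.random.SeedSequence([0 if seed is None else seed, c, r])
                        .generate_state(1)[0] % (2 ** 31))
            model = fuzzy_cmeans(matrix, c, m=m, seed=child, tol=tol,
                                 max_iter=max_iter)
            dmins.append(model.dmin)
        out.append((c, float(np.mean(dmins))))
    return out


def hard_assign(model: ClusterModel) -> np.ndarray:
    """Crisp 1-based cluster labels: argmax membership per row, ties broken
    toward the lowest cluster index."""
    return np.argmax(model.membership, axis=1) + 1
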