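"""Correlation-based Feature Selection (CFS) with best-first subset search.

CFS scores a candidate feature subset S of size k by the merit heuristic

    Merit(S) = k * mean(r_cf) / sqrt(k + k * (k - 1) * mean(r_ff)),

where ``r_cf`` is the association of each member with the class label and
``r_ff`` the pairwise association between members: good subsets contain
features that are individually predictive and mutually non-redundant.  At
k = 1 the pairwise term vanishes and the merit reduces to ``r_cf``.

Associations are measured by symmetrical uncertainty,
SU(x, y) = 2 I(x; y) / (H(x) + H(y)), on features discretized by the
Fayyad-Irani minimum-description-length criterion; absolute Pearson
correlation is available as an alternative for continuous data.

Subset space is explored by forward best-first search with backtracking: a
priority queue of unexpanded subsets keyed by merit, expanding the best by
every single-feature addition, with a stopping patience of ``stale_limit``
consecutive non-improving expansions.  Ties are broken by canonical feature
order, making the search fully deterministic.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .features import FeatureMatrix, FeatureSubset
from .seqio import PhavipError

AssociationMethod = Literal["symmetrical-uncertainty", "abs-pearson"]


class SelectionError(PhavipError):
    """Feature selection cannot proceed (empty subset, unlabelled data, ...)."""


# --------------------------------------------------------------------------
# Fayyad-Irani MDL discretization
# --------------------------------------------------------------------------

def _entropy_bits(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def _binary_entropy_from_pos(n_pos: np.ndarray | float, n: np.ndarray | float):
    """Entropy (bits) of binary splits given positive counts, vectorized."""
    n = np.asarray(n, dtype=np.float64)
    n_pos = np.asarray(n_pos, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = np.where(n > 0, n_pos / n, 0.0)
        p0 = 1.0 - p1
        h = -(np.where(p1 > 0, p1 * np.log2(p1), 0.0)
              + np.where(p0 > 0, p0 * np.log2(p0), 0.0))
    return h


def mdlp_cut_points(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Fayyad-Irani recursive entropy discretization of one feature.

    Returns the strictly increasing cut points (midpoints between adjacent
    observed values) accepted by the MDL stopping criterion; an empty array
    means the feature is left as a single bin.
    """
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    order = np.argsort(values, kind="stable")
    v = values[order]
    y = labels[order]
    cuts: list[float] = []

    def recurse(lo: int, hi: int) -> None:
        n = hi - lo
        if n < 2:
            return
        seg_v = v[lo:hi]
        seg_y = y[lo:hi]
        # candidate boundaries: between adjacent distinct values
        cand = np.nonzero(seg_v[:-1] < seg_v[1:])[0]  # split after index i
        if cand.size == 0:
            return
        cum_pos = np.cumsum(seg_y)
        total_pos = cum_pos[-1]
        n_left = cand + 1
        n_right = n - n_left
        pos_left = cum_pos[cand]
        pos_right = total_pos - pos_left
        h_left = _binary_entropy_from_pos(pos_left, n_left)
        h_right = _binary_entropy_from_pos(pos_right, n_right)
        weighted = (n_left * h_left + n_right * h_right) / n
        ent_s = _binary_entropy_from_pos(total_pos, n)
        gains = ent_s - weighted
        best = int(np.argmax(gains))  # ties -> smallest candidate index
        gain = float(gains[best])
        i = int(cand[best])
        k = int(len(np.unique(seg_y)))
        k1 = int(len(np.unique(seg_y[: i + 1])))
        k2 = int(len(np.unique(seg_y[i + 1:])))
        delta = (math.log2(3 ** k - 2)
                 - (k * float(ent_s) - k1 * float(h_left[best]) - k2 * float(h_right[best])))
        threshold = (math.log2(n - 1) + delta) / n
        if gain <= threshold:
            return
        cuts.append(float((seg_v[i] + seg_v[i + 1]) / 2.0))
        recurse(lo, lo + i + 1)
        recurse(lo + i + 1, hi)

    recurse(0, len(v))
    return np.array(sorted(cuts), dtype=np.float64)


@dataclass(frozen=True)
class DiscretizationScheme:
    """Per-feature MDL cut points learned from a labelled training matrix."""

    feature_names: tuple[str, ...]
    cut_points: tuple[np.ndarray, ...]

    def bins(self, name: str, values: np.ndarray) -> np.ndarray:
        i = self.feature_names.index(name)
        return np.searchsorted(self.cut_points[i], values, side="right")


def discretize_mdl(matrix: FeatureMatrix) -> DiscretizationScheme:
    """Learn Fayyad-Irani cut points for every feature of a labelled matrix."""
    matrix.require_labelled()
    cuts = tuple(
        mdlp_cut_points(matrix.values[:, j], matrix.labels)
        for j in range(matrix.n_features)
    )
    return DiscretizationScheme(feature_names=matrix.feature_names, cut_points=cuts)


# --------------------------------------------------------------------------
# Association measures
# --------------------------------------------------------------------------

def symmetrical_uncertainty(x: np.ndarray, y: np.ndarray) -> float:
    """SU(x, y) = 2 I(x; y) / (H(x) + H(y)), base-2 logs, in [0, 1].

    Both arguments are discrete (integer-coded) samples of equal length.
    When both variables are constant the denominator vanishes and SU is
    defined as 0.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise SelectionError("SU requires two equal-length 1-d samples")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    nx = xi.max() + 1
    ny = yi.max() + 1
    joint = np.bincount(xi * ny + yi, minlength=nx * ny)
    hx = _entropy_bits(np.bincount(xi))
    hy = _entropy_bits(np.bincount(yi))
    hxy = _entropy_bits(joint)
    denom = hx + hy
    if denom <= 0.0:
        return 0.0
    mi = hx + hy - hxy
    return float(min(1.0, max(0.0, 2.0 * mi / denom)))


def _abs_pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    sx = x.std()
    sy = y.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    r = float(np.corrcoef(x, y)[0, 1])
    return min(1.0, abs(r))


class CorrelationTable:
    """Lazily cached feature-class and feature-feature associations.

    ``r_cf(i)`` is the association of feature i with the class label and
    ``r_ff(i, j)`` the symmetric association between features i and j, both
    in [0, 1] with ``r_ff(i, i) = 1``.
    """

    def __init__(
        self,
        columns: np.ndarray,
        labels: np.ndarray,
        feature_names: tuple[str, ...],
        method: AssociationMethod,
    ):
        self._columns = columns
        self._labels = labels
        self.feature_names = feature_names
        self.method = method
        self.n_features = columns.shape[1]
        self._cf_cache: dict[int, float] = {}
        self._ff_cache: dict[tuple[int, int], float] = {}

    @classmethod
    def from_matrix(
        cls, matrix: FeatureMatrix, method: AssociationMethod = "symmetrical-uncertainty"
    ) -> "CorrelationTable":
        matrix.require_labelled()
        if method == "symmetrical-uncertainty":
            scheme = discretize_mdl(matrix)
            cols = np.column_stack([
                np.searchsorted(scheme.cut_points[j], matrix.values[:, j], side="right")
                for j in range(matrix.n_features)
            ])
        elif method == "abs-pearson":
            cols = matrix.values
        else:
            raise SelectionError(f"unknown association method {method!r}")
        return cls(cols, matrix.labels, matrix.feature_names, method)

    def _assoc(self, a: np.ndarray, b: np.ndarray) -> float:
        if self.method == "symmetrical-uncertainty":
            return symmetrical_uncertainty(a, b)
        return _abs_pearson(a, b)

    def r_cf(self, i: int) -> float:
        if i not in self._cf_cache:
            self._cf_cache[i] = self._assoc(self._columns[:, i], self._labels)
        return self._cf_cache[i]

    def r_ff(self, i: int, j: int) -> float:
        if i == j:
            return 1.0
        key = (i, j) if i < j else (j, i)
        if key not in self._ff_cache:
            self._ff_cache[key] = self._assoc(self._columns[:, key[0]], self._columns[:, key[1]])
        return self._ff_cache[key]


# --------------------------------------------------------------------------
# Merit and best-first search
# --------------------------------------------------------------------------

def cfs_merit(subset: Sequence[int] | FeatureSubset, table: CorrelationTable) -> float:
    """CFS merit of a non-empty subset under a correlation table."""
    if isinstance(subset, FeatureSubset):
        index = {n: i for i, n in enumerate(table.feature_names)}
        idx = [index[n] for n in subset.names]
    else:
        idx = list(subset)
    k = len(idx)
    if k == 0:
        raise SelectionError("CFS merit is undefined for the empty subset")
    rcf = sum(table.r_cf(i) for i in idx) / k
    if k == 1:
        return rcf
    pair_sum = 0.0
    for a in range(k):
        for b in range(a + 1, k):
            pair_sum += table.r_ff(idx[a], idx[b])
    rff = pair_sum / (k * (k - 1) / 2)
    return (k * rcf) / math.sqrt(k + k * (k - 1) * rff)


@dataclass(frozen=True)
class TraceEntry:
    step: int
    subset: tuple[str, ...]
    merit: float
    action: str  # expand | backtrack | stop


@dataclass
class SearchTrace:
    """Audit log of a best-first run: one entry per expanded node plus a stop."""

    entries: list[TraceEntry] = field(default_factory=list)
    stale_counter: int = 0

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("step\tsubset\tmerit\taction\n")
            for e in self.entries:
                fh.write(f"{e.step}\t{','.join(e.subset)}\t{e.merit:.17g}\t{e.action}\n")


def best_first_search(
    matrix: FeatureMatrix,
    stale_limit: float = 5,
    method: AssociationMethod = "symmetrical-uncertainty",
    table: CorrelationTable | None = None,
) -> tuple[FeatureSubset, SearchTrace]:
    """Forward best-first subset search with backtracking.

    Starting from the empty set, repeatedly expands the best unexpanded
    subset by every single-feature addition, tracking the best merit seen
    anywhere.  The search stops after ``stale_limit`` consecutive expansions
    without a strict improvement of the global best (``math.inf`` removes
    the patience and runs until the queue is exhausted).
    """
    if matrix.n_features < 1:
        raise SelectionError("best-first search requires at least one feature")
    if stale_limit < 1:
        raise SelectionError("stale_limit must be >= 1")
    if table is None:
        table = CorrelationTable.from_matrix(matrix, method)
    p = table.n_features
    names = table.feature_names

    evaluated: set[frozenset[int]] = {frozenset()}
    # heap entries: (-merit, canonical index tuple); canonical order breaks ties
    heap: list[tuple[float, tuple[int, ...]]] = [(-0.0, ())]
    best_subset: tuple[int, ...] | None = None
    best_merit = -math.inf
    trace = SearchTrace()
    stale = 0
    step = 0
    prev: frozenset[int] = frozenset()

    while heap and stale < stale_limit:
        neg_m, key = heapq.heappop(heap)
        node = frozenset(key)
        action = "expand" if prev <= node else "backtrack"
        trace.entries.append(TraceEntry(step, tuple(names[i] for i in key), -neg_m, action))
        prev = node
        step += 1
        improved = False
        for f in range(p):
            if f in node:
                continue
            child = node | {f}
            if child in evaluated:
                continue
            evaluated.add(child)
            child_key = tuple(sorted(child))
            m = cfs_merit(child_key, table)
            if m > best_merit:
                best_merit = m
                best_subset = child_key
                improved = True
            heapq.heappush(heap, (-m, child_key))
        if improved:
            stale = 0
        else:
            stale += 1

    trace.stale_counter = stale
    if best_subset is None:  # single feature already in queue but never expanded
        best_subset = (0,)
        best_merit = cfs_merit(best_subset, table)
    trace.entries.append(
        TraceEntry(step, tuple(names[i] for i in best_subset), best_merit, "stop")
    )
    return FeatureSubset(tuple(names[i] for i in best_subset)), trace
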