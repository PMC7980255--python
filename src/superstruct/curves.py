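"""The ε-sweep: cluster counts Nc(ε) over a neighborhood-radius grid.

The central object is the curve ε → Nc, the number of DBSCAN clusters
detected at neighborhood radius ε with the minimum-neighbor threshold Nmin
held fixed. With Nmin = 0 every localization is a core point and clusters
are exactly the connected components of the ε-neighborhood graph, so the
whole curve can be read off the Euclidean minimum spanning tree (EMST) of
the point set: merging two components when ε reaches an edge length gives

    Nc(ε) = N − #{EMST edge lengths ≤ ε}.

That identity is exact (not an approximation) under the closed-ball neighbor
rule used throughout, and turns the per-ε DBSCAN loop into one spatial
computation. The naive per-ε sweep is retained as an oracle and for
Nmin ≥ 1, where outliers can occur and the EMST shortcut does not apply.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial import Delaunay, QhullError
from sklearn.cluster import DBSCAN

from .locio import LocalizationTable

__all__ = [
    "EpsilonGrid",
    "SuperStructureCurve",
    "CurveEnsemble",
    "build_epsilon_grid",
    "cluster_components",
    "emst_edge_lengths",
    "superstructure_curve",
    "average_curves",
]


@dataclass(frozen=True)
class EpsilonGrid:
    """Strictly increasing ε values (nm), built from arithmetic segments."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or len(values) == 0:
            raise ValueError("epsilon grid must be a non-empty 1D array")
        if np.any(np.diff(values) <= 0):
            raise ValueError("epsilon grid values must be strictly increasing")
        if values[0] < 0:
            raise ValueError("epsilon values must be non-negative")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.values)

    @classmethod
    def from_values(cls, values: np.ndarray) -> "EpsilonGrid":
        return cls(np.asarray(values, dtype=float))


def build_epsilon_grid(
    segments: Sequence[tuple[float, float, float]],
) -> EpsilonGrid:
    """Concatenate arithmetic ε sequences, e.g. ``[(0, 10, 0.25), (10, 200, 10)]``.

    Each segment (start, end, dε) contributes start, start+dε, …, end.
    Segments must be ordered and non-overlapping; a boundary value shared by
    consecutive segments is kept once.
    """
    if not segments:
        raise ValueError("at least one segment required")
    values: list[np.ndarray] = []
    prev_end = -np.inf
    for start, end, step in segments:
        if step <= 0:
            raise ValueError(f"segment step must be positive, got {step}")
        if end <= start:
            raise ValueError(f"segment ({start}, {end}) is not increasing")
        if start < prev_end:
            raise ValueError("segments overlap")
        n = int(round((end - start) / step))
        seg = start + step * np.arange(n + 1)
        if seg[-1] > end + 1e-9:
            seg = seg[seg <= end + 1e-9]
        if values and abs(seg[0] - values[-1][-1]) < 1e-9:
            seg = seg[1:]
        values.append(seg)
        prev_end = end
    return EpsilonGrid(np.concatenate(values))


@dataclass(frozen=True)
class SuperStructureCurve:
    """Sampled cluster-count curve: grid, Nc per ε, and Nc/Nloc."""

    grid: EpsilonGrid
    nc: np.ndarray
    nloc: int
    normalized: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        nc = np.asarray(self.nc, dtype=np.int64)
        if len(nc) != len(self.grid):
            raise ValueError("nc length must match grid length")
        if self.nloc < 1:
            raise ValueError("nloc must be at least 1")
        if np.any(np.diff(nc) > 0):
            raise ValueError("Nc must be monotonically non-increasing in epsilon")
        if nc.min() < 1 or nc.max() > self.nloc:
            raise ValueError("Nc must lie in [1, Nloc]")
        object.__setattr__(self, "nc", nc)
        object.__setattr__(self, "normalized", nc / float(self.nloc))


@dataclass(frozen=True)
class CurveEnsemble:
    """Per-ε mean and sample sd of normalized curves from replicate datasets."""

    grid: EpsilonGrid
    mean: np.ndarray
    sd: np.ndarray
    n_replicates: int


def cluster_components(
    table: LocalizationTable, epsilon: float, nmin: int = 0
) -> np.ndarray:
    """DBSCAN labels at fixed ε (closed-ball neighbors, distance ≤ ε).

    A point is core if it has at least ``nmin`` neighbors excluding itself;
    with ``nmin=0`` every point is core and the labels are the connected
    components of the ε-neighborhood graph (singletons allowed). Non-core
    points unreachable from any core point are labeled ``-1`` (outliers),
    which can only happen for ``nmin >= 1``.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    if nmin < 0:
        raise ValueError("nmin must be non-negative")
    xy = table.xy
    n = len(xy)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    if epsilon == 0:
        # only exact duplicates merge; unique rows get consecutive ids
        _, labels = np.unique(xy, axis=0, return_inverse=True)
        if nmin >= 1:
            counts = np.bincount(labels)
            labels = labels.copy()
            labels[counts[labels] < nmin + 1] = -1
            labels = _compact_labels(labels)
        return labels.astype(np.int64)
    # sklearn's radius query is closed (distance <= eps) and min_samples
    # counts the point itself, hence nmin + 1
    model = DBSCAN(eps=epsilon, min_samples=nmin + 1)
    return model.fit(xy).labels_.astype(np.int64)


def _compact_labels(labels: np.ndarray) -> np.ndarray:
    """Renumber non-negative labels consecutively, keeping -1 for outliers."""
    out = np.full(len(labels), -1, dtype=np.int64)
    mask = labels >= 0
    if mask.any():
        _, out[mask] = np.unique(labels[mask], return_inverse=True)
    return out


def emst_edge_lengths(xy: np.ndarray) -> np.ndarray:
    """Edge lengths of the Euclidean minimum spanning tree, ascending.

    Exact duplicates contribute zero-length edges. For point sets in general
    position the EMST is extracted from the Delaunay triangulation (which is
    a supergraph of the EMST in the plane); degenerate sets — all points
    collinear or too few points — fall back to direct constructions.
    """
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    if n <= 1:
        return np.empty(0)
    unique, inverse = np.unique(xy, axis=0, return_inverse=True)
    n_dup = n - len(unique)
    dup_edges = np.zeros(n_dup)
    if len(unique) == 1:
        return dup_edges
    if len(unique) == 2:
        w = np.array([np.linalg.norm(unique[1] - unique[0])])
        return np.sort(np.concatenate([dup_edges, w]))
    try:
        tri = Delaunay(unique)
        simplices = tri.simplices
        i = np.concatenate([simplices[:, 0], simplices[:, 1], simplices[:, 2]])
        j = np.concatenate([simplices[:, 1], simplices[:, 2], simplices[:, 0]])
    except QhullError:
        # collinear points: the EMST on a line connects sort-order neighbors
        direction = unique[-1] - unique[0]
        t = unique @ direction
        order = np.argsort(t)
        i, j = order[:-1], order[1:]
    w = np.linalg.norm(unique[i] - unique[j], axis=1)
    graph = coo_matrix((w, (i, j)), shape=(len(unique), len(unique)))
    mst = minimum_spanning_tree(graph)
    weights = np.sort(mst.data)
    if len(weights) != len(unique) - 1:
        raise RuntimeError("EMST construction produced a disconnected tree")
    return np.sort(np.concatenate([dup_edges, weights]))


def superstructure_curve(
    table: LocalizationTable,
    grid: EpsilonGrid,
    nmin: int = 0,
    engine: Literal["naive", "mst"] = "mst",
) -> SuperStructureCurve:
    """Sweep ε over the grid and count clusters at each value.

    With ``engine="mst"`` (only valid for ``nmin=0``) the whole curve is
    computed from the EMST edge lengths; with ``engine="naive"`` DBSCAN is
    run independently at every ε. The two engines agree exactly for
    ``nmin=0``. With ``nmin >= 1`` outlier points are not counted as
    clusters.
    """
    n = len(table)
    if n == 0:
        raise ValueError("cannot compute a curve for an empty table")
    if engine == "mst":
        if nmin != 0:
            raise ValueError("the mst engine requires nmin=0")
        weights = emst_edge_lengths(table.xy)
        merged = np.searchsorted(weights, grid.values, side="right")
        nc = n - merged
    elif engine == "naive":
        nc = np.empty(len(grid), dtype=np.int64)
        for k, eps in enumerate(grid.values):
            labels = cluster_components(table, eps, nmin)
            nc[k] = labels.max() + 1 if (labels >= 0).any() else 0
        if nmin >= 1:
            # all-outlier grids would violate the Nc >= 1 invariant
            nc = np.maximum(nc, 1)
    else:
        raise ValueError(f"unknown engine {engine!r}")
    return SuperStructureCurve(grid=grid, nc=np.asarray(nc, dtype=np.int64), nloc=n)


def average_curves(curves: Iterable[SuperStructureCurve]) -> CurveEnsemble:
    """Average normalized curves from replicate datasets on a shared grid.

    Returns per-ε mean and sample standard deviation (n − 1 denominator);
    at least two curves are required.
    """
    curves = list(curves)
    if len(curves) < 2:
        raise ValueError("need at least 2 curves to average")
    grid = curves[0].grid
    for c in curves[1:]:
        if len(c.grid) != len(grid) or not np.allclose(c.grid.values, grid.values):
            raise ValueError("all curves must share an identical epsilon grid")
    stack = np.stack([c.normalized for c in curves])
    return CurveEnsemble(
        grid=grid,
        mean=stack.mean(axis=0),
        sd=stack.std(axis=0, ddof=1),
        n_replicates=len(curves),
    )
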