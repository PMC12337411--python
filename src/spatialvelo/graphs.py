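"""Cell graphs: within-batch spatial kNN plus cross-batch OT-based MNN edges.

The graph-attention encoder consumes a single combined graph. Within each
batch, cells connect to their k spatially nearest neighbours (Euclidean on
the platform coordinates). Across batches, cells connect to mutual nearest
neighbours, where "nearness" is the coupling mass of an optimal-transport
plan between the two batches' expression profiles (Euclidean cost on a
low-dimensional PCA representation, uniform marginals): cell pairs that are
mutually within each other's top-k coupling mass become MNN edges.

The OT solver is local: exact linear-assignment transport when the two
batches have equal size (the optimal coupling with uniform marginals is then
a permutation, found by the Hungarian algorithm), entropic Sinkhorn
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "CellGraph",
    "spatial_knn_edges",
    "ot_mnn_edges",
    "ot_coupling",
    "sinkhorn",
    "combine_graph",
    "build_cell_graph",
]


@dataclass
class CellGraph:
    """Weighted, typed edge list over ``n_cells`` cells.

    ``kind`` is ``"spatial"`` (same-batch) or ``"mnn"`` (cross-batch) per
    edge; ``"self"`` loops may be added for the attention layer.
    """

    src: np.ndarray
    dst: np.ndarray
    weight: np.ndarray
    kind: np.ndarray
    n_cells: int

    @property
    def n_edges(self) -> int:
        return len(self.src)

    def with_self_loops(self, weight: float = 1.0) -> "CellGraph":
        loops = np.arange(self.n_cells)
        return CellGraph(
            src=np.concatenate([self.src, loops]),
            dst=np.concatenate([self.dst, loops]),
            weight=np.concatenate([self.weight, np.full(self.n_cells, weight)]),
            kind=np.concatenate([self.kind, np.full(self.n_cells, "self")]),
            n_cells=self.n_cells,
        )

    def subset_kinds(self, kinds) -> "CellGraph":
        m = np.isin(self.kind, list(kinds))
        return CellGraph(self.src[m], self.dst[m], self.weight[m], self.kind[m],
                         self.n_cells)

    def to_tsv(self, path):
        import pandas as pd

        pd.DataFrame({"source": self.src, "target": self.dst,
                      "weight": self.weight, "kind": self.kind}).to_csv(
            path, sep="\t", index=False)


def _symmetrize(src, dst):
    """Undirected closure: keep an edge in both directions if either exists."""
    a = np.concatenate([src, dst])
    b = np.concatenate([dst, src])
    pairs = np.unique(np.stack([a, b], axis=1), axis=0)
    return pairs[:, 0], pairs[:, 1]


def spatial_knn_edges(X: np.ndarray, batch, k: int = 15):
    """Per-batch spatial kNN edges (symmetrised), no cross-batch edges.

    Ties in distance are broken by lower cell index (stable sort).
    """
    X = np.asarray(X, dtype=float)
    batch = np.asarray(batch)
    srcs, dsts = [], []
    for b in np.unique(batch):
        idx = np.flatnonzero(batch == b)
        if len(idx) < k + 1:
            raise ValueError(
                f"batch {b!r} has {len(idx)} cells; spatial kNN with k={k} "
                f"needs at least {k + 1}"
            )
        D = cdist(X[idx], X[idx])
        np.fill_diagonal(D, np.inf)
        order = np.argsort(D, axis=1, kind="stable")[:, :k]
        s = np.repeat(idx, k)
        d = idx[order.ravel()]
        srcs.append(s)
        dsts.append(d)
    src, dst = _symmetrize(np.concatenate(srcs), np.concatenate(dsts))
    return src, dst


def sinkhorn(C: np.ndarray, reg: float, a=None, b=None, n_iter: int = 500,
             tol: float = 1e-9) -> np.ndarray:
    """Entropic OT coupling for cost ``C`` with marginals ``a``, ``b``."""
    n, m = C.shape
    a = np.full(n, 1.0 / n) if a is None else a
    b = np.full(m, 1.0 / m) if b is None else b
    K = np.exp(-C / reg)
    K = np.clip(K, 1e-300, None)
    u = np.ones(n) / n
    for _ in range(n_iter):
        v = b / (K.T @ u)
        u_new = a / (K @ v)
        if np.max(np.abs(u_new - u)) < tol * np.max(np.abs(u_new)):
            u = u_new
            break
        u = u_new
    return u[:, None] * K * v[None, :]


def ot_coupling(A: np.ndarray, B: np.ndarray, reg: float = 0.05) -> np.ndarray:
    """Optimal-transport coupling between two point clouds, uniform marginals.

    Equal sizes: exact (assignment-based) transport. Unequal sizes: Sinkhorn
    with regularisation ``reg`` relative to the mean cost.
    """
    C = cdist(A, B)
    n, m = C.shape
    if n == m:
        r, c = linear_sum_assignment(C)
        P = np.zeros((n, m))
        P[r, c] = 1.0 / n
        return P
    scale = C.mean() if C.mean() > 0 else 1.0
    return sinkhorn(C / scale, reg)


def ot_mnn_edges(expr: np.ndarray, batch, k: int = 15, n_pcs: int = 30,
                 reg: float = 0.05):
    """Cross-batch mutual-nearest-neighbour edges under OT coupling mass.

    ``expr`` is a cell x feature expression representation; if wider than
    ``n_pcs`` it is reduced by PCA first. For every unordered batch pair the
    OT coupling is computed and a cell pair (i, j) becomes an edge when j is
    among i's top-k coupling masses AND i among j's. Requires >= 2 batches;
    k is clipped (with a warning) for batches smaller than k.
    """
    import warnings

    expr = np.asarray(expr, dtype=float)
    batch = np.asarray(batch)
    levels = np.unique(batch)
    if len(levels) < 2:
        raise ValueError("OT-MNN edges require at least 2 batches")
    if k == 0:
        e = np.array([], dtype=int)
        return e, e.copy()
    if expr.shape[1] > n_pcs:
        expr = PCA(n_components=n_pcs, random_state=0).fit_transform(expr)
    srcs, dsts = [], []
    for i1 in range(len(levels)):
        for i2 in range(i1 + 1, len(levels)):
            ia = np.flatnonzero(batch == levels[i1])
            ib = np.flatnonzero(batch == levels[i2])
            kk = min(k, len(ia), len(ib))
            if kk < k:
                warnings.warn(
                    f"batch pair ({levels[i1]!r}, {levels[i2]!r}) smaller than "
                    f"k={k}; clipping to {kk}"
                )
            P = ot_coupling(expr[ia], expr[ib], reg=reg)
            # top-k by coupling mass, ties to lower index (stable on -P)
            top_a = np.argsort(-P, axis=1, kind="stable")[:, :kk]
            top_b = np.argsort(-P.T, axis=1, kind="stable")[:, :kk]
            in_top_a = np.zeros_like(P, dtype=bool)
            np.put_along_axis(in_top_a, top_a, True, axis=1)
            in_top_b = np.zeros_like(P.T, dtype=bool)
            np.put_along_axis(in_top_b, top_b, True, axis=1)
            mutual = in_top_a & in_top_b.T & (P > 0)
            r, c = np.nonzero(mutual)
            srcs.append(ia[r])
            dsts.append(ib[c])
    if not srcs or all(len(s) == 0 for s in srcs):
        e = np.array([], dtype=int)
        return e, e.copy()
    src, dst = _symmetrize(np.concatenate(srcs), np.concatenate(dsts))
    return src, dst


def combine_graph(spatial_edges, mnn_edges, w_spatial: float = 1.0,
                  w_mnn: float = 1.0, n_cells: int | None = None) -> CellGraph:
    """Union of the two edge sets with per-kind weights; zero weight drops a kind."""
    if w_spatial < 0 or w_mnn < 0:
        raise ValueError("edge weights must be non-negative")
    s_src, s_dst = spatial_edges
    m_src, m_dst = mnn_edges
    parts = []
    if w_spatial > 0 and len(s_src):
        parts.append((s_src, s_dst, w_spatial, "spatial"))
    if w_mnn > 0 and len(m_src):
        parts.append((m_src, m_dst, w_mnn, "mnn"))
    if parts:
        src = np.concatenate([p[0] for p in parts])
        dst = np.concatenate([p[1] for p in parts])
        weight = np.concatenate([np.full(len(p[0]), float(p[2])) for p in parts])
        kind = np.concatenate([np.full(len(p[0]), p[3]) for p in parts])
    else:
        src = dst = np.array([], dtype=int)
        weight = np.array([])
        kind = np.array([], dtype="<U7")
    if n_cells is None:
        n_cells = int(max(src.max(initial=-1), dst.max(initial=-1)) + 1)
    return CellGraph(src=src, dst=dst, weight=weight, kind=kind, n_cells=n_cells)


def build_cell_graph(dataset, k: int = 15, w_spatial: float = 1.0,
                     w_mnn: float = 1.0, n_pcs: int = 30) -> CellGraph:
    """Combined graph for a dataset: spatial kNN + (if multi-batch) OT-MNN edges.

    Expression for the OT cost uses spliced logcounts (the ``spliced`` layer
    at normalised/scaled stages).
    """
    import scipy.sparse as sp

    codes = np.asarray(dataset.batch.codes)
    spatial = spatial_knn_edges(dataset.X, codes, k=k) if w_spatial > 0 else (
        np.array([], dtype=int), np.array([], dtype=int))
    if len(np.unique(codes)) >= 2 and w_mnn > 0:
        S = dataset.S
        S = np.asarray(S.todense()) if sp.issparse(S) else np.asarray(S, dtype=float)
        mnn = ot_mnn_edges(S, codes, k=k, n_pcs=n_pcs)
    else:
        mnn = (np.array([], dtype=int), np.array([], dtype=int))
    return combine_graph(spatial, mnn, w_spatial=w_spatial, w_mnn=w_mnn,
                         n_cells=dataset.n_cells)
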