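"""Spatial ligand-receptor communication scores and their time derivative.

The cell-level interaction score between a sender i and receiver j for a
ligand-receptor pair (l, r) is the co-expression gated by spatial proximity,

    LRscore(i, j) = S_il * S_jr * 1{d_ij < q},

with d the Euclidean distance between the cells' spatial positions and q a
distance threshold (default 30, platform units). Cell-type-level scores sum
the cell-level scores over all (sender-type, receiver-type) cell pairs;
significance comes from permuting the cell-type labels and
Benjamini-Hochberg correction across type pairs.

The temporal score is the exact time derivative of LRscore under the
inferred velocity (product rule):

    LRvelo(i, j) = (S_il * V_jr + V_il * S_jr) * 1{d_ij < q}.

Per-cell sender/receiver communication rates are its row and column sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial import cKDTree
from statsmodels.stats.multitest import multipletests

__all__ = [
    "LRPair",
    "lrscore_cells",
    "lrscore_celltypes",
    "permutation_fdr",
    "lrvelo",
]


@dataclass
class LRPair:
    ligand: str
    receptor: str
    distance_threshold: float = 30.0


def _gene_column(M, gene_names, gene: str) -> np.ndarray:
    names = list(gene_names)
    if gene not in names:
        raise KeyError(f"gene {gene!r} not present in the dataset")
    col = names.index(gene)
    M = np.asarray(M.todense()) if sp.issparse(M) else np.asarray(M, dtype=float)
    return M[:, col]


def _proximity_pairs(X: np.ndarray, q: float):
    """Ordered cell pairs (i, j), i != j, with d_ij strictly below q."""
    tree = cKDTree(np.asarray(X, dtype=float))
    pairs = tree.query_pairs(q, output_type="ndarray")  # unordered, d <= q
    if len(pairs) == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    d = np.linalg.norm(X[pairs[:, 0]] - X[pairs[:, 1]], axis=1)
    pairs = pairs[d < q]  # strict inequality
    i = np.concatenate([pairs[:, 0], pairs[:, 1]])
    j = np.concatenate([pairs[:, 1], pairs[:, 0]])
    return i, j


def lrscore_cells(S, X, pair: LRPair, gene_names) -> sp.coo_matrix:
    """Sparse cell x cell LRscore matrix (sender rows, receiver columns)."""
    lig = _gene_column(S, gene_names, pair.ligand)
    rec = _gene_column(S, gene_names, pair.receptor)
    i, j = _proximity_pairs(X, pair.distance_threshold)
    vals = lig[i] * rec[j]
    n = len(lig)
    return sp.coo_matrix((vals, (i, j)), shape=(n, n))


def _aggregate_by_type(M: sp.spmatrix, labels: np.ndarray, types) -> np.ndarray:
    """types x types sums of the cell-level matrix: I_A^T M I_B."""
    codes = np.searchsorted(types, labels)
    n = M.shape[0]
    onehot = sp.csr_matrix(
        (np.ones(n), (np.arange(n), codes)), shape=(n, len(types)))
    return np.asarray((onehot.T @ M @ onehot).todense())


def lrscore_celltypes(S, X, labels, pair: LRPair, gene_names,
                      _cells_matrix=None) -> pd.DataFrame:
    """Cell-type x cell-type LRscore: sum of cell-level scores over C_A x C_B."""
    M = (_cells_matrix if _cells_matrix is not None
         else lrscore_cells(S, X, pair, gene_names)).tocsr()
    labels = np.asarray(labels)
    types = np.unique(labels)
    return pd.DataFrame(_aggregate_by_type(M, labels, types),
                        index=types, columns=types)


def permutation_fdr(S, X, labels, pair: LRPair, gene_names, n_perm: int = 50,
                    seed: int = 0) -> pd.DataFrame:
    """Permutation p-values and BH q-values per cell-type pair.

    The empirical p-value is the smoothed exceedance fraction
    (1 + #{permuted >= observed}) / (1 + n_perm) under random relabelling
    of cells; q-values are Benjamini-Hochberg across all type pairs.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = np.asarray(labels)
    types = np.unique(labels)
    if len(types) < 2:
        raise ValueError("permutation test needs at least 2 cell types")
    M = lrscore_cells(S, X, pair, gene_names).tocsr()
    observed = _aggregate_by_type(M, labels, types)
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(observed, dtype=int)
    for _ in range(n_perm):
        perm = _aggregate_by_type(M, rng.permutation(labels), types)
        exceed += (perm >= observed).astype(int)
    p = (1 + exceed) / (1 + n_perm)
    q = multipletests(p.ravel(), method="fdr_bh")[1].reshape(p.shape)
    rows = []
    for ia, a in enumerate(types):
        for ib, b in enumerate(types):
            rows.append({"sender": a, "receiver": b,
                         "score": observed[ia, ib],
                         "p_value": p[ia, ib], "q_value": q[ia, ib]})
    return pd.DataFrame(rows)


def lrvelo(S, V, X, pair: LRPair, gene_names):
    """Temporal communication scores and per-cell sender/receiver rates.

    Returns (sparse cell x cell LRvelo matrix, DataFrame with per-cell
    ``sender_rate`` (row sums) and ``receiver_rate`` (column sums)).
    """
    lig_s = _gene_column(S, gene_names, pair.ligand)
    rec_s = _gene_column(S, gene_names, pair.receptor)
    lig_v = _gene_column(V, gene_names, pair.ligand)
    rec_v = _gene_column(V, gene_names, pair.receptor)
    i, j = _proximity_pairs(X, pair.distance_threshold)
    vals = lig_s[i] * rec_v[j] + lig_v[i] * rec_s[j]
    n = len(lig_s)
    M = sp.coo_matrix((vals, (i, j)), shape=(n, n))
    rates = pd.DataFrame({
        "sender_rate": np.asarray(M.sum(axis=1)).ravel(),
        "receiver_rate": np.asarray(M.sum(axis=0)).ravel(),
    })
    return M, rates
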