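"""Velocity evaluation suite.

All scores operate on local neighbourhoods of "boundary cells": for an
ordered cell-type pair (A, B), the boundary set C_{A->B} holds the A-cells
with at least one B-cell among their neighbours. Three neighbourhood graphs
are supported — expression kNN (on PCA of spliced logcounts), within-batch
spatial kNN, and cross-batch OT-MNN — mirroring the three views the model
integrates.

* confidence — mean cosine similarity between a boundary cell's velocity and
  its B-neighbours' velocities (velocity consistency);
* transition — mean row-normalised transition probability towards the
  B-neighbours, where the unnormalised probability from c to c' is
  exp(cos(S_c' - S_c, V_c) / sigma) (does expression displacement match
  predicted change);
* direction — mean cosine between the PCA displacement towards B-neighbours
  and the transition-probability-weighted velocity embedding
  v~_c = sum_{c'!=c} (pi~_cc' - 1/n) (x_c' - x_c)/||x_c' - x_c||;
* coherence — cosine agreement of MNN-averaged velocities across batch
  pairs, averaged over randomly sampled cells (batch-correction quality).

Aggregation over a ground-truth transition list: confidence averages the
correct pairs; transition and direction average the correct-pair scores
together with the negated scores of the incorrect (reversed) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "TransitionGroundTruth",
    "ScoreReport",
    "boundary_cells",
    "confidence_score",
    "transition_matrix",
    "transition_score",
    "direction_score",
    "coherence_score",
    "aggregate_scores",
    "neighbor_sets",
    "score_dataset",
]


@dataclass
class TransitionGroundTruth:
    """Ordered (source, target) cell-type pairs with known transitions."""

    pairs: list

    def __post_init__(self):
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicate transition pairs")

    def incorrect_pairs(self):
        """Reversed pairs serve as the incorrect transitions."""
        return [(b, a) for (a, b) in self.pairs]


@dataclass
class ScoreReport:
    per_pair: dict = field(default_factory=dict)   # (graph, A, B) -> scores dict
    aggregated: dict = field(default_factory=dict)  # graph -> {confidence, transition, direction}
    coherence: float | None = None


def _cosine(a, b):
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return np.nan
    return float(a @ b / (na * nb))


def neighbor_sets(idx_matrix: np.ndarray) -> list:
    """Neighbour index rows (excluding self if present in column 0)."""
    out = []
    for i, row in enumerate(idx_matrix):
        out.append(np.asarray([j for j in row if j != i]))
    return out


def knn_neighbor_sets(X: np.ndarray, n_neighbors: int = 30) -> list:
    nn = NearestNeighbors(n_neighbors=min(n_neighbors + 1, len(X)))
    nn.fit(X)
    _, idx = nn.kneighbors(X)
    return neighbor_sets(idx)


def _check_labels(labels, *names):
    cats = set(np.asarray(labels))
    for n in names:
        if n not in cats:
            raise ValueError(f"unknown cell type label {n!r}")


def boundary_cells(labels, neighbors: list, A: str, B: str) -> np.ndarray:
    """C_{A->B}: indices of A-cells with at least one B-neighbour."""
    _check_labels(labels, A, B)
    labels = np.asarray(labels)
    out = [c for c in np.flatnonzero(labels == A)
           if np.any(labels[neighbors[c]] == B)]
    return np.asarray(out, dtype=int)


def confidence_score(V, neighbors: list, labels, A: str, B: str):
    """Mean over C_{A->B} of mean cosine(V_c, V_c') over B-neighbours c'."""
    V = np.asarray(V, dtype=float)
    labels = np.asarray(labels)
    cells = boundary_cells(labels, neighbors, A, B)
    if len(cells) == 0:
        return np.nan
    vals = []
    for c in cells:
        nb = neighbors[c][labels[neighbors[c]] == B]
        cos = [_cosine(V[c], V[j]) for j in nb]
        cos = [x for x in cos if np.isfinite(x)]
        if cos:
            vals.append(np.mean(cos))
    return float(np.mean(vals)) if vals else np.nan


def transition_matrix(V, S, sigma: float = 0.1, restrict: list | None = None
                      ) -> np.ndarray:
    """Row-normalised transition probabilities pi~ from the velocity graph.

    pi_cc' = cos(S_c' - S_c, V_c); pi~ row-normalises exp(pi / sigma) over
    c' != c (zero-displacement pairs are skipped). ``restrict`` optionally
    limits the normalisation to each cell's neighbour set.
    """
    V = np.asarray(V, dtype=float)
    S = np.asarray(S, dtype=float)
    n = len(S)
    P = np.zeros((n, n))
    for c in range(n):
        disp = S - S[c]
        nrm = np.linalg.norm(disp, axis=1)
        vn = np.linalg.norm(V[c])
        cos = np.zeros(n)
        valid = (nrm > 0) & (vn > 0)
        valid[c] = False
        if restrict is not None:
            mask = np.zeros(n, dtype=bool)
            mask[restrict[c]] = True
            valid &= mask
        cos[valid] = disp[valid] @ V[c] / (nrm[valid] * vn)
        w = np.zeros(n)
        w[valid] = np.exp(cos[valid] / sigma)
        z = w.sum()
        if z > 0:
            P[c] = w / z
    return P


def transition_score(V, S, neighbors: list, labels, A: str, B: str,
                     sigma: float = 0.1, tilde_pi: np.ndarray | None = None):
    """Mean over C_{A->B} of mean pi~ towards B-neighbours."""
    labels = np.asarray(labels)
    cells = boundary_cells(labels, neighbors, A, B)
    if len(cells) == 0:
        return np.nan
    if tilde_pi is None:
        tilde_pi = transition_matrix(V, S, sigma=sigma)
    vals = []
    for c in cells:
        nb = neighbors[c][labels[neighbors[c]] == B]
        if len(nb):
            vals.append(tilde_pi[c, nb].mean())
    return float(np.mean(vals)) if vals else np.nan


def velocity_embedding(tilde_pi: np.ndarray, X_emb: np.ndarray) -> np.ndarray:
    """Project velocity into the embedding: v~_c = sum (pi~ - 1/n) unit-displacement."""
    X_emb = np.asarray(X_emb, dtype=float)
    n = len(X_emb)
    Vt = np.zeros_like(X_emb)
    for c in range(n):
        disp = X_emb - X_emb[c]
        nrm = np.linalg.norm(disp, axis=1)
        ok = nrm > 0
        ok[c] = False
        unit = np.zeros_like(disp)
        unit[ok] = disp[ok] / nrm[ok, None]
        w = tilde_pi[c] - 1.0 / n
        w[c] = 0.0
        Vt[c] = w @ unit
    return Vt


def direction_score(V, S, X_emb, neighbors: list, labels, A: str, B: str,
                    sigma: float = 0.1, tilde_pi: np.ndarray | None = None):
    """Mean cosine between embedding displacement to B-neighbours and v~_c.

    Cells with a (numerically) zero projected velocity contribute 0.
    """
    labels = np.asarray(labels)
    cells = boundary_cells(labels, neighbors, A, B)
    if len(cells) == 0:
        return np.nan
    if tilde_pi is None:
        tilde_pi = transition_matrix(V, S, sigma=sigma)
    Vt = velocity_embedding(tilde_pi, X_emb)
    X_emb = np.asarray(X_emb, dtype=float)
    vals = []
    for c in cells:
        nb = neighbors[c][labels[neighbors[c]] == B]
        if not len(nb):
            continue
        if np.linalg.norm(Vt[c]) < 1e-12:
            vals.append(0.0)
            continue
        cos = [_cosine(X_emb[j] - X_emb[c], Vt[c]) for j in nb]
        cos = [x for x in cos if np.isfinite(x)]
        if cos:
            vals.append(np.mean(cos))
    return float(np.mean(vals)) if vals else np.nan


def coherence_score(V, batch, mnn_neighbors: list, n_cells: int = 100,
                    seed: int = 0):
    """Cross-batch velocity coherence via MNN-averaged velocities.

    For each sampled cell, average over batch pairs of the cosine between
    the mean velocity of its MNNs in each batch; batches where the cell has
    no MNN are skipped. Since MNN edges are cross-batch, the cell itself
    represents its own batch (its neighbourhood is taken to include it), so
    with two batches the score compares each cell's velocity with the MNN
    average in the other batch.
    """
    V = np.asarray(V, dtype=float)
    batch = np.asarray(batch)
    levels = np.unique(batch)
    if len(levels) < 2:
        raise ValueError("coherence requires at least 2 batches")
    rng = np.random.default_rng(seed)
    n = len(V)
    cells = rng.choice(n, size=min(n_cells, n), replace=False)
    scores = []
    for c in cells:
        nb = np.append(np.asarray(mnn_neighbors[c], dtype=int), c)
        vb = {}
        for b in levels:
            sel = nb[batch[nb] == b] if len(nb) else np.array([], dtype=int)
            if len(sel):
                vb[b] = V[sel].mean(axis=0)
        keys = list(vb)
        pair_cos = []
        for i1 in range(len(keys)):
            for i2 in range(len(keys)):
                if i1 == i2:
                    continue
                cc = _cosine(vb[keys[i1]], vb[keys[i2]])
                if np.isfinite(cc):
                    pair_cos.append(cc)
        if pair_cos:
            scores.append(np.mean(pair_cos))
    return float(np.mean(scores)) if scores else np.nan


def aggregate_scores(correct: dict, incorrect: dict) -> dict:
    """Aggregate per-pair scores against the transition ground truth.

    ``correct``/``incorrect`` map pair -> {score_name: value}. Confidence
    averages correct pairs only; transition and direction average correct
    scores together with negated incorrect scores. Missing (NaN) pairs are
    dropped; aggregation fails if no correct pair is evaluable.
    """
    out = {}
    for name in ("confidence", "transition", "direction"):
        good = [v[name] for v in correct.values()
                if name in v and np.isfinite(v[name])]
        if not good:
            raise ValueError(f"no correct pair evaluable for {name!r}")
        if name == "confidence":
            out[name] = float(np.mean(good))
        else:
            bad = [-v[name] for v in incorrect.values()
                   if name in v and np.isfinite(v[name])]
            out[name] = float(np.mean(good + bad))
    return out


def format_score_table(method_scores: dict) -> "object":
    """Optional reporting helper: min-max scale scores across methods.

    ``method_scores`` maps method name -> {score name: value}; each score
    column is mapped to [0, 1] across methods (a presentation convention
    for cross-method dotplots; constant columns map to 0).
    """
    import pandas as pd

    df = pd.DataFrame(method_scores).T
    rng_ = df.max() - df.min()
    return (df - df.min()) / rng_.where(rng_ > 0, 1.0)


def _mnn_neighbor_sets(dataset, n_neighbors: int):
    from .graphs import ot_mnn_edges

    S = dataset.S
    S = np.asarray(S.todense()) if sp.issparse(S) else np.asarray(S, dtype=float)
    src, dst = ot_mnn_edges(S, np.asarray(dataset.batch.codes), k=n_neighbors)
    sets = [[] for _ in range(dataset.n_cells)]
    for a, b in zip(src, dst):
        sets[a].append(b)
    return [np.asarray(s, dtype=int) for s in sets]


def score_dataset(dataset, V, transition_pairs, n_neighbors: int = 30,
                  n_pcs: int = 30, sigma: float = 0.1, seed: int = 0,
                  graphs=("expression", "spatial", "mnn")) -> ScoreReport:
    """Full score report for a dataset with cell-type labels.

    Computes per-pair confidence/transition/direction on each requested
    neighbourhood graph, aggregates against the transition ground truth, and
    (for multi-batch data) the velocity coherence on the MNN graph.
    """
    labels = np.asarray(dataset.cell_type)
    if dataset.cell_type is None:
        raise ValueError("score_dataset requires cell_type labels")
    S = dataset.S
    S = np.asarray(S.todense()) if sp.issparse(S) else np.asarray(S, dtype=float)
    V = np.asarray(V, dtype=float)
    gt = TransitionGroundTruth(list(transition_pairs))

    n_comps = int(min(n_pcs, S.shape[0] - 1, S.shape[1]))
    X_pca = PCA(n_components=n_comps, random_state=0).fit_transform(S)
    tilde_pi = transition_matrix(V, S, sigma=sigma)

    sets = {}
    if "expression" in graphs:
        sets["expression"] = knn_neighbor_sets(X_pca, n_neighbors)
    if "spatial" in graphs:
        codes = np.asarray(dataset.batch.codes)
        spatial = [None] * dataset.n_cells
        for b in np.unique(codes):
            idx = np.flatnonzero(codes == b)
            kk = min(n_neighbors + 1, len(idx))
            nn = NearestNeighbors(n_neighbors=kk).fit(dataset.X[idx])
            _, loc = nn.kneighbors(dataset.X[idx])
            for row_i, gcell in enumerate(idx):
                spatial[gcell] = idx[[j for j in loc[row_i] if idx[j] != gcell]]
        sets["spatial"] = spatial
    mnn_sets = None
    if ("mnn" in graphs or len(dataset.batch.categories) > 1):
        try:
            mnn_sets = _mnn_neighbor_sets(dataset, n_neighbors)
        except ValueError:
            mnn_sets = None
    if "mnn" in graphs and mnn_sets is not None:
        sets["mnn"] = mnn_sets

    report = ScoreReport()
    for gname, nbrs in sets.items():
        correct, incorrect = {}, {}
        for pairs, store in ((gt.pairs, correct), (gt.incorrect_pairs(), incorrect)):
            for (a, b) in pairs:
                store[(a, b)] = {
                    "confidence": confidence_score(V, nbrs, labels, a, b),
                    "transition": transition_score(V, S, nbrs, labels, a, b,
                                                   sigma, tilde_pi),
                    "direction": direction_score(V, S, X_pca, nbrs, labels, a,
                                                 b, sigma, tilde_pi),
                }
        for (a, b), v in correct.items():
            report.per_pair[(gname, a, b)] = v
        report.aggregated[gname] = aggregate_scores(correct, incorrect)
    if mnn_sets is not None and len(dataset.batch.categories) > 1:
        report.coherence = coherence_score(
            V, np.asarray(dataset.batch.codes), mnn_sets, seed=seed)
    return report
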