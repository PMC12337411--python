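"""Preprocessing pipeline for spliced/unspliced expression.

Stage order (each stage validates its precondition):

1. shared-count gene filter (raw counts)
2. per-cell normalisation to the median total
3. log1p + highly-variable-gene selection (dispersion-based, on spliced)
4. PCA + kNN neighbour graph, neighbour moments (smoothed Mu/Ms)
5. per-gene min-max scaling of the moments to [0, 1]
6. steady-state-ratio / R^2 velocity-gene filter

Standard steps run through scanpy; the moment smoothing, min-max scaling and
steady-state filter are implemented here. The per-gene (min, range) of the
scaling is stored in ``var`` so velocities can be mapped back to data units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.neighbors import NearestNeighbors

from .datasets import SpatialVeloDataset

__all__ = [
    "PreprocessConfig",
    "VelocityPreprocessor",
    "filter_genes_shared_counts",
    "normalize_to_median",
    "log_and_hvg",
    "neighbors_and_moments",
    "minmax_scale",
    "steady_state_gene_filter",
    "preprocess",
]


@dataclass
class PreprocessConfig:
    min_shared_counts: int = 20
    n_hvg: int = 2000
    n_neighbors: int = 30
    n_pcs: int = 30
    r2_threshold: float = 0.2

    def __post_init__(self):
        if min(self.min_shared_counts, self.n_hvg, self.n_neighbors, self.n_pcs) < 0:
            raise ValueError("all config values must be positive")
        if not 0.0 <= self.r2_threshold < 1.0:
            raise ValueError("r2_threshold must lie in [0, 1)")


def _dense(M) -> np.ndarray:
    return np.asarray(M.todense()) if sp.issparse(M) else np.asarray(M, dtype=float)


def filter_genes_shared_counts(d: SpatialVeloDataset, min_shared_counts: int = 20
                               ) -> SpatialVeloDataset:
    """Keep genes whose summed min(spliced, unspliced) count reaches the threshold.

    "Shared" counts follow the min-of-the-pair semantics: a cell contributes
    min(S_ng, U_ng) to gene g, i.e. only expression seen in both species
    counts.
    """
    if d.stage != "raw":
        raise ValueError("shared-count filter applies to raw counts")
    S, U = _dense(d.S), _dense(d.U)
    shared = np.minimum(S, U).sum(axis=0)
    mask = shared >= min_shared_counts
    if not mask.any():
        raise ValueError(
            f"no gene reaches {min_shared_counts} shared counts; lower the threshold"
        )
    out = d.adata[:, mask].copy()
    return SpatialVeloDataset(out, stage="raw")


def normalize_to_median(d: SpatialVeloDataset) -> SpatialVeloDataset:
    """Scale each cell so its spliced (resp. unspliced) total equals the median total."""
    if d.stage != "raw":
        raise ValueError("normalisation applies to raw counts")
    ad = d.adata.copy()
    for layer in ("spliced", "unspliced"):
        M = _dense(ad.layers[layer])
        totals = M.sum(axis=1)
        zero = np.flatnonzero(totals == 0)
        if zero.size:
            raise ValueError(
                f"cells with zero total {layer} counts cannot be normalised: "
                f"{zero[:10].tolist()}{'...' if zero.size > 10 else ''}"
            )
        ad.layers[layer] = M * (np.median(totals) / totals)[:, None]
    out = SpatialVeloDataset(ad, stage="raw")
    out.stage = "normalized"
    return out


def log_and_hvg(d: SpatialVeloDataset, n_hvg: int = 2000) -> SpatialVeloDataset:
    """log1p-transform both layers and keep the top dispersion-ranked HVGs (spliced)."""
    if d.stage != "normalized":
        raise ValueError("log/HVG apply to normalised data")
    ad = d.adata.copy()
    for layer in ("spliced", "unspliced"):
        ad.layers[layer] = np.log1p(_dense(ad.layers[layer]))
    ad.X = ad.layers["spliced"].copy()
    if ad.n_vars > n_hvg:
        sc.pp.highly_variable_genes(ad, n_top_genes=n_hvg, flavor="seurat")
        ad = ad[:, ad.var["highly_variable"].to_numpy()].copy()
    out = SpatialVeloDataset(ad, stage="raw")
    out.stage = "normalized"
    return out


def neighbors_and_moments(d: SpatialVeloDataset, n_neighbors: int = 30,
                          n_pcs: int = 30, second_order: bool = False
                          ) -> SpatialVeloDataset:
    """kNN graph on PCA of spliced logcounts; first (and optionally second) moments.

    Each cell's Mu/Ms row is the mean of itself and its ``n_neighbors``
    nearest neighbours; second moments are uncentred (E[x^2]) over the same
    set and stored as ``Mu2``/``Ms2`` on request.
    """
    if d.stage != "normalized":
        raise ValueError("moments require log-normalised data")
    if n_neighbors >= d.n_cells:
        raise ValueError(f"n_neighbors={n_neighbors} must be < n_cells={d.n_cells}")
    from sklearn.decomposition import PCA

    ad = d.adata.copy()
    ad.X = _dense(ad.layers["spliced"])
    n_comps = int(max(1, min(n_pcs, ad.n_obs - 1, ad.n_vars - 1)))
    ad.obsm["X_pca"] = PCA(n_components=n_comps, random_state=0).fit_transform(ad.X)
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1)
    nn.fit(ad.obsm["X_pca"])
    _, idx = nn.kneighbors(ad.obsm["X_pca"])  # includes self in column 0
    ad.obsm["neighbor_indices"] = idx
    for layer, mom in (("unspliced", "Mu"), ("spliced", "Ms")):
        M = _dense(ad.layers[layer])
        ad.layers[mom] = M[idx].mean(axis=1)
        if second_order:
            ad.layers[mom + "2"] = (M[idx] ** 2).mean(axis=1)
    out = SpatialVeloDataset(ad, stage="raw")
    out.stage = "normalized"
    return out


def minmax_scale(d: SpatialVeloDataset) -> SpatialVeloDataset:
    """Map each gene's Mu/Ms column to [0, 1]; constant columns map to 0.

    Stores per-gene (min, range) in ``var`` for the inverse mapping.
    """
    ad = d.adata.copy()
    if "Mu" not in ad.layers or "Ms" not in ad.layers:
        raise ValueError("min-max scaling requires neighbour moments (Mu/Ms)")
    for mom, tag in (("Mu", "u"), ("Ms", "s")):
        M = np.asarray(ad.layers[mom], dtype=float)
        lo, hi = M.min(axis=0), M.max(axis=0)
        rng_ = hi - lo
        safe = np.where(rng_ > 0, rng_, 1.0)
        ad.layers[mom + "_scaled"] = np.where(rng_ > 0, (M - lo) / safe, 0.0)
        ad.var[f"{tag}_min"] = lo
        ad.var[f"{tag}_range"] = np.where(rng_ > 0, rng_, 1.0)
        # gene-wise dynamic range on the de-logged (linear) scale, for
        # mapping fitted rates back to data units
        E = np.expm1(M)
        lin = E.max(axis=0) - E.min(axis=0)
        ad.var[f"{tag}_range_linear"] = np.where(lin > 0, lin, 1.0)
    out = SpatialVeloDataset(ad, stage="raw")
    out.stage = "scaled"
    return out


def steady_state_gene_filter(d: SpatialVeloDataset, r2_threshold: float = 0.2,
                             quantile: float = 0.05):
    """Velocity-gene filter from the steady-state model.

    Per gene, cells in the union of the top and bottom ``quantile`` of
    u + s are assumed near steady state; a least-squares line through the
    origin, u ~ ratio * s, is fitted on them. R^2 of that line is evaluated
    on all cells (evaluating it on the selected cells only would reward any
    gene whose u and s merely co-vary with the total). Genes with positive
    steady-state ratio and R^2 >= ``r2_threshold`` are retained.

    Returns
    -------
    mask : boolean array (n_genes,)
    table : DataFrame with per-gene ``steady_state_ratio`` and ``r2``.
    """
    if d.stage != "scaled":
        raise ValueError("steady-state filter requires min-max scaled moments")
    Mu = np.asarray(d.adata.layers["Mu_scaled"], dtype=float)
    Ms = np.asarray(d.adata.layers["Ms_scaled"], dtype=float)
    n, G = Mu.shape
    ratios = np.zeros(G)
    r2 = np.zeros(G)
    for g in range(G):
        u, s = Mu[:, g], Ms[:, g]
        tot = u + s
        lo, hi = np.quantile(tot, quantile), np.quantile(tot, 1.0 - quantile)
        sel = (tot <= lo) | (tot >= hi)
        us, ss = u[sel], s[sel]
        denom = (ss**2).sum()
        ratios[g] = (us * ss).sum() / denom if denom > 0 else 0.0
        resid = u - ratios[g] * s
        sstot = ((u - u.mean()) ** 2).sum()
        r2[g] = 1.0 - resid @ resid / sstot if sstot > 0 else 0.0
    mask = (ratios > 0) & (r2 >= r2_threshold)
    if not mask.any():
        raise ValueError(
            "steady-state filter removed every gene; consider lowering r2_threshold"
        )
    table = pd.DataFrame(
        {"steady_state_ratio": ratios, "r2": r2, "velocity_gene": mask},
        index=d.adata.var_names,
    )
    return mask, table


class VelocityPreprocessor(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer running the full preprocessing pipeline.

    ``fit_transform`` takes a raw :class:`SpatialVeloDataset` and returns a
    scaled dataset restricted to velocity genes, with ``Mu_scaled``/
    ``Ms_scaled`` layers, the PCA embedding, the neighbour index matrix and
    the per-gene steady-state table (``var``).
    """

    def __init__(self, min_shared_counts: int = 20, n_hvg: int = 2000,
                 n_neighbors: int = 30, n_pcs: int = 30,
                 r2_threshold: float = 0.2):
        self.min_shared_counts = min_shared_counts
        self.n_hvg = n_hvg
        self.n_neighbors = n_neighbors
        self.n_pcs = n_pcs
        self.r2_threshold = r2_threshold

    def fit(self, d: SpatialVeloDataset, y=None):
        self.fit_transform(d)
        return self

    def fit_transform(self, d: SpatialVeloDataset, y=None) -> SpatialVeloDataset:
        d = filter_genes_shared_counts(d, self.min_shared_counts)
        d = normalize_to_median(d)
        d = log_and_hvg(d, self.n_hvg)
        d = neighbors_and_moments(d, self.n_neighbors, self.n_pcs)
        d = minmax_scale(d)
        mask, table = steady_state_gene_filter(d, self.r2_threshold)
        ad = d.adata[:, mask].copy()
        ad.var = ad.var.join(table.loc[mask, ["steady_state_ratio", "r2"]])
        out = SpatialVeloDataset(ad, stage="raw")
        out.stage = "scaled"
        self.gene_mask_ = mask
        self.steady_state_table_ = table
        self.n_velocity_genes_ = int(mask.sum())
        return out

    def transform(self, d: SpatialVeloDataset) -> SpatialVeloDataset:
        return self.fit_transform(d)


def preprocess(d: SpatialVeloDataset, config: PreprocessConfig | None = None
               ) -> SpatialVeloDataset:
    """Functional wrapper over :class:`VelocityPreprocessor`."""
    config = config or PreprocessConfig()
    return VelocityPreprocessor(
        min_shared_counts=config.min_shared_counts,
        n_hvg=config.n_hvg,
        n_neighbors=config.n_neighbors,
        n_pcs=config.n_pcs,
        r2_threshold=config.r2_threshold,
    ).fit_transform(d)
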