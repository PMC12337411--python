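"""Dataset container and h5ad I/O.

The pipeline's universal input is a cell x gene spliced/unspliced pair with
2-D spatial coordinates and batch labels. On disk this is an AnnData h5ad
file with layers ``"spliced"`` and ``"unspliced"``, ``obsm["spatial"]`` and
``obs["batch"]`` (optional ``obs["cell_type"]``), interoperable with the
scVelo-style ecosystem. In memory, :class:`SpatialVeloDataset` wraps an
:class:`anndata.AnnData` and validates the contract.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData, read_h5ad

__all__ = ["SpatialVeloDataset", "read_dataset", "write_dataset"]

_STAGES = ("raw", "normalized", "scaled")


class SpatialVeloDataset:
    """Validated view over an AnnData with spliced/unspliced layers.

    Parameters
    ----------
    adata
        AnnData with layers ``spliced`` and ``unspliced``, ``obsm['spatial']``
        (n_obs x 2) and categorical ``obs['batch']``; ``obs['cell_type']`` is
        optional.
    stage
        Processing stage; entries of both layers must be finite, and
        non-negative at stage ``"raw"``.
    """

    def __init__(self, adata: AnnData, stage: str = "raw"):
        if stage not in _STAGES:
            raise ValueError(f"stage must be one of {_STAGES}, got {stage!r}")
        self.adata = adata
        adata.uns["stage"] = stage
        self._validate()

    # ------------------------------------------------------------------ fields
    @property
    def S(self):
        return self.adata.layers["spliced"]

    @property
    def U(self):
        return self.adata.layers["unspliced"]

    @property
    def X(self) -> np.ndarray:
        return np.asarray(self.adata.obsm["spatial"])

    @property
    def batch(self) -> pd.Categorical:
        return pd.Categorical(self.adata.obs["batch"])

    @property
    def cell_type(self) -> Optional[pd.Categorical]:
        if "cell_type" not in self.adata.obs:
            return None
        return pd.Categorical(self.adata.obs["cell_type"])

    @property
    def gene_names(self) -> np.ndarray:
        return self.adata.var_names.to_numpy()

    @property
    def stage(self) -> str:
        return str(self.adata.uns["stage"])

    @stage.setter
    def stage(self, value: str):
        if value not in _STAGES:
            raise ValueError(f"stage must be one of {_STAGES}")
        self.adata.uns["stage"] = value

    @property
    def n_cells(self) -> int:
        return self.adata.n_obs

    @property
    def n_genes(self) -> int:
        return self.adata.n_vars

    def __repr__(self):
        ct = "present" if self.cell_type is not None else "absent"
        return (
            f"SpatialVeloDataset({self.n_cells} cells x {self.n_genes} genes, "
            f"{len(self.batch.categories)} batch(es), cell_type {ct}, stage={self.stage})"
        )

    # -------------------------------------------------------------- validation
    def _validate(self):
        ad = self.adata
        for layer in ("spliced", "unspliced"):
            if layer not in ad.layers:
                raise KeyError(f"missing required layer {layer!r}")
        if "spatial" not in ad.obsm:
            raise KeyError("missing required obsm key 'spatial'")
        if "batch" not in ad.obs:
            raise KeyError("missing required obs column 'batch'")
        S, U = ad.layers["spliced"], ad.layers["unspliced"]
        if S.shape != U.shape or S.shape != ad.shape:
            raise ValueError(
                f"layer shapes disagree: spliced {S.shape}, unspliced {U.shape}, "
                f"AnnData {ad.shape}"
            )
        Xs = np.asarray(ad.obsm["spatial"])
        if Xs.ndim != 2 or Xs.shape != (ad.n_obs, 2):
            raise ValueError(f"obsm['spatial'] must be (n_obs, 2), got {Xs.shape}")
        for name, M in (("spliced", S), ("unspliced", U)):
            dat = M.data if sp.issparse(M) else np.asarray(M)
            if not np.all(np.isfinite(dat)):
                raise ValueError(f"layer {name!r} contains non-finite entries")
            if self.stage == "raw" and dat.size and dat.min() < 0:
                raise ValueError(f"layer {name!r} has negative entries at stage 'raw'")
        if len(pd.Categorical(ad.obs["batch"]).categories) < 1:
            raise ValueError("batch must have at least one level")

    def require_multibatch(self):
        if len(self.batch.categories) < 2:
            raise ValueError("this operation requires at least 2 batches")

    def copy(self) -> "SpatialVeloDataset":
        return SpatialVeloDataset(self.adata.copy(), stage=self.stage)


def read_dataset(path, dialect: str = "h5ad") -> SpatialVeloDataset:
    """Load a dataset from an h5ad file, validating the layout contract."""
    if dialect != "h5ad":
        raise ValueError(f"unsupported dialect {dialect!r}; only 'h5ad' is implemented")
    adata = read_h5ad(path)
    stage = str(adata.uns.get("stage", "raw"))
    return SpatialVeloDataset(adata, stage=stage)


def write_dataset(d: SpatialVeloDataset, path) -> None:
    """Write the dataset to h5ad; round-trips through :func:`read_dataset`."""
    d.adata.write_h5ad(path)
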