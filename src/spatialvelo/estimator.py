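"""Scikit-learn style estimator wrapping the full velocity model.

``SpatialVelocityModel`` composes graph construction, variational training
and posterior summarisation behind fit/predict/transform so it can be used
with sklearn tooling (``get_params``/``set_params``, cloning, pipelines
operating on preprocessed datasets).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import posterior as post
from .graphs import CellGraph, build_cell_graph
from .model import VelocityNetworks
from .train import FitResult, TrainConfig, fit

__all__ = ["SpatialVelocityModel"]


class SpatialVelocityModel(BaseEstimator):
    """RNA velocity for multi-batch spatial data via a graph-attention VAE.

    Parameters
    ----------
    d_latent, hidden, heads
        Latent dimension (default 10), encoder width and attention heads.
    n_graph_neighbors, w_spatial, w_mnn
        Combined-graph construction: spatial kNN size and per-kind edge
        weights (set ``w_mnn=0`` or ``w_spatial=0`` for the ablations).
    lambda_penalty
        Weight of both the switch and the inter-batch MMD penalties
        (default 2); ``lambda_switch``/``lambda_mmd`` override individually.
    epochs, learning_rate, weight_decay, batch_size, mmd_bandwidth
        Optimisation settings (Adam with weight decay; full-batch gradients,
        MMD on up to ``batch_size`` cells per batch).
    t_max
        Global kinetic time scale shared across genes (default 20).
    n_mc
        Monte-Carlo samples for posterior summaries (default 25).
    seed
        Seed for every source of randomness; fixing it fixes all outputs.

    Attributes
    ----------
    networks_ : trained parameter container
    history_ : per-epoch loss components (DataFrame)
    kinetics_ : fitted per-gene kinetic parameters (scaled space)
    graph_ : the combined cell graph used during training
    summary_ : cached :class:`~spatialvelo.posterior.PosteriorSummary`
    """

    def __init__(self, d_latent: int = 10, hidden: int = 128, heads: int = 4,
                 n_graph_neighbors: int = 15, w_spatial: float = 1.0,
                 w_mnn: float = 1.0, lambda_penalty: float = 2.0,
                 lambda_switch: float | None = None,
                 lambda_mmd: float | None = None, epochs: int = 500,
                 learning_rate: float = 1e-3, weight_decay: float = 1e-4,
                 batch_size: int = 256, mmd_bandwidth="median",
                 t_max: float = 20.0, n_mc: int = 25, seed: int = 0):
        self.d_latent = d_latent
        self.hidden = hidden
        self.heads = heads
        self.n_graph_neighbors = n_graph_neighbors
        self.w_spatial = w_spatial
        self.w_mnn = w_mnn
        self.lambda_penalty = lambda_penalty
        self.lambda_switch = lambda_switch
        self.lambda_mmd = lambda_mmd
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.mmd_bandwidth = mmd_bandwidth
        self.t_max = t_max
        self.n_mc = n_mc
        self.seed = seed

    # ------------------------------------------------------------------- fit
    def fit(self, dataset, graph: CellGraph | None = None):
        """Train on a preprocessed (scaled) dataset; builds the graph if absent."""
        if dataset.stage != "scaled":
            raise ValueError("fit expects a preprocessed dataset at stage 'scaled'")
        if graph is None:
            graph = build_cell_graph(
                dataset, k=self.n_graph_neighbors,
                w_spatial=self.w_spatial, w_mnn=self.w_mnn,
            )
        config = TrainConfig(
            lambda_penalty=self.lambda_penalty, lambda_switch=self.lambda_switch,
            lambda_mmd=self.lambda_mmd, epochs=self.epochs,
            learning_rate=self.learning_rate, weight_decay=self.weight_decay,
            batch_size=self.batch_size, seed=self.seed,
            mmd_bandwidth=self.mmd_bandwidth,
        )
        result: FitResult = fit(
            dataset, graph, config, d_latent=self.d_latent, hidden=self.hidden,
            heads=self.heads, t_max=self.t_max,
        )
        self.networks_: VelocityNetworks = result.networks
        self.history_ = result.history
        self.graph_ = graph
        self.kinetics_ = result.networks.kinetic_params()
        self.summary_ = None
        self._dataset_id = id(dataset)
        return self

    def _check_fitted(self):
        if not hasattr(self, "networks_"):
            raise RuntimeError("model is not fitted; call fit first")

    def _summary(self, dataset, graph=None):
        self._check_fitted()
        graph = graph if graph is not None else self.graph_
        if self.summary_ is None or id(dataset) != self._dataset_id:
            self.summary_ = post.posterior_summary(
                self.networks_, dataset, graph, n_mc=self.n_mc, seed=self.seed)
            self._dataset_id = id(dataset)
        return self.summary_

    # ------------------------------------------------------------ inference
    def predict(self, dataset, scale: str = "scaled") -> np.ndarray:
        """Posterior-mean velocity matrix (cells x genes)."""
        s = self._summary(dataset)
        if scale == "original":
            return s.V * dataset.adata.var["s_range"].to_numpy()
        return s.V

    def transform(self, dataset) -> np.ndarray:
        """Posterior-mean latent coordinates z (cells x d_latent)."""
        self._check_fitted()
        import numpy as _np

        u = _np.asarray(dataset.adata.layers["Mu_scaled"], dtype=float)
        s = _np.asarray(dataset.adata.layers["Ms_scaled"], dtype=float)
        mean, _ = self.networks_.encode_expression(u, s)
        from ._autodiff import Tensor

        z_vae = Tensor(mean.data)
        z = z_vae + self.networks_.gat_encode(z_vae, self.graph_.with_self_loops())
        return z.data

    def state_probabilities(self, dataset) -> np.ndarray:
        return self._summary(dataset).pi_tilde

    def latent_time(self, dataset) -> np.ndarray:
        return self._summary(dataset).t_tilde

    def uncertainty(self, dataset) -> np.ndarray:
        self._check_fitted()
        return post.latent_uncertainty(self.networks_, dataset)

    def rate_ratio(self, dataset=None, units: str = "data") -> np.ndarray:
        """Fitted per-gene degradation/splicing ratio gamma/beta.

        ``units="scaled"`` returns the ratio in the min-max likelihood space;
        ``units="data"`` (default) maps it back to (normalised-count) data
        units. The spliced ODE reads ds/dt = beta u - gamma s, so a per-gene
        rescaling of u and s by gains g_u and g_s turns beta into
        beta * g_u / g_s while leaving gamma untouched; the likelihood space
        is reached from counts via log1p followed by min-max, and the
        per-gene gain of that chain is the gene's dynamic range on the
        linear scale (stored at scaling time), so the data-unit ratio is the
        scaled ratio times g_u / g_s with g the linear-scale ranges.
        """
        self._check_fitted()
        ratio = self.kinetics_.gamma / self.kinetics_.beta
        if units == "scaled":
            return ratio
        if units == "data":
            if dataset is None:
                raise ValueError("data-unit ratios need the dataset (stored ranges)")
            var = dataset.adata.var
            return (ratio * var["u_range_linear"].to_numpy()
                    / var["s_range_linear"].to_numpy())
        raise ValueError("units must be 'data' or 'scaled'")

    def write(self, dataset) -> None:
        """Write velocity, latent time, uncertainty and rates into the AnnData."""
        s = self._summary(dataset)
        post.write_results(dataset, s, networks=self.networks_)

    # -------------------------------------------------------------- checkpoint
    def save(self, path) -> None:
        """Single-file checkpoint: all weights plus the model configuration."""
        self._check_fitted()
        import json

        from . import __version__

        arrays = {f"param_{i}": p.data for i, p in
                  enumerate(self.networks_.params)}
        meta = {"version": __version__, "params": self.get_params(),
                "n_genes": self.networks_.n_genes}
        np.savez(path, __meta__=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path, graph: CellGraph) -> "SpatialVelocityModel":
        """Restore a fitted model from :meth:`save` (graph supplied anew)."""
        import json

        with np.load(path, allow_pickle=False) as f:
            meta = json.loads(str(f["__meta__"]))
            data = {k: f[k] for k in f.files if k.startswith("param_")}
        model = cls(**meta["params"])
        model.networks_ = VelocityNetworks(
            n_genes=meta["n_genes"], d_latent=model.d_latent,
            hidden=model.hidden, heads=model.heads, t_max=model.t_max,
            rng=np.random.default_rng(model.seed),
        )
        for i, p in enumerate(model.networks_.params):
            loaded = data[f"param_{i}"]
            if loaded.shape != p.data.shape:
                raise ValueError("checkpoint does not match the architecture")
            p.data = loaded
        model.graph_ = graph
        model.kinetics_ = model.networks_.kinetic_params()
        model.history_ = None
        model.summary_ = None
        model._dataset_id = None
        return model
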