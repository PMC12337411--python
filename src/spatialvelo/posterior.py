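"""Posterior summaries: states, latent times, velocity, uncertainty.

All summaries are Monte-Carlo expectations over the latent posterior
q(z | u, s) (``n_mc`` samples, default 25); the inner expectation over the
state simplex uses the Dirichlet mean analytically. Velocity is the
posterior mean of v = beta * u_bar(t, k) - gamma * s_bar(t, k), mixed over
states with the state probabilities; it can be reported in the min-max
scaled likelihood space (default) or mapped back to data units through the
stored per-gene ranges. Latent-state uncertainty is the differential entropy
of the Gaussian posterior, h(z) = 1/2 log((2 pi e)^d det Sigma).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import kinetics as kin
from ._autodiff import Tensor
from .model import VelocityNetworks

__all__ = [
    "PosteriorSummary",
    "infer_states",
    "infer_latent_time",
    "infer_velocity",
    "latent_uncertainty",
    "gaussian_entropy",
    "posterior_summary",
    "write_results",
]

_STATES = (kin.INDUCTION, kin.INDUCTION_SS, kin.REPRESSION, kin.REPRESSION_SS)


@dataclass
class PosteriorSummary:
    pi_tilde: np.ndarray     # (N, G, 4)
    t_tilde: np.ndarray      # (N, G)
    V: np.ndarray            # (N, G)
    entropy: np.ndarray      # (N,)
    n_mc: int


def _scaled_layers(dataset):
    ad = dataset.adata
    return (np.asarray(ad.layers["Mu_scaled"], dtype=float),
            np.asarray(ad.layers["Ms_scaled"], dtype=float))


def _mc_pass(networks: VelocityNetworks, u, s, graph, rng, sample: bool):
    mean, var = networks.encode_expression(u, s)
    if sample:
        z_vae = networks.sample_latent(mean, var, rng)
    else:
        z_vae = mean
    z = z_vae + networks.gat_encode(z_vae, graph)
    _, pi = networks.state_posterior(z)
    _, _, _, t_s, _, _ = networks.kinetic_tensors()
    times = networks.latent_time(z, t_s)
    return mean, var, pi, times


def _expected_quantities(networks, u, s, graph, n_mc, seed, sample=True):
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    rng = np.random.default_rng(seed)
    g = graph.with_self_loops()
    N, G = u.shape
    pi_acc = np.zeros((N, G, 4))
    t_acc = np.zeros((N, G))
    v_acc = np.zeros((N, G))
    mean = var = None
    for _ in range(n_mc):
        mean, var, pi, times = _mc_pass(networks, u, s, g, rng, sample)
        mu, ms, _ = networks.state_means(times)
        _, beta, gamma, t_s, _, _ = networks.kinetic_tensors()
        pi_d = pi.data
        pi_acc += pi_d
        t_mat = np.stack([
            times[kin.INDUCTION].data,
            np.broadcast_to(t_s.data, (N, G)),
            times[kin.REPRESSION].data,
            np.full((N, G), networks.t_max),
        ], axis=2)
        t_acc += (pi_d * t_mat).sum(axis=2)
        for j, k in enumerate(_STATES):
            u_k = mu[k].data if isinstance(mu[k], Tensor) else np.zeros((N, G))
            s_k = ms[k].data if isinstance(ms[k], Tensor) else np.zeros((N, G))
            v_k = beta.data * u_k - gamma.data * s_k
            v_acc += pi_d[:, :, j] * (v_k * np.ones((N, G)))
    return (pi_acc / n_mc, t_acc / n_mc, v_acc / n_mc,
            mean.data.copy(), var.data.copy())


def infer_states(networks, dataset, graph, n_mc: int = 25, seed: int = 0):
    """Posterior-mean state probabilities pi_tilde, (N, G, 4)."""
    u, s = _scaled_layers(dataset)
    pi, _, _, _, _ = _expected_quantities(networks, u, s, graph, n_mc, seed)
    return pi

def infer_latent_time(networks, dataset, graph, n_mc: int = 25, seed: int = 0):
    """Posterior-mean cell-gene latent time, mixed over states; in [0, t_max]."""
    u, s = _scaled_layers(dataset)
    _, t, _, _, _ = _expected_quantities(networks, u, s, graph, n_mc, seed)
    return t


def infer_velocity(networks, dataset, graph, n_mc: int = 25, seed: int = 0,
                   scale: str = "scaled"):
    """Posterior-mean velocity matrix (N, G).

    ``scale="scaled"`` reports in the min-max likelihood space;
    ``scale="original"`` multiplies by the stored per-gene spliced range.
    """
    if scale not in ("scaled", "original"):
        raise ValueError("scale must be 'scaled' or 'original'")
    u, s = _scaled_layers(dataset)
    _, _, V, _, _ = _expected_quantities(networks, u, s, graph, n_mc, seed)
    if scale == "original":
        V = V * dataset.adata.var["s_range"].to_numpy()
    return V


def gaussian_entropy(var: np.ndarray) -> np.ndarray:
    """Differential entropy of diagonal Gaussians: rows of per-dim variances."""
    var = np.atleast_2d(np.asarray(var, dtype=float))
    if np.any(var <= 0):
        raise ValueError("variances must be strictly positive")
    d = var.shape[1]
    return 0.5 * (d * np.log(2.0 * np.pi * np.e) + np.log(var).sum(axis=1))


def latent_uncertainty(networks, dataset, graph=None) -> np.ndarray:
    """Per-cell differential entropy of q(z_VAE | u, s)."""
    u, s = _scaled_layers(dataset)
    mean, var = networks.encode_expression(u, s)
    return gaussian_entropy(var.data)


def posterior_summary(networks, dataset, graph, n_mc: int = 25, seed: int = 0
                      ) -> PosteriorSummary:
    u, s = _scaled_layers(dataset)
    pi, t, V, mean, var = _expected_quantities(networks, u, s, graph, n_mc, seed)
    return PosteriorSummary(pi_tilde=pi, t_tilde=t, V=V,
                            entropy=gaussian_entropy(var), n_mc=n_mc)


def write_results(dataset, summary: PosteriorSummary, networks=None) -> None:
    """Write summaries back into the AnnData container."""
    ad = dataset.adata
    ad.layers["velocity"] = summary.V
    ad.layers["latent_time"] = summary.t_tilde
    ad.obs["latent_time_mean"] = summary.t_tilde.mean(axis=1)
    ad.obs["uncertainty"] = summary.entropy
    ad.obsm["state_probability_max"] = summary.pi_tilde.max(axis=2)
    if networks is not None:
        p = networks.kinetic_params()
        ad.var["fit_alpha"] = p.alpha1
        ad.var["fit_beta"] = p.beta
        ad.var["fit_gamma"] = p.gamma
        ad.var["fit_t_switch"] = p.t_switch
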