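"""Training objective and optimisation loop.

The loss is L = L_elbo + lambda * L_switch + lambda * L_batch:

* L_elbo — negative evidence lower bound: expected negative Gaussian-mixture
  log-likelihood plus KL of the latent Normal against N(0, I) plus the
  per-gene Dirichlet KL of the state posterior against Dirichlet(0.25 * 1),
  averaged per cell;
* L_switch — squared distance between the switch point (u, s at t_switch on
  the induction branch) and the per-gene median of the scaled expression,
  anchoring the switch in the phase portrait;
* L_batch — sum over unordered batch pairs of the squared maximum mean
  discrepancy (Gaussian kernel, biased V-statistic) between the batches'
  latent vectors, aligning batches in latent space.

Optimisation is Adam with weight decay on full-batch gradients (the graph
attention needs the whole graph each pass; at the supported problem sizes a
full pass is cheap). MMD uses up to ``batch_size`` cells per batch per step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._autodiff import Tensor, as_tensor, exp
from .graphs import CellGraph
from .model import VelocityNetworks

__all__ = ["TrainConfig", "FitResult", "mmd2", "switch_penalty", "fit", "Adam"]


@dataclass
class TrainConfig:
    lambda_penalty: float = 2.0
    lambda_switch: float | None = None   # defaults to lambda_penalty
    lambda_mmd: float | None = None      # defaults to lambda_penalty
    epochs: int = 2000
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    batch_size: int = 256
    seed: int = 0
    mmd_bandwidth: float | str = "median"
    grad_clip: float = 10.0
    # phase-portrait orientation warm-up: for the first ``state_warmup_frac``
    # of epochs the state posterior is pulled towards the steady-state-line
    # heuristic (cells above u = ratio * s are induction, below repression),
    # with a weight decaying linearly to zero. This breaks the mirror
    # symmetry of the mixture (swapping branches together with beta/gamma)
    # towards the physical orientation in which unspliced leads spliced.
    state_warmup_weight: float = 2.0
    state_warmup_frac: float = 0.3

    def __post_init__(self):
        if self.lambda_penalty < 0:
            raise ValueError("lambda_penalty must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    @property
    def lam_switch(self) -> float:
        return self.lambda_penalty if self.lambda_switch is None else self.lambda_switch

    @property
    def lam_mmd(self) -> float:
        return self.lambda_penalty if self.lambda_mmd is None else self.lambda_mmd


def mmd2(U, V, bandwidth: float):
    """Squared maximum mean discrepancy, biased V-statistic, Gaussian kernel.

    Works on plain arrays (returns float) or autodiff tensors (returns a
    Tensor). k(x, y) = exp(-||x-y||^2 / (2 sigma^2)).
    """
    U, V = _atleast2d(U), _atleast2d(V)
    nu = U.shape[0] if not isinstance(U, Tensor) else U.data.shape[0]
    nv = V.shape[0] if not isinstance(V, Tensor) else V.data.shape[0]
    if nu == 0 or nv == 0:
        raise ValueError("MMD requires non-empty sets")
    s2 = 2.0 * bandwidth**2
    kuu = exp(-_sqdist(U, U) / s2)
    kvv = exp(-_sqdist(V, V) / s2)
    kuv = exp(-_sqdist(U, V) / s2)
    out = kuu.mean() - 2.0 * kuv.mean() + kvv.mean()
    return out if isinstance(out, Tensor) else float(out)


def _atleast2d(X):
    if isinstance(X, Tensor):
        return X.reshape(1, -1) if X.data.ndim == 1 else X
    X = np.asarray(X, dtype=float)
    return X.reshape(1, -1) if X.ndim == 1 else X


def _sqdist(A, B):
    aa = (A * A).sum(axis=1).reshape(-1, 1)
    bb = (B * B).sum(axis=1).reshape(1, -1)
    return aa + bb - 2.0 * (A @ B.T)


def median_bandwidth(Z: np.ndarray) -> float:
    """Median pairwise distance heuristic (on at most 500 points)."""
    from scipy.spatial.distance import pdist

    Z = np.asarray(Z, dtype=float)
    if Z.shape[0] > 500:
        Z = Z[:: max(1, Z.shape[0] // 500)][:500]
    if Z.shape[0] < 2:
        return 1.0
    med = np.median(pdist(Z))
    return float(med) if med > 0 else 1.0


def switch_penalty(networks: VelocityNetworks, u_star: np.ndarray, s_star: np.ndarray):
    """Sum over genes of squared distance of the switch point to the medians."""
    times = {  # only needed to evaluate the switch point through state_means
        1: networks.kinetic_tensors()[3], 3: networks.kinetic_tensors()[3],
    }
    _, _, (u0, s0) = networks.state_means(
        {1: times[1], 2: None, 3: times[3], 4: None})
    return ((u0 - np.asarray(u_star)) ** 2 + (s0 - np.asarray(s_star)) ** 2).sum()


class Adam:
    """Adam with decoupled weight decay and global-norm gradient clipping."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0,
                 grad_clip: float | None = None):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay = weight_decay
        self.grad_clip = grad_clip
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data)
                 for p in self.params]
        if self.grad_clip is not None:
            norm = np.sqrt(sum(float((g**2).sum()) for g in grads))
            if norm > self.grad_clip:
                grads = [g * (self.grad_clip / norm) for g in grads]
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            if self.weight_decay:
                p.data *= 1.0 - self.lr * self.weight_decay
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class FitResult:
    networks: VelocityNetworks
    history: pd.DataFrame
    config: TrainConfig


def _batch_indices(codes: np.ndarray):
    return [np.flatnonzero(codes == b) for b in np.unique(codes)]


def elbo_terms(networks: VelocityNetworks, u_scaled, s_scaled, graph: CellGraph,
               rng: np.random.Generator):
    """One forward pass; returns (reconstruction, kl_z, kl_pi, z) — per-cell means."""
    mean, var = networks.encode_expression(u_scaled, s_scaled)
    z_vae = networks.sample_latent(mean, var, rng)
    z_gat = networks.gat_encode(z_vae, graph)
    z = z_vae + z_gat
    conc, pi = networks.state_posterior(z)
    _, _, _, t_s, _, _ = networks.kinetic_tensors()
    times = networks.latent_time(z, t_s)
    ll = networks.mixture_loglik(u_scaled, s_scaled, pi, times)
    n = u_scaled.shape[0]
    recon = -ll.sum() * (1.0 / n)
    kl_z = networks.kl_normal(mean, var).sum() * (1.0 / n)
    kl_pi = networks.kl_dirichlet(conc).sum() * (1.0 / n)
    return recon, kl_z, kl_pi, z, pi


def fit(dataset, graph: CellGraph, config: TrainConfig | None = None,
        networks: VelocityNetworks | None = None, d_latent: int = 10,
        hidden: int = 128, heads: int = 4, t_max: float = 20.0,
        callback=None) -> FitResult:
    """Train the model on a preprocessed (scaled) dataset.

    The dataset must carry ``Mu_scaled``/``Ms_scaled`` layers; the graph is
    the combined spatial/MNN graph over the same cells (self-loops are added
    here). Deterministic given ``config.seed``.
    """
    config = config or TrainConfig()
    ad = dataset.adata
    u = np.asarray(ad.layers["Mu_scaled"], dtype=float)
    s = np.asarray(ad.layers["Ms_scaled"], dtype=float)
    rng = np.random.default_rng(config.seed)

    if networks is None:
        init_ratio = (ad.var["steady_state_ratio"].to_numpy()
                      if "steady_state_ratio" in ad.var else None)
        networks = VelocityNetworks(
            n_genes=u.shape[1], d_latent=d_latent, hidden=hidden, heads=heads,
            t_max=t_max, rng=np.random.default_rng(config.seed + 1),
            init_ratio=init_ratio,
        )

    g = graph.with_self_loops()
    u_star = np.median(u, axis=0)
    s_star = np.median(s, axis=0)

    # steady-state-line orientation target for the warm-up
    if "steady_state_ratio" in ad.var:
        ss_ratio = ad.var["steady_state_ratio"].to_numpy()
    else:
        denom = (s * s).sum(axis=0)
        ss_ratio = np.where(denom > 0, (u * s).sum(axis=0) / denom, 1.0)
    induction_mask = (u > ss_ratio[None, :] * s).astype(float)
    codes = np.asarray(dataset.batch.codes)
    groups = _batch_indices(codes)

    opt = Adam(networks.params, lr=config.learning_rate,
               weight_decay=config.weight_decay, grad_clip=config.grad_clip)
    rows = []
    for epoch in range(config.epochs):
        opt.zero_grad()
        recon, kl_z, kl_pi, z, pi = elbo_terms(networks, u, s, g, rng)
        elbo = recon + kl_z + kl_pi

        sw = switch_penalty(networks, u_star, s_star)

        warm_epochs = max(1, int(config.state_warmup_frac * config.epochs))
        if config.state_warmup_weight > 0 and epoch < warm_epochs:
            w_warm = config.state_warmup_weight * (1.0 - epoch / warm_epochs)
            p_ind = pi[:, :, 0:2].sum(axis=2)
            p_rep = pi[:, :, 2:4].sum(axis=2)
            aux = -(induction_mask * p_ind.log()
                    + (1.0 - induction_mask) * p_rep.log()).sum(axis=1).mean()
            warm = w_warm * aux
        else:
            warm = as_tensor(0.0)

        if len(groups) > 1 and config.lam_mmd > 0:
            mmd_total = 0.0
            for i1 in range(len(groups)):
                for i2 in range(i1 + 1, len(groups)):
                    a = groups[i1]
                    b = groups[i2]
                    if len(a) > config.batch_size:
                        a = rng.choice(a, config.batch_size, replace=False)
                    if len(b) > config.batch_size:
                        b = rng.choice(b, config.batch_size, replace=False)
                    za, zb = z.take_rows(a), z.take_rows(b)
                    bw = (median_bandwidth(np.vstack([za.data, zb.data]))
                          if config.mmd_bandwidth == "median"
                          else float(config.mmd_bandwidth))
                    mmd_total = mmd_total + mmd2(za, zb, bw)
        else:
            mmd_total = as_tensor(0.0)

        total = elbo + config.lam_switch * sw + config.lam_mmd * mmd_total + warm
        if not np.isfinite(total.item()):
            raise FloatingPointError(
                f"non-finite loss at epoch {epoch}: elbo={elbo.item():.4g} "
                f"switch={sw.item():.4g} mmd={float(mmd_total.item()):.4g}"
            )
        total.backward()
        opt.step()
        rows.append({
            "epoch": epoch, "elbo": elbo.item(), "recon": recon.item(),
            "kl_z": kl_z.item(), "kl_pi": kl_pi.item(), "switch": sw.item(),
            "mmd": float(mmd_total.item()), "total": total.item(),
        })
        if callback is not None:
            callback(epoch, rows[-1])
    return FitResult(networks=networks, history=pd.DataFrame(rows), config=config)
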