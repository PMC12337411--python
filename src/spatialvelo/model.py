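"""Generative model and variational family.

Each cell's latent state z_n (dimension d, default 10) is the sum of two
parts: a reparameterised sample from an amortised Gaussian posterior
q(z_VAE | u, s) produced by an MLP encoder over the concatenated scaled
unspliced/spliced profile, and a graph-attention encoding z_GAT of that
sample over the combined spatial/MNN cell graph. Downstream of z:

* a state network maps z to per-cell-per-gene 4-dimensional Dirichlet
  concentrations (variational posterior over the transcriptional-state
  simplex; prior Dirichlet(0.25, 0.25, 0.25, 0.25));
* two state-specific time networks h1, h3 map z to (0,1) values rho which
  place each cell-gene on the induction branch (t = rho1 * t_switch) or the
  repression branch (t = t_switch + rho3 * (t_max - t_switch)); the steady
  states use the conventions t(2) = t_switch, t(4) = t_max;
* per-gene kinetic parameters (alpha, beta, gamma, t_switch, noise scales)
  are free learnable parameters, positivity enforced by exp/sigmoid links.

The observation model is a per-cell-per-gene 4-component Gaussian mixture
over states: obs ~ sum_k pi_k Normal(mean_k(t_k), (c_k sigma)^2) with
c = (1, 1, 1, 0.1) — the repression steady state is modelled tightly.
"""

from __future__ import annotations

import numpy as np

from . import kinetics as kin
from ._autodiff import Tensor, as_tensor, concat, scatter_sum, segment_softmax, stack
from .graphs import CellGraph

__all__ = ["Linear", "MLP", "GATLayer", "VelocityNetworks", "DIRICHLET_PRIOR"]

#: symmetric Dirichlet prior concentration on the 4 transcriptional states
DIRICHLET_PRIOR = 0.25

LOG2PI = float(np.log(2.0 * np.pi))


class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 gain: float = 1.0):
        s = gain * np.sqrt(2.0 / (n_in + n_out))
        self.W = Tensor(rng.normal(0.0, s, (n_in, n_out)))
        self.b = Tensor(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return as_tensor(x) @ self.W + self.b

    @property
    def params(self):
        return [self.W, self.b]


class MLP:
    """Fully connected stack with ELU hidden activations, linear output."""

    def __init__(self, sizes, rng, gain_last: float = 1.0):
        self.layers = [
            Linear(a, b, rng, gain=(gain_last if i == len(sizes) - 2 else 1.0))
            for i, (a, b) in enumerate(zip(sizes[:-1], sizes[1:]))
        ]

    def __call__(self, x):
        h = as_tensor(x)
        for i, layer in enumerate(self.layers):
            h = layer(h)
            if i < len(self.layers) - 1:
                h = h.elu()
        return h

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]


class GATLayer:
    """Single multi-head graph-attention layer with weighted edges.

    Per head: h_i = W x_i; the unnormalised attention on edge (j -> i) is
    LeakyReLU(a_src . h_j + a_dst . h_i); attention is softmax-normalised
    over each target's incoming edges with the edge weights multiplying the
    exponentiated scores (so a zero-weight edge carries no message). Heads
    are concatenated, passed through ELU and linearly projected to
    ``out_dim``.
    """

    def __init__(self, in_dim: int, out_dim: int, heads: int,
                 rng: np.random.Generator, head_dim: int | None = None):
        self.heads = heads
        self.head_dim = head_dim or out_dim
        self.W = [Linear(in_dim, self.head_dim, rng) for _ in range(heads)]
        self.a_src = [Tensor(rng.normal(0, 0.1, self.head_dim)) for _ in range(heads)]
        self.a_dst = [Tensor(rng.normal(0, 0.1, self.head_dim)) for _ in range(heads)]
        self.proj = Linear(heads * self.head_dim, out_dim, rng)

    def __call__(self, x: Tensor, graph: CellGraph) -> Tensor:
        n = graph.n_cells
        src, dst, w = graph.src, graph.dst, graph.weight
        outs = []
        for h in range(self.heads):
            Wh = self.W[h](x)
            hs = Wh.take_rows(src)
            hd = Wh.take_rows(dst)
            e = ((hs * self.a_src[h]).sum(axis=1)
                 + (hd * self.a_dst[h]).sum(axis=1)).leaky_relu(0.2)
            alpha = segment_softmax(e, dst, n, weights=w)
            msg = alpha.reshape(-1, 1) * hs
            outs.append(scatter_sum(msg, dst, n))
        return self.proj(concat(outs, axis=1).elu())

    @property
    def params(self):
        ps = [p for lin in self.W for p in lin.params]
        ps += self.a_src + self.a_dst + self.proj.params
        return ps


class VelocityNetworks:
    """All learnable components plus the forward passes used in training."""

    def __init__(self, n_genes: int, d_latent: int = 10, hidden: int = 128,
                 heads: int = 4, t_max: float = 20.0,
                 rng: np.random.Generator | None = None,
                 init_ratio: np.ndarray | None = None):
        rng = rng or np.random.default_rng(0)
        G = n_genes
        self.n_genes = G
        self.d_latent = d_latent
        self.t_max = float(t_max)

        self.encoder = MLP([2 * G, hidden, hidden], rng)
        self.enc_mean = Linear(hidden, d_latent, rng, gain=0.1)
        self.enc_logvar = Linear(hidden, d_latent, rng, gain=0.1)
        self.gat = GATLayer(d_latent, d_latent, heads, rng)
        self.state_net = MLP([d_latent, hidden, G * 4], rng, gain_last=0.1)
        self.time_net = {
            kin.INDUCTION: MLP([d_latent, hidden, G], rng, gain_last=0.1),
            kin.REPRESSION: MLP([d_latent, hidden, G], rng, gain_last=0.1),
        }

        # per-gene kinetics, positivity through exp links; gamma initialised
        # at the steady-state ratio when available (beta initialised at 1)
        ratio = np.ones(G) if init_ratio is None else np.clip(init_ratio, 0.05, 5.0)
        self.log_alpha = Tensor(np.zeros(G))
        self.log_beta = Tensor(np.zeros(G))
        self.log_gamma = Tensor(np.log(ratio))
        self.ts_logit = Tensor(np.zeros(G))
        self.log_sigma_u = Tensor(np.full(G, np.log(0.1)))
        self.log_sigma_s = Tensor(np.full(G, np.log(0.1)))

    # ------------------------------------------------------------------ params
    @property
    def params(self):
        ps = (self.encoder.params + self.enc_mean.params + self.enc_logvar.params
              + self.gat.params + self.state_net.params
              + self.time_net[kin.INDUCTION].params
              + self.time_net[kin.REPRESSION].params)
        ps += [self.log_alpha, self.log_beta, self.log_gamma, self.ts_logit,
               self.log_sigma_u, self.log_sigma_s]
        return ps

    def kinetic_tensors(self):
        """(alpha, beta, gamma, t_switch, sigma_u, sigma_s) as Tensors."""
        alpha = self.log_alpha.exp()
        beta = self.log_beta.exp()
        gamma = self.log_gamma.exp()
        # t_switch strictly inside (0, t_max)
        t_s = self.ts_logit.sigmoid() * (0.9 * self.t_max) + 0.05 * self.t_max
        sig_u = self.log_sigma_u.exp() + 1e-3
        sig_s = self.log_sigma_s.exp() + 1e-3
        return alpha, beta, gamma, t_s, sig_u, sig_s

    def kinetic_params(self) -> kin.KineticParams:
        """Current kinetics as a plain (detached) :class:`KineticParams`."""
        a, b, g, ts, su, ss = self.kinetic_tensors()
        return kin.KineticParams(
            alpha1=a.data.copy(), beta=b.data.copy(), gamma=g.data.copy(),
            t_switch=ts.data.copy(), t_max=self.t_max,
            sigma_u=su.data.copy(), sigma_s=ss.data.copy(),
        )

    # ----------------------------------------------------------------- encoder
    def encode_expression(self, u_scaled: np.ndarray, s_scaled: np.ndarray):
        """Amortised Normal posterior q(z_VAE | u, s): (mean, var) Tensors."""
        x = np.concatenate([np.asarray(u_scaled), np.asarray(s_scaled)], axis=1)
        if not np.all(np.isfinite(x)):
            raise ValueError("encoder input contains non-finite values")
        h = self.encoder(Tensor(x)).elu()
        mean = self.enc_mean(h)
        logvar = self.enc_logvar(h)
        var = logvar.tanh() * 5.0  # keep log-variance in (-5, 5)
        return mean, var.exp()

    def sample_latent(self, mean: Tensor, var: Tensor, rng: np.random.Generator):
        eps = rng.standard_normal(mean.shape)
        return mean + var.sqrt() * eps

    def gat_encode(self, z_vae: Tensor, graph: CellGraph) -> Tensor:
        if graph.n_cells != z_vae.shape[0]:
            raise ValueError("graph size does not match number of cells")
        return self.gat(z_vae, graph)

    # ------------------------------------------------------- state / time heads
    def state_posterior(self, z: Tensor):
        """Variational Dirichlet concentrations and their mean pi, (N, G, 4)."""
        raw = self.state_net(z).reshape(-1, self.n_genes, 4)
        conc = raw.softplus() + 1e-4
        pi = conc / conc.sum(axis=2, keepdims=True)
        return conc, pi

    def latent_time(self, z: Tensor, t_s):
        """Per-state times: dict k -> (N, G) Tensor/array.

        t(1) = rho1 * t_s on the induction branch, t(3) = t_s +
        rho3 * (t_max - t_s) on the repression branch; the steady states sit
        at t(2) = t_s and t(4) = t_max by convention.
        """
        rho1 = self.time_net[kin.INDUCTION](z).sigmoid()
        rho3 = self.time_net[kin.REPRESSION](z).sigmoid()
        t1 = rho1 * t_s
        t3 = rho3 * (self.t_max - t_s) + t_s
        return {kin.INDUCTION: t1, kin.INDUCTION_SS: t_s,
                kin.REPRESSION: t3, kin.REPRESSION_SS: self.t_max,
                "rho1": rho1, "rho3": rho3}

    # -------------------------------------------------------------- likelihood
    def state_means(self, times):
        """Mixture-component means (u, s) per state given per-state times."""
        alpha, beta, gamma, t_s, _, _ = self.kinetic_tensors()
        u0 = kin.induction_u(t_s, alpha, beta)
        s0 = kin.induction_s(t_s, alpha, beta, gamma)
        t1 = times[kin.INDUCTION]
        tau = times[kin.REPRESSION] - t_s
        mu = {
            kin.INDUCTION: kin.induction_u(t1, alpha, beta),
            kin.INDUCTION_SS: alpha / beta,
            kin.REPRESSION: kin.repression_u(tau, u0, beta),
            kin.REPRESSION_SS: 0.0,
        }
        ms = {
            kin.INDUCTION: kin.induction_s(t1, alpha, beta, gamma),
            kin.INDUCTION_SS: alpha / gamma,
            kin.REPRESSION: kin.repression_s(tau, u0, s0, beta, gamma),
            kin.REPRESSION_SS: 0.0,
        }
        return mu, ms, (u0, s0)

    def mixture_loglik(self, u_scaled, s_scaled, pi: Tensor, times,
                       c_state=(1.0, 1.0, 1.0, 0.1)):
        """Per-cell-gene log p(u) + log p(s) under the 4-state Gaussian mixture."""
        _, _, _, _, sig_u, sig_s = self.kinetic_tensors()
        mu, ms, _ = self.state_means(times)
        u = np.asarray(u_scaled)
        s = np.asarray(s_scaled)
        log_pi = pi.log()
        lp_u, lp_s = [], []
        for j, k in enumerate((kin.INDUCTION, kin.INDUCTION_SS,
                               kin.REPRESSION, kin.REPRESSION_SS)):
            c = c_state[j]
            su = sig_u * c
            ss = sig_s * c
            ones = np.ones_like(u)
            lp_u.append(-su.log() - 0.5 * LOG2PI
                        - (u - mu[k] * ones) ** 2 / (2.0 * su**2))
            lp_s.append(-ss.log() - 0.5 * LOG2PI
                        - (s - ms[k] * ones) ** 2 / (2.0 * ss**2))
        ll_u = (stack(lp_u, axis=2) + log_pi).logsumexp(axis=2)
        ll_s = (stack(lp_s, axis=2) + log_pi).logsumexp(axis=2)
        return ll_u + ll_s

    # --------------------------------------------------------------- KL terms
    @staticmethod
    def kl_normal(mean: Tensor, var: Tensor) -> Tensor:
        """Per-cell KL(q(z) || N(0, I))."""
        return 0.5 * (mean**2 + var - var.log() - 1.0).sum(axis=1)

    @staticmethod
    def kl_dirichlet(conc: Tensor, prior: float = DIRICHLET_PRIOR) -> Tensor:
        """Per-cell-gene KL(Dirichlet(conc) || Dirichlet(prior * 1_4))."""
        from scipy.special import gammaln

        K = conc.shape[-1]
        c0 = conc.sum(axis=-1)
        term = ((conc - prior) * (conc.digamma() - c0.digamma().reshape(
            *c0.shape, 1))).sum(axis=-1)
        return (c0.gammaln() - conc.gammaln().sum(axis=-1)
                - float(gammaln(K * prior)) + K * float(gammaln(prior)) + term)
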