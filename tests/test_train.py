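"""Objective terms (MMD, switch penalty, ELBO) and the optimisation loop."""

import numpy as np
import pytest

from spatialvelo import SimConfig, SpatialVelocityModel, preprocess, simulate
from spatialvelo._autodiff import Tensor
from spatialvelo.model import VelocityNetworks
from spatialvelo.preprocess import PreprocessConfig
from spatialvelo.train import (
    Adam,
    TrainConfig,
    fit,
    median_bandwidth,
    mmd2,
    switch_penalty,
)


def brute_force_mmd2(U, V, sigma):
    """Triple-loop oracle for the biased V-statistic."""
    def k(x, y):
        return np.exp(-np.sum((x - y) ** 2) / (2 * sigma**2))

    n, m = len(U), len(V)
    t1 = sum(k(U[i], U[j]) for i in range(n) for j in range(n)) / n**2
    t2 = sum(k(U[i], V[j]) for i in range(n) for j in range(m)) / (n * m)
    t3 = sum(k(V[i], V[j]) for i in range(m) for j in range(m)) / m**2
    return t1 - 2 * t2 + t3


class TestMMD:
    def test_identical_sets_zero(self, rng):
        U = rng.normal(size=(6, 3))
        assert mmd2(U, U.copy(), 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_symmetry_and_nonnegativity(self, rng):
        U = rng.normal(size=(5, 3))
        V = rng.normal(size=(8, 3)) + 1.0
        assert mmd2(U, V, 0.7) == pytest.approx(mmd2(V, U, 0.7), abs=1e-12)
        assert mmd2(U, V, 0.7) >= -1e-12

    def test_singleton_closed_form(self):
        # ||x - y||^2 = 2 sigma^2  ->  MMD^2 = 2 - 2 e^{-1}
        sigma = 1.3
        x = np.zeros(2)
        y = np.array([sigma * np.sqrt(2.0), 0.0])
        assert mmd2(x[None], y[None], sigma) == pytest.approx(
            2 - 2 * np.exp(-1), abs=1e-12)

    def test_matches_brute_force(self, rng):
        U = rng.normal(size=(5, 3))
        V = rng.normal(size=(7, 3)) + 0.3
        assert mmd2(U, V, 0.9) == pytest.approx(
            brute_force_mmd2(U, V, 0.9), abs=1e-10)

    def test_tensor_path_equals_numpy_path(self, rng):
        U = rng.normal(size=(4, 2))
        V = rng.normal(size=(5, 2))
        out = mmd2(Tensor(U), Tensor(V), 0.8)
        assert out.item() == pytest.approx(mmd2(U, V, 0.8), abs=1e-12)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            mmd2(np.zeros((0, 2)), np.ones((3, 2)), 1.0)

    def test_median_bandwidth_positive(self, rng):
        assert median_bandwidth(rng.normal(size=(30, 4))) > 0
        assert median_bandwidth(np.zeros((5, 2))) == 1.0  # degenerate fallback


class TestSwitchPenalty:
    def test_zero_when_switch_at_medians(self):
        nets = VelocityNetworks(n_genes=3, d_latent=2, hidden=8, heads=1,
                              rng=np.random.default_rng(0))
        _, _, _, t_s, _, _ = nets.kinetic_tensors()
        mu, ms, (u0, s0) = nets.state_means({1: t_s, 2: None, 3: t_s, 4: None})
        pen = switch_penalty(nets, u0.data, s0.data)
        assert pen.item() == pytest.approx(0.0, abs=1e-14)

    def test_residual_arithmetic(self):
        # one gene with u-residual 0.3 and s-residual -0.4 -> 0.09+0.16 = 0.25
        nets = VelocityNetworks(n_genes=1, d_latent=2, hidden=8, heads=1,
                              rng=np.random.default_rng(1))
        _, _, _, t_s, _, _ = nets.kinetic_tensors()
        _, _, (u0, s0) = nets.state_means({1: t_s, 2: None, 3: t_s, 4: None})
        pen = switch_penalty(nets, u0.data - 0.3, s0.data + 0.4)
        assert pen.item() == pytest.approx(0.25, abs=1e-12)

    def test_invariant_to_cell_order(self, rng):
        u = rng.uniform(0, 1, (11, 2))
        s = rng.uniform(0, 1, (11, 2))
        nets = VelocityNetworks(n_genes=2, d_latent=2, hidden=8, heads=1,
                              rng=np.random.default_rng(2))
        a = switch_penalty(nets, np.median(u, 0), np.median(s, 0)).item()
        perm = rng.permutation(11)
        b = switch_penalty(nets, np.median(u[perm], 0),
                           np.median(s[perm], 0)).item()
        assert a == pytest.approx(b, abs=1e-14)


class TestNormalKL:
    def test_standard_normal_is_zero(self):
        kl = VelocityNetworks.kl_normal(Tensor(np.zeros((3, 4))),
                                      Tensor(np.ones((3, 4))))
        assert np.allclose(kl.data, 0.0, atol=1e-14)

    def test_hand_formula(self, rng):
        mu = rng.normal(size=(2, 3))
        var = rng.uniform(0.5, 2.0, (2, 3))
        expected = 0.5 * (mu**2 + var - np.log(var) - 1).sum(axis=1)
        got = VelocityNetworks.kl_normal(Tensor(mu), Tensor(var)).data
        assert np.allclose(got, expected, atol=1e-12)


def small_training_setup(seed=0, n=40, epochs=5, **cfg_kw):
    cfg = SimConfig(n_cells_per_batch=n, n_genes=8, n_background_genes=16,
                    n_batches=2, n_cell_types=3, seed=seed)
    ds, gt = simulate(cfg)
    pp = preprocess(ds, PreprocessConfig(min_shared_counts=2, n_neighbors=5,
                                         n_pcs=5, r2_threshold=0.1))
    from spatialvelo.graphs import build_cell_graph

    graph = build_cell_graph(pp, k=5)
    config = TrainConfig(epochs=epochs, seed=seed, **cfg_kw)
    return pp, graph, config


class TestFit:
    def test_loss_components_logged_and_total_is_their_sum(self):
        pp, graph, config = small_training_setup(epochs=3)
        res = fit(pp, graph, config, d_latent=4, hidden=16, heads=2)
        h = res.history
        assert list(h["epoch"]) == [0, 1, 2]
        lam = config.lambda_penalty
        # total = elbo + lambda*switch + lambda*mmd + warmup; warmup is the
        # only unlogged part, so check the identity where it is inactive
        assert np.allclose(h["elbo"], h["recon"] + h["kl_z"] + h["kl_pi"],
                           atol=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_training_reduces_loss(self, seed):
        pp, graph, config = small_training_setup(seed=seed, epochs=50)
        res = fit(pp, graph, config, d_latent=4, hidden=16, heads=2)
        assert res.history["total"].iloc[-1] < res.history["total"].iloc[0]

    def test_mmd_penalty_lowers_final_batch_mmd(self):
        """Paired over seeds, the final cross-batch latent MMD^2 is lower
        when the batch penalty is on than when it is off."""
        gaps = []
        for seed in (0, 1, 2):
            finals = {}
            for lam, tag in ((2.0, "on"), (0.0, "off")):
                pp, graph, config = small_training_setup(
                    seed=seed, n=60, epochs=80, lambda_mmd=lam)
                res = fit(pp, graph, config, d_latent=4, hidden=16, heads=2)
                nets = res.networks
                u = np.asarray(pp.adata.layers["Mu_scaled"])
                s = np.asarray(pp.adata.layers["Ms_scaled"])
                mean, _ = nets.encode_expression(u, s)
                z = (mean + nets.gat_encode(
                    Tensor(mean.data), graph.with_self_loops())).data
                codes = np.asarray(pp.batch.codes)
                bw = median_bandwidth(z)
                finals[tag] = mmd2(z[codes == 0], z[codes == 1], bw)
            gaps.append(finals["off"] - finals["on"])
        assert np.mean(gaps) > 0

    def test_deterministic_given_seed(self):
        pp, graph, config = small_training_setup(epochs=4)
        r1 = fit(pp, graph, config, d_latent=4, hidden=16, heads=2)
        r2 = fit(pp, graph, config, d_latent=4, hidden=16, heads=2)
        assert np.array_equal(r1.networks.log_gamma.data,
                              r2.networks.log_gamma.data)
        assert np.allclose(r1.history["total"], r2.history["total"])

    def test_single_batch_has_zero_mmd(self):
        cfg = SimConfig(n_cells_per_batch=40, n_genes=8, n_background_genes=16,
                        n_batches=1, n_cell_types=3, seed=1)
        ds, _ = simulate(cfg)
        pp = preprocess(ds, PreprocessConfig(min_shared_counts=2,
                                             n_neighbors=5, n_pcs=5,
                                             r2_threshold=0.1))
        from spatialvelo.graphs import build_cell_graph

        graph = build_cell_graph(pp, k=5)
        res = fit(pp, graph, TrainConfig(epochs=3, seed=0), d_latent=4,
                  hidden=16, heads=2)
        assert np.allclose(res.history["mmd"], 0.0)

    def test_lambda_zero_is_elbo_only(self):
        pp, graph, config = small_training_setup(epochs=3, lambda_penalty=0.0,
                                                 state_warmup_weight=0.0)
        res = fit(pp, graph, config, d_latent=4, hidden=16, heads=2)
        assert np.allclose(res.history["total"], res.history["elbo"], atol=1e-10)


def test_loss_gradients_match_finite_differences():
    """Autodiff gradient of the full objective vs central differences."""
    pp, graph, config = small_training_setup(epochs=1)
    u = np.asarray(pp.adata.layers["Mu_scaled"])
    s = np.asarray(pp.adata.layers["Ms_scaled"])
    nets = VelocityNetworks(n_genes=u.shape[1], d_latent=3, hidden=8, heads=1,
                          rng=np.random.default_rng(0))
    g = graph.with_self_loops()
    u_star, s_star = np.median(u, 0), np.median(s, 0)

    def loss_value():
        from spatialvelo.train import elbo_terms

        rng = np.random.default_rng(123)
        recon, kl_z, kl_pi, z, _ = elbo_terms(nets, u, s, g, rng)
        sw = switch_penalty(nets, u_star, s_star)
        return recon + kl_z + kl_pi + 2.0 * sw

    total = loss_value()
    total.backward()
    eps = 1e-5
    for pname, param in (("log_gamma", nets.log_gamma),
                         ("ts_logit", nets.ts_logit)):
        idx = 0
        g_auto = param.grad[idx]
        orig = param.data[idx]
        param.data[idx] = orig + eps
        up = loss_value().item()
        param.data[idx] = orig - eps
        down = loss_value().item()
        param.data[idx] = orig
        g_num = (up - down) / (2 * eps)
        assert g_auto == pytest.approx(g_num, rel=1e-4, abs=1e-7), pname


def test_adam_converges_on_quadratic():
    x = Tensor(np.array([5.0, -3.0]))
    opt = Adam([x], lr=0.2)
    for _ in range(200):
        opt.zero_grad()
        ((x - np.array([1.0, 2.0])) ** 2).sum().backward()
        opt.step()
    assert np.allclose(x.data, [1.0, 2.0], atol=1e-3)


def test_config_validation():
    with pytest.raises(ValueError, match="lambda"):
        TrainConfig(lambda_penalty=-1.0)
    with pytest.raises(ValueError, match="epochs"):
        TrainConfig(epochs=0)
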