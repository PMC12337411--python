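"""Velocity evaluation scores against brute-force implementations."""

import numpy as np
import pytest

from spatialvelo import ground_truth_scores
from spatialvelo.evaluation import (
    TransitionGroundTruth,
    aggregate_scores,
    boundary_cells,
    coherence_score,
    confidence_score,
    direction_score,
    transition_matrix,
    transition_score,
    velocity_embedding,
)


def cos(a, b):
    return a @ b / (np.linalg.norm(a) * np.linalg.norm(b))


class TestBoundary:
    labels = np.array(["A", "A", "A", "B", "B", "C"])
    nbrs = [np.array([1, 3]), np.array([0, 2]), np.array([1, 5]),
            np.array([0, 4]), np.array([3, 5]), np.array([2, 4])]

    def test_enumerated_set(self):
        got = boundary_cells(self.labels, self.nbrs, "A", "B")
        assert got.tolist() == [0]  # only cell 0 has a B neighbour

    def test_every_a_adjacent_to_b(self):
        labels = np.array(["A", "A", "B", "B"])
        nbrs = [np.array([2]), np.array([3]), np.array([0]), np.array([1])]
        assert boundary_cells(labels, nbrs, "A", "B").tolist() == [0, 1]

    def test_separated_clusters_empty(self):
        labels = np.array(["A", "A", "B", "B"])
        nbrs = [np.array([1]), np.array([0]), np.array([3]), np.array([2])]
        assert len(boundary_cells(labels, nbrs, "A", "B")) == 0

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            boundary_cells(self.labels, self.nbrs, "A", "Z")


class TestConfidence:
    def test_identical_velocities_give_one(self):
        V = np.tile([1.0, 2.0], (4, 1))
        labels = np.array(["A", "A", "B", "B"])
        nbrs = [np.array([2]), np.array([3]), np.array([0]), np.array([1])]
        assert confidence_score(V, nbrs, labels, "A", "B") == pytest.approx(1.0)

    def test_antiparallel_gives_minus_one(self):
        V = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0]])
        labels = np.array(["A", "X", "B"])
        nbrs = [np.array([2]), np.array([0]), np.array([0])]
        assert confidence_score(V, nbrs, labels, "A", "B") == pytest.approx(-1.0)

    def test_brute_force_double_loop(self, rng):
        n = 5
        V = rng.normal(size=(n, 3))
        labels = np.array(["A", "A", "B", "B", "B"])
        nbrs = [np.array([1, 2, 3]), np.array([0, 3, 4]), np.array([0, 1]),
                np.array([1, 4]), np.array([2, 3])]
        got = confidence_score(V, nbrs, labels, "A", "B")
        vals = []
        for c in (0, 1):
            bn = [j for j in nbrs[c] if labels[j] == "B"]
            vals.append(np.mean([cos(V[c], V[j]) for j in bn]))
        assert got == pytest.approx(np.mean(vals), abs=1e-12)

    def test_empty_boundary_is_missing(self):
        V = np.ones((2, 2))
        labels = np.array(["A", "B"])
        nbrs = [np.array([], dtype=int), np.array([], dtype=int)]
        assert np.isnan(confidence_score(V, nbrs, labels, "A", "B"))


class TestTransition:
    def test_two_cell_normalisation(self):
        S = np.array([[0.0, 0.0], [1.0, 0.0]])
        V = np.array([[1.0, 0.0], [1.0, 0.0]])
        P = transition_matrix(V, S, sigma=0.1)
        assert P[0, 1] == pytest.approx(1.0)  # only one candidate

    def test_brute_force_four_cells(self, rng):
        n, sigma = 4, 0.1
        S = rng.uniform(0, 1, (n, 3))
        V = rng.normal(size=(n, 3))
        P = transition_matrix(V, S, sigma=sigma)
        for c in range(n):
            w = np.zeros(n)
            for j in range(n):
                if j == c:
                    continue
                disp = S[j] - S[c]
                w[j] = np.exp(cos(disp, V[c]) / sigma)
            assert np.allclose(P[c], w / w.sum(), atol=1e-12)

    def test_score_matches_manual_average(self, rng):
        n = 4
        S = rng.uniform(0, 1, (n, 2))
        V = rng.normal(size=(n, 2))
        labels = np.array(["A", "B", "B", "C"])
        nbrs = [np.array([1, 2]), np.array([0]), np.array([0]), np.array([0])]
        P = transition_matrix(V, S, sigma=0.1)
        got = transition_score(V, S, nbrs, labels, "A", "B", sigma=0.1)
        assert got == pytest.approx(P[0, [1, 2]].mean(), abs=1e-12)


class TestDirection:
    def test_embedding_uniform_probabilities_cancel(self):
        n = 5
        X = np.random.default_rng(0).normal(size=(n, 2))
        P = np.full((n, n), 1.0 / n)
        np.fill_diagonal(P, 0.0)
        # with pi~ = 1/n the weights (pi~ - 1/n) vanish off-diagonal and the
        # diagonal is excluded, leaving only the -1/n self-term ... which is
        # skipped, so the projected velocity is the zero vector
        Vt = velocity_embedding(P, X)
        assert np.allclose(Vt, 0.0, atol=1e-12)

    def test_brute_force_embedding(self, rng):
        n = 5
        X = rng.normal(size=(n, 2))
        P = rng.uniform(0, 1, (n, n))
        np.fill_diagonal(P, 0.0)
        P /= P.sum(axis=1, keepdims=True)
        Vt = velocity_embedding(P, X)
        for c in range(n):
            v = np.zeros(2)
            for j in range(n):
                if j == c:
                    continue
                disp = X[j] - X[c]
                v += (P[c, j] - 1.0 / n) * disp / np.linalg.norm(disp)
            assert np.allclose(Vt[c], v, atol=1e-12)

    def test_probability_mass_on_sole_neighbour_hand_value(self):
        # pi~ concentrates on cell 1; the projected velocity is
        # (1 - 1/3) * (1,0) + (0 - 1/3) * (0,1) = (2/3, -1/3), whose cosine
        # with the displacement (1,0) is 2/sqrt(5)
        S = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        V = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        X = S.copy()
        labels = np.array(["A", "B", "C"])
        nbrs = [np.array([1]), np.array([0]), np.array([0])]
        got = direction_score(V, S, X, nbrs, labels, "A", "B", sigma=0.05)
        assert got == pytest.approx(2.0 / np.sqrt(5.0), abs=1e-6)


class TestAggregation:
    def test_plain_mean_without_incorrect_pairs(self):
        correct = {("A", "B"): {"confidence": 0.5, "transition": 0.6,
                                "direction": 0.7}}
        out = aggregate_scores(correct, {})
        assert out == {"confidence": 0.5, "transition": 0.6, "direction": 0.7}

    def test_negated_incorrect_arithmetic(self):
        correct = {("A", "B"): {"confidence": 0.8, "transition": 0.8,
                                "direction": 0.8}}
        incorrect = {("B", "A"): {"confidence": 0.2, "transition": 0.2,
                                  "direction": 0.2}}
        out = aggregate_scores(correct, incorrect)
        assert out["transition"] == pytest.approx(0.3)   # mean(0.8, -0.2)
        assert out["direction"] == pytest.approx(0.3)
        assert out["confidence"] == pytest.approx(0.8)   # correct pairs only

    def test_no_correct_pair_raises(self):
        with pytest.raises(ValueError, match="no correct pair"):
            aggregate_scores({("A", "B"): {"confidence": np.nan,
                                           "transition": np.nan,
                                           "direction": np.nan}}, {})

    def test_duplicate_ground_truth_pairs_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            TransitionGroundTruth([("A", "B"), ("A", "B")])


class TestCoherence:
    def test_identical_velocities_everywhere(self):
        V = np.tile([1.0, 1.0], (6, 1))
        batch = np.array([0, 0, 0, 1, 1, 1])
        mnn = [np.array([3]), np.array([4]), np.array([5]), np.array([0]),
               np.array([1]), np.array([2])]
        assert coherence_score(V, batch, mnn, n_cells=6) == pytest.approx(1.0)

    def test_flipped_batch_velocities(self):
        V = np.vstack([np.tile([1.0, 0.0], (3, 1)), np.tile([-1.0, 0.0], (3, 1))])
        batch = np.array([0, 0, 0, 1, 1, 1])
        mnn = [np.array([3]), np.array([4]), np.array([5]), np.array([0]),
               np.array([1]), np.array([2])]
        assert coherence_score(V, batch, mnn, n_cells=6) == pytest.approx(-1.0)

    def test_three_batch_brute_force(self, rng):
        n = 9
        V = rng.normal(size=(n, 3))
        batch = np.repeat([0, 1, 2], 3)
        mnn = [np.setdiff1d(np.arange(n)[batch != batch[c]],
                            []) [:3] for c in range(n)]
        got = coherence_score(V, batch, mnn, n_cells=n, seed=0)
        scores = []
        for c in range(n):
            nb = np.append(mnn[c], c)
            vb = {}
            for b in (0, 1, 2):
                sel = nb[batch[nb] == b]
                if len(sel):
                    vb[b] = V[sel].mean(axis=0)
            pc = [cos(vb[b1], vb[b2]) for b1 in vb for b2 in vb if b1 != b2]
            scores.append(np.mean(pc))
        assert got == pytest.approx(np.mean(scores), abs=1e-12)

    def test_single_batch_rejected(self):
        with pytest.raises(ValueError, match="2 batches"):
            coherence_score(np.ones((3, 2)), np.zeros(3, dtype=int),
                            [np.array([])] * 3)


class TestRotationInvariance:
    def test_scores_invariant_to_joint_rotation(self, rng):
        """Cosine-based scores are unchanged by a joint orthogonal map of
        expression and velocity space."""
        n, g = 6, 3
        S = rng.uniform(0, 1, (n, g))
        V = rng.normal(size=(n, g))
        labels = np.array(["A", "A", "A", "B", "B", "B"])
        nbrs = [np.array([3, 1]), np.array([4, 0]), np.array([5, 1]),
                np.array([0]), np.array([1]), np.array([2])]
        Q, _ = np.linalg.qr(rng.normal(size=(g, g)))
        c1 = confidence_score(V, nbrs, labels, "A", "B")
        c2 = confidence_score(V @ Q, nbrs, labels, "A", "B")
        assert c1 == pytest.approx(c2, abs=1e-10)
        t1 = transition_score(V, S, nbrs, labels, "A", "B")
        t2 = transition_score(V @ Q, S @ Q, nbrs, labels, "A", "B")
        assert t1 == pytest.approx(t2, abs=1e-10)


def test_planted_transitions_have_positive_direction(small_sim):
    """With true velocities, planted consecutive-type transitions score well
    and the sign flips when velocities flip."""
    ds, gt = small_sim
    rep = ground_truth_scores(ds, gt, n_neighbors=15)
    d = rep.aggregated["expression"]["direction"]
    assert d > 0.1
    gt_flipped = type(gt)(**{**gt.__dict__, "velocity": -gt.velocity})
    rep2 = ground_truth_scores(ds, gt_flipped, n_neighbors=15)
    assert rep2.aggregated["expression"]["direction"] < 0
    assert d > rep2.aggregated["expression"]["direction"]
    assert rep.coherence is not None and rep.coherence > 0.5
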