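import numpy as np
import pytest

from gatorst import (RunConfig, build_knn_graph, class_prototypes,
                     classification_loss, combined_loss, contrastive_loss,
                     query_class_probabilities, sample_episode, train)
from gatorst.encoder import batch_for_spots, build_subgraph_cache, init_params
from gatorst.meta import _episode_step, episode_losses_and_grads


def direct_contrastive(H, classes, tau):
    """Unstabilized direct evaluation of the episodic contrastive loss."""
    n_way = classes.max() + 1
    protos = np.array([H[classes == i].mean(axis=0) for i in range(n_way)])
    total = 0.0
    for s in range(len(H)):
        i = classes[s]
        num = np.exp(H[s] @ protos[i] / tau)
        den = sum(np.exp(H[s] @ protos[k] / tau)
                  for k in range(n_way) if k != i)
        total += np.log(num / den)
    return -total / len(H)


class TestSampleEpisode:
    def test_exhaustion_support_takes_everything(self, rng):
        labels = np.array([0, 0, 0, 1, 1, 1])
        ep = sample_episode(labels, n_way=2, m_shot=3, q_query=0, rng=rng)
        assert sorted(ep.support_nodes) == [0, 1, 2, 3, 4, 5]
        assert len(ep.query_nodes) == 0

    def test_no_overlap_and_query_labels_valid(self):
        rng = np.random.default_rng(42)
        labels = np.random.default_rng(1).integers(0, 6, size=200)
        for _ in range(1000):
            ep = sample_episode(labels, n_way=3, m_shot=4, q_query=6, rng=rng)
            assert not set(ep.support_nodes) & set(ep.query_nodes)
            assert set(labels[ep.query_nodes]) <= set(ep.class_list)
            # class positions agree with actual pseudo-labels
            assert np.array_equal(ep.class_list[ep.support_classes],
                                  labels[ep.support_nodes])

    def test_determinism(self):
        labels = np.random.default_rng(0).integers(0, 5, size=60)
        a = sample_episode(labels, 3, 2, 4, np.random.default_rng(7))
        b = sample_episode(labels, 3, 2, 4, np.random.default_rng(7))
        assert np.array_equal(a.support_nodes, b.support_nodes)
        assert np.array_equal(a.query_nodes, b.query_nodes)

    def test_too_few_classes_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_episode(np.zeros(10, dtype=int), 2, 2, 2, rng)

    def test_one_way_rejected(self, rng):
        with pytest.raises(ValueError, match="n_way"):
            sample_episode(np.array([0, 0, 1, 1]), 1, 1, 1, rng)

    def test_candidate_restriction(self, rng):
        labels = np.tile([0, 1, 2], 20)
        cand = np.arange(30)
        ep = sample_episode(labels, 2, 3, 5, rng, candidates=cand)
        assert set(ep.support_nodes) <= set(cand)
        assert set(ep.query_nodes) <= set(cand)


class TestPrototypes:
    def test_single_shot_prototype_is_embedding(self):
        H = np.array([[1.0, 2.0], [3.0, 4.0]])
        protos = class_prototypes(H, np.array([0, 1]), 2)
        assert np.array_equal(protos, H)

    def test_two_point_mean(self):
        H = np.array([[0.0, 0.0], [2.0, 2.0]])
        protos = class_prototypes(H, np.array([0, 0]), 1)
        assert np.array_equal(protos, [[1.0, 1.0]])

    def test_matches_direct_mean(self, rng):
        H = rng.normal(size=(12, 5))
        classes = rng.integers(0, 3, size=12)
        classes[:3] = [0, 1, 2]
        protos = class_prototypes(H, classes, 3)
        for i in range(3):
            assert np.allclose(protos[i], H[classes == i].mean(axis=0),
                               atol=1e-12)


class TestContrastiveLoss:
    def test_matches_direct_formula(self, rng):
        H = rng.normal(size=(6, 4))
        classes = np.array([0, 0, 1, 1, 2, 2])
        for tau in (0.5, 1.0, 2.0):
            assert contrastive_loss(H, classes, tau) == pytest.approx(
                direct_contrastive(H, classes, tau), abs=1e-8)

    def test_infinite_temperature_limit(self, rng):
        # all exponentials -> 1, each ratio -> 1/(N-1)
        H = rng.normal(size=(8, 3))
        classes = np.array([0, 0, 1, 1, 2, 2, 3, 3])
        loss = contrastive_loss(H, classes, tau=1e6)
        assert loss == pytest.approx(np.log(4 - 1), abs=1e-3)

    def test_two_way_one_shot_hand_expansion(self, rng):
        h1, h2 = rng.normal(size=(2, 5))
        tau = 0.7
        # M=1: prototypes are the embeddings themselves
        expected = -0.5 * ((h1 @ h1 - h1 @ h2) + (h2 @ h2 - h2 @ h1)) / tau
        loss = contrastive_loss(np.vstack([h1, h2]), np.array([0, 1]), tau)
        assert loss == pytest.approx(expected, abs=1e-10)

    def test_class_relabeling_invariance(self, rng):
        H = rng.normal(size=(6, 4))
        classes = np.array([0, 0, 1, 1, 2, 2])
        perm = np.array([2, 0, 1])
        assert contrastive_loss(H, perm[classes], 0.5) == pytest.approx(
            contrastive_loss(H, classes, 0.5), abs=1e-12)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            contrastive_loss(rng.normal(size=(3, 2)), np.zeros(3, dtype=int), 1.0)


class TestQueryProbabilities:
    def test_identical_prototypes_uniform(self, rng):
        protos = np.tile(rng.normal(size=3), (4, 1))
        P = query_class_probabilities(rng.normal(size=(5, 3)), protos, 0.5)
        assert np.allclose(P, 0.25)

    def test_rows_sum_to_one(self, rng):
        for _ in range(100):
            P = query_class_probabilities(rng.normal(size=(3, 4)),
                                          rng.normal(size=(5, 4)), 0.8)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)

    def test_matches_direct_softmax(self, rng):
        q = rng.normal(size=(2, 3))
        protos = rng.normal(size=(4, 3))
        tau = 0.6
        P = query_class_probabilities(q, protos, tau)
        for i in range(2):
            raw = np.exp(q[i] @ protos.T / tau)
            assert np.allclose(P[i], raw / raw.sum(), atol=1e-10)


class TestClassificationLoss:
    def test_perfect_predictions_zero(self):
        P = np.eye(3)
        assert classification_loss(P, np.arange(3)) == pytest.approx(0.0)

    def test_uniform_predictions_log_n(self):
        P = np.full((5, 4), 0.25)
        assert classification_loss(P, np.zeros(5, dtype=int)) == pytest.approx(
            np.log(4))

    def test_matches_direct_summation(self, rng):
        P = rng.dirichlet(np.ones(3), size=6)
        y = rng.integers(0, 3, size=6)
        expected = -np.mean([np.log(P[i, y[i]]) for i in range(6)])
        assert classification_loss(P, y) == pytest.approx(expected, abs=1e-10)

    def test_zero_probability_clamped(self):
        P = np.array([[1.0, 0.0], [0.0, 1.0]])
        loss = classification_loss(P, np.array([1, 1]))
        assert np.isfinite(loss)


class TestCombinedLoss:
    @pytest.mark.parametrize("alpha,expected", [(1.0, 2.0), (0.0, 4.0), (0.5, 3.0)])
    def test_endpoints_and_midpoint(self, alpha, expected):
        assert combined_loss(2.0, 4.0, alpha) == expected

    def test_linear_in_alpha(self):
        l1, l2 = 1.7, -0.3
        vals = [combined_loss(l1, l2, a) for a in (0.2, 0.5, 0.8)]
        assert vals[1] == pytest.approx((vals[0] + vals[2]) / 2, abs=1e-12)

    def test_alpha_out_of_range(self):
        with pytest.raises(ValueError):
            combined_loss(1.0, 1.0, 1.5)


class TestGradients:
    def test_backprop_matches_finite_differences(self, tiny_dataset):
        """Analytic gradient of L_T through prototypes and the subgraph GCN
        agrees with central finite differences."""
        graph = build_knn_graph(tiny_dataset.coordinates, 2)
        X = tiny_dataset.expression
        cache = build_subgraph_cache(graph, X)
        params = init_params(X.shape[1], (5,), 4, rng=np.random.default_rng(1))
        labels = np.array(tiny_dataset.true_labels)
        ep = sample_episode(labels, 2, 2, 2, np.random.default_rng(3))
        tau, alpha = 0.7, 0.6

        def loss_at(p):
            spots = np.concatenate([ep.support_nodes, ep.query_nodes])
            emb = batch_for_spots(spots, cache, X).forward(p)
            ns = len(ep.support_nodes)
            lb, _, _ = episode_losses_and_grads(
                emb[:ns], ep.support_classes, emb[ns:], ep.query_classes,
                tau, alpha)
            return lb.combined

        _, dW, db = _episode_step(ep, X, cache, params, tau, alpha)
        analytic = np.concatenate([a.ravel() for a in dW + db])
        vec = params.flat()
        probe = params.copy()
        eps = 1e-6
        numeric = np.empty_like(vec)
        for i in range(len(vec)):
            v = vec.copy()
            v[i] += eps
            probe.set_flat(v)
            up = loss_at(probe)
            v[i] -= 2 * eps
            probe.set_flat(v)
            down = loss_at(probe)
            numeric[i] = (up - down) / (2 * eps)
        rel = np.abs(numeric - analytic) / np.maximum(
            np.abs(numeric) + np.abs(analytic), 1e-8)
        assert rel.max() < 1e-4

    def test_loss_breakdown_combination_identity(self, rng):
        H = rng.normal(size=(6, 4))
        cs = np.array([0, 0, 0, 1, 1, 1])
        Hq = rng.normal(size=(4, 4))
        cq = np.array([0, 1, 0, 1])
        lb, _, _ = episode_losses_and_grads(H, cs, Hq, cq, 0.5, 0.3)
        assert lb.combined == pytest.approx(
            0.3 * lb.contrastive + 0.7 * lb.classification, abs=1e-9)


class TestTrain:
    def test_loss_decreases_over_training(self, trained_result):
        losses = [r["loss_combined"] for r in trained_result.log]
        assert np.median(losses[-10:]) < np.median(losses[:10])

    def test_training_deterministic(self, separable_fixture):
        dataset, graph, _ = separable_fixture
        cfg = RunConfig(seed=1, n_epochs=2, episodes_per_epoch=25)
        a = train(dataset, graph, cfg)
        b = train(dataset, graph, cfg)
        assert np.array_equal(a.embeddings, b.embeddings)

    def test_within_class_similarity_exceeds_between(self, trained_result):
        H = trained_result.embeddings
        labels = trained_result.pseudo.hard_labels
        Hn = H / np.linalg.norm(H, axis=1, keepdims=True)
        sims = Hn @ Hn.T
        same = labels[:, None] == labels[None, :]
        off_diag = ~np.eye(len(H), dtype=bool)
        assert sims[same & off_diag].mean() > sims[~same].mean()

    def test_non_finite_loss_aborts_with_diagnostic(self, tiny_dataset):
        import dataclasses

        from gatorst.pseudolabels import PseudoLabels, fit_soft_kmeans

        pseudo = fit_soft_kmeans(tiny_dataset.expression, 3, seed=0)
        bad = dataclasses.replace(
            tiny_dataset, expression=np.full_like(tiny_dataset.expression, np.inf))
        graph = build_knn_graph(bad.coordinates, 2)
        cfg = RunConfig(seed=0, n_epochs=1, episodes_per_epoch=5,
                        n_way=2, m_shot=2, q_query=2, k_clusters=3,
                        standardize_features=False, pca_components=None)
        with pytest.raises(FloatingPointError, match="diverged"):
            train(bad, graph, cfg, pseudo=pseudo)
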