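"""Pooling operators: set-function contracts, attention, contrastive training."""

import numpy as np
import pytest

from wsibpg.features import PatchBag
from wsibpg.pooling import (
    PoolingModel,
    TrainingConfig,
    _attention,
    _batch_grads,
    average_pool,
    contrastive_loss,
    hopfield_pool,
    init_pooling_model,
    load_pooling_model,
    save_pooling_model,
    train_pooling,
)
from wsibpg.retrieval import evaluate_retrieval
from wsibpg.synthetic import CohortSpec, generate_cohort


def _bag(X, sid="s"):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return PatchBag(sid, X, [f"p{i}" for i in range(X.shape[0])])


def _model(d=4, k=3, p=5, seed=0, beta=None):
    rng = np.random.default_rng(seed)
    return PoolingModel(
        query=rng.standard_normal(k),
        key_projection=rng.standard_normal((k, d)),
        value_projection=rng.standard_normal((p, d)),
        beta=beta if beta is not None else 1.0 / np.sqrt(k),
    )


class TestAveragePool:
    def test_repeated_vector_is_fixed_point(self):
        v = np.array([1.0, -2.0, 3.0])
        out = average_pool(_bag(np.tile(v, (6, 1))))
        np.testing.assert_allclose(out.vector, v)

    def test_elementwise_mean(self):
        out = average_pool(_bag([[0.0, 2.0], [2.0, 0.0]]))
        np.testing.assert_allclose(out.vector, [1.0, 1.0])

    def test_permutation_invariant(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((20, 6))
        base = average_pool(_bag(X)).vector
        for _ in range(20):
            perm = rng.permutation(20)
            np.testing.assert_allclose(
                average_pool(_bag(X[perm])).vector, base, atol=1e-12
            )


class TestHopfieldPool:
    def test_single_patch_is_projection(self):
        model = _model()
        x = np.array([1.0, 2.0, -1.0, 0.5])
        out = hopfield_pool(model, _bag(x))
        np.testing.assert_allclose(out.vector, model.value_projection @ x)

    def test_small_beta_limit_is_projected_average(self):
        model = _model(beta=1e-12)
        rng = np.random.default_rng(1)
        X = rng.standard_normal((15, 4))
        out = hopfield_pool(model, _bag(X))
        np.testing.assert_allclose(
            out.vector, (model.value_projection @ X.T).mean(axis=1), atol=1e-8
        )

    def test_attention_is_probability_vector(self):
        model = _model()
        rng = np.random.default_rng(2)
        alpha, _ = _attention(model, rng.standard_normal((30, 4)))
        assert alpha.sum() == pytest.approx(1.0)
        assert (alpha >= 0).all()

    def test_permutation_invariant(self):
        model = _model()
        rng = np.random.default_rng(3)
        X = rng.standard_normal((20, 4))
        base = hopfield_pool(model, _bag(X)).vector
        for _ in range(20):
            perm = rng.permutation(20)
            np.testing.assert_allclose(
                hopfield_pool(model, _bag(X[perm])).vector, base, atol=1e-12
            )

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            hopfield_pool(_model(d=4), _bag(np.ones((3, 7))))


class TestGradients:
    def test_closed_form_matches_finite_differences(self):
        """Backprop through attention, projection, normalization and the
        contrastive loss agrees with central finite differences."""
        rng = np.random.default_rng(5)
        model = _model(d=5, k=3, p=4, seed=6)
        bags = [_bag(rng.standard_normal((n, 5)), f"s{i}")
                for i, n in enumerate([3, 4, 2, 5])]
        labels = np.array(["a", "a", "b", "b"], dtype=object)
        tau = 0.2
        _, gq, gK, gV = _batch_grads(model, bags, labels, tau)

        def loss_with(param, name):
            m = model.copy()
            setattr(m, name, param)
            return contrastive_loss(m, bags, labels, tau)

        eps = 1e-6
        for name, grad in (("query", gq), ("key_projection", gK),
                           ("value_projection", gV)):
            base = getattr(model, name)
            num = np.zeros_like(base)
            it = np.nditer(base, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                plus = base.copy(); plus[idx] += eps
                minus = base.copy(); minus[idx] -= eps
                num[idx] = (loss_with(plus, name) - loss_with(minus, name)) / (2 * eps)
            np.testing.assert_allclose(grad, num, rtol=1e-4, atol=1e-7)


def _separable_bags(n_per_class=10, d=8, seed=0):
    rng = np.random.default_rng(seed)
    bags, labels = [], []
    for c, mean in enumerate([np.r_[3.0, np.zeros(d - 1)],
                              np.r_[0.0, 3.0, np.zeros(d - 2)]]):
        for i in range(n_per_class):
            X = mean + 0.5 * rng.standard_normal((12, d))
            bags.append(_bag(X, f"c{c}s{i}"))
            labels.append(f"class{c}")
    return bags, labels


class TestTraining:
    def test_zero_epochs_returns_initialized_model(self):
        bags, labels = _separable_bags(4)
        cfg = TrainingConfig(epochs=0, query_dim=3, seed=2)
        model = train_pooling(bags, labels, cfg)
        init = init_pooling_model(bags[0].dim, cfg)
        np.testing.assert_array_equal(model.query, init.query)
        np.testing.assert_array_equal(model.value_projection, init.value_projection)

    def test_single_class_rejected(self):
        bags, _ = _separable_bags(3)
        with pytest.raises(ValueError, match="two classes"):
            train_pooling(bags, ["same"] * len(bags), TrainingConfig(epochs=1))

    def test_deterministic_under_fixed_seed(self):
        bags, labels = _separable_bags(5)
        cfg = TrainingConfig(epochs=3, query_dim=4, seed=9)
        a = train_pooling(bags, labels, cfg)
        b = train_pooling(bags, labels, cfg)
        np.testing.assert_array_equal(a.query, b.query)
        np.testing.assert_array_equal(a.key_projection, b.key_projection)
        np.testing.assert_array_equal(a.value_projection, b.value_projection)
        assert a.loss_history == b.loss_history

    def test_training_reduces_contrastive_loss(self):
        bags, labels = _separable_bags(10)
        cfg = TrainingConfig(epochs=15, query_dim=4, seed=1, lr=5e-3)
        before = contrastive_loss(init_pooling_model(bags[0].dim, cfg), bags, labels)
        model = train_pooling(bags, labels, cfg)
        after = contrastive_loss(model, bags, labels)
        assert after < before

    def test_embeddings_separate_classes_on_held_out_slides(self):
        bags, labels = _separable_bags(12, seed=3)
        # first 12 bags are class 0, last 12 class 1: hold out 4 of each
        keep = list(range(8)) + list(range(12, 20))
        hold = list(range(8, 12)) + list(range(20, 24))
        train_b = [bags[i] for i in keep]
        train_l = [labels[i] for i in keep]
        test_b = [bags[i] for i in hold]
        test_l = [labels[i] for i in hold]
        cfg = TrainingConfig(epochs=20, query_dim=4, seed=4, lr=5e-3)
        model = train_pooling(train_b, train_l, cfg)
        Z = np.stack([hopfield_pool(model, b).vector for b in test_b])
        Z /= np.linalg.norm(Z, axis=1, keepdims=True)
        sims = Z @ Z.T
        same = np.equal.outer(test_l, test_l)
        np.fill_diagonal(same, False)
        off = ~np.eye(len(test_b), dtype=bool)
        intra = sims[same].mean()
        inter = sims[off & ~same].mean()
        assert intra > inter


def test_trained_pooling_does_not_hurt_retrieval():
    """Contrastive training should not degrade retrieval quality relative to
    the randomly initialized pooler (20 slides per class)."""
    spec = CohortSpec(
        n_slides=120, feature_dim=32, bag_size_range=(20, 40),
        noise_fraction_range=(0.3, 0.5), seed=13,
    )
    cohort = generate_cohort(spec)
    labels = cohort.labels_by_slide
    cfg = TrainingConfig(epochs=10, query_dim=16, seed=5)
    untrained = init_pooling_model(32, cfg)
    trained = train_pooling(cohort.bags, cohort.slide_labels, cfg)
    map_untrained = evaluate_retrieval(
        [hopfield_pool(untrained, b) for b in cohort.bags], labels
    )
    map_trained = evaluate_retrieval(
        [hopfield_pool(trained, b) for b in cohort.bags], labels
    )
    assert map_trained >= map_untrained


def test_model_round_trip(tmp_path):
    bags, labels = _separable_bags(4)
    cfg = TrainingConfig(epochs=2, query_dim=3, seed=0)
    model = train_pooling(bags, labels, cfg)
    save_pooling_model(model, tmp_path / "hp")
    loaded = load_pooling_model(tmp_path / "hp")
    np.testing.assert_array_equal(loaded.query, model.query)
    out_a = hopfield_pool(model, bags[0]).vector
    out_b = hopfield_pool(loaded, bags[0]).vector
    np.testing.assert_array_equal(out_a, out_b)
    assert loaded.training_config == cfg
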