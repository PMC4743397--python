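import numpy as np
import pytest

from cytoblock import classify as cl
from cytoblock.features import fit_normalizer


def two_clouds(n=50, sep=4.0, dim=11, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 0.5, (n, dim))
    b = rng.normal(sep, 0.5, (n, dim))
    X = np.vstack([a, b])
    y = np.array([1] * n + [-1] * n)
    return X, y


class TestKernel:
    def test_published_width_maps_to_gamma_005(self):
        np.testing.assert_allclose(cl.g_to_gamma(3.1623), 0.05, rtol=1e-4)

    def test_unit_diagonal_symmetry_and_psd(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 11))
        K = cl.rbf_kernel(X, X, g=1.7)
        np.testing.assert_allclose(np.diag(K), 1.0)
        np.testing.assert_allclose(K, K.T)
        assert np.linalg.eigvalsh(K).min() >= -1e-8


class TestTrainPredict:
    def test_separable_clouds_reach_perfect_training_accuracy(self):
        X, y = two_clouds()
        model = cl.train(X, y, c=10.0, g=3.1623)
        assert (cl.predict(model, X) == y).all()

    def test_support_vector_predicts_own_label(self):
        X, y = two_clouds(seed=1)
        model = cl.train(X, y)
        sv = model.support_vectors[0]
        idx = np.flatnonzero((X == sv).all(axis=1))[0]
        assert cl.predict(model, sv[None, :])[0] == y[idx]

    def test_far_point_gets_sign_of_bias(self):
        X, y = two_clouds(seed=2)
        model = cl.train(X, y)
        far = np.full((1, X.shape[1]), 1e6)
        expected = 1 if model.bias >= 0 else -1
        assert cl.predict(model, far)[0] == expected

    def test_duplicated_training_set_keeps_decision_function(self):
        X, y = two_clouds(n=25, seed=3)
        rng = np.random.default_rng(4)
        probe = rng.normal(1.5, 2.0, (40, X.shape[1]))
        base = cl.decision_function(cl.train(X, y), probe)
        doubled = cl.decision_function(
            cl.train(np.vstack([X, X]), np.concatenate([y, y])), probe
        )
        np.testing.assert_allclose(np.sign(base), np.sign(doubled))
        np.testing.assert_allclose(base, doubled, rtol=1e-3, atol=1e-6)

    def test_single_class_rejected(self):
        X = np.zeros((10, 11))
        with pytest.raises(ValueError):
            cl.train(X, np.ones(10))

    def test_bad_labels_rejected(self):
        X, _ = two_clouds(n=5)
        with pytest.raises(ValueError):
            cl.train(X, np.array([0, 1] * 5))

    def test_wrong_dimensionality_rejected(self):
        X, y = two_clouds(n=12)
        model = cl.train(X, y)
        with pytest.raises(ValueError):
            cl.predict(model, np.zeros((3, 5)))

    def test_zero_decision_value_maps_to_normal(self):
        model = cl.TrainedModel(
            support_vectors=np.zeros((1, 2)), dual_coef=np.zeros(1), bias=0.0,
            c=1.0, g=1.0,
        )
        assert cl.predict(model, np.zeros((1, 2)))[0] == 1


class TestSerialization:
    def test_round_trip_is_bit_identical(self, tmp_path):
        X, y = two_clouds(seed=5)
        norm = fit_normalizer(X)
        model = cl.train(norm.transform(X), y, normalization=norm)
        path = tmp_path / "model.json"
        cl.save_model(model, path)
        loaded = cl.load_model(path)
        rng = np.random.default_rng(6)
        probe = rng.normal(0.5, 1.0, (30, X.shape[1]))
        np.testing.assert_array_equal(
            cl.decision_function(model, probe), cl.decision_function(loaded, probe)
        )
        np.testing.assert_array_equal(
            cl.predict(model, probe, prenormalized=False),
            cl.predict(loaded, probe, prenormalized=False),
        )

    def test_foreign_file_rejected(self, tmp_path):
        path = tmp_path / "junk.json"
        path.write_text('{"format": "something-else"}')
        with pytest.raises(ValueError):
            cl.load_model(path)


class TestGridSearch:
    def test_single_point_grid_returns_it(self):
        X, y = two_clouds(n=20, seed=7)
        res = cl.grid_search(X, y, folds=2, log10_c_range=(1.0, 1.0),
                             log10_g_range=(0.5, 0.5), step=0.25, seed=0)
        np.testing.assert_allclose(res.best_c, 10.0)
        np.testing.assert_allclose(res.best_g, 10**0.5)

    def test_separable_data_reaches_perfect_cv(self):
        X, y = two_clouds(n=30, seed=8)
        res = cl.grid_search(X, y, folds=3, log10_c_range=(-1, 2),
                             log10_g_range=(-1, 1), step=1.0, seed=0)
        assert res.best_accuracy == 1.0
        assert res.accuracy.max() == res.best_accuracy

    def test_default_grid_covers_published_optimum(self):
        lc = np.arange(cl.DEFAULT_LOG10_C[0], cl.DEFAULT_LOG10_C[1] + 0.125, cl.DEFAULT_GRID_STEP)
        lg = np.arange(cl.DEFAULT_LOG10_G[0], cl.DEFAULT_LOG10_G[1] + 0.125, cl.DEFAULT_GRID_STEP)
        assert any(np.isclose(lc, 1.0))    # c = 10
        assert any(np.isclose(lg, 0.5))    # g = 3.1623

    def test_cv_accuracy_invariant_to_sample_order(self):
        X, y = two_clouds(n=25, sep=1.0, seed=9)
        rng = np.random.default_rng(10)
        perm = rng.permutation(len(y))
        a = cl.cv_accuracy(X, y, c=1.0, g=1.0, folds=5, seed=3)
        b = cl.cv_accuracy(X[perm], y[perm], c=1.0, g=1.0, folds=5, seed=3)
        assert a == b

    def test_tie_break_prefers_smaller_c_then_g(self):
        X, y = two_clouds(n=30, seed=11)  # separable: many grid points tie at 1.0
        res = cl.grid_search(X, y, folds=3, log10_c_range=(0, 1),
                             log10_g_range=(0, 1), step=1.0, seed=0)
        ties = np.argwhere(res.accuracy == res.best_accuracy)
        first = ties[np.lexsort((ties[:, 1], ties[:, 0]))][0]
        np.testing.assert_allclose(res.best_c, 10.0 ** res.log10_c[first[0]])
        np.testing.assert_allclose(res.best_g, 10.0 ** res.log10_g[first[1]])

    def test_insufficient_class_size_rejected(self):
        X, y = two_clouds(n=4)
        with pytest.raises(ValueError, match="fold"):
            cl.grid_search(X, y, folds=10)
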