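"""Component extraction, deflation, diagnostics, and the stopping rule."""

import numpy as np
import pytest
from scipy.linalg import eig

from kernelpls import (
    KernelPLS,
    KernelSpec,
    KplsConfig,
    center_gram,
    compute_gram,
    deflate,
    encode_labels,
    extract_component,
    fisher_ratio,
    fit_components,
    rd_contribution,
)
from kernelpls.pls import SignalExhausted

from primal_pls import one_hot_centered, rd_oracle


class TestEncodeLabels:
    def test_balanced_two_class(self):
        ind = encode_labels(["A", "A", "B", "B"])
        assert ind.values.shape == (4, 2)
        np.testing.assert_allclose(ind.values.sum(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(np.abs(ind.values), 0.5)

    def test_three_balanced_classes(self):
        ind = encode_labels(["A", "B", "C"] * 2)
        assert ind.values.shape == (6, 3)
        np.testing.assert_allclose(ind.values.sum(axis=0), 0.0, atol=1e-12)
        assert ind.classes == ["A", "B", "C"]

    def test_unbalanced_column_centering(self):
        # centering [1,1,1,0,0] gives [0.4, 0.4, 0.4, -0.6, -0.6]
        ind = encode_labels(["A", "A", "A", "B", "B"])
        np.testing.assert_allclose(ind.values[:, 0], [0.4, 0.4, 0.4, -0.6, -0.6])

    def test_rejects_single_class(self):
        with pytest.raises(ValueError, match="2 distinct classes"):
            encode_labels(["A", "A", "A"])

    def test_rejects_singleton_class(self):
        with pytest.raises(ValueError, match="fewer than 2 samples"):
            encode_labels(["A", "A", "A", "B"])


class TestExtractComponent:
    def test_two_class_fixed_point_is_immediate(self, rng):
        # rank-1 Y: t = normalize(K y_centered) after the first pass
        X = rng.normal(size=(8, 5))
        K = center_gram(compute_gram(X, KernelSpec("linear"))).values
        ind = encode_labels(["a"] * 4 + ["b"] * 4)
        comp = extract_component(K, ind.values, KplsConfig())
        assert comp.n_iter <= 2
        y = ind.values[:, 0]
        expected = K @ (y / np.linalg.norm(y))
        expected /= np.linalg.norm(expected)
        sign = np.sign(expected @ comp.t)
        np.testing.assert_allclose(comp.t, sign * expected, atol=1e-10)

    def test_score_is_unit_norm(self, three_class_toy):
        X, labels = three_class_toy
        K = center_gram(compute_gram(X, KernelSpec("rbf"))).values
        comp = extract_component(K, encode_labels(labels).values, KplsConfig())
        assert np.linalg.norm(comp.t) == pytest.approx(1.0, abs=1e-10)

    def test_matches_dominant_eigenvector_oracle(self, rng):
        # 6-sample 3-class instance against dense eigendecomposition of K Y Y'
        X = rng.normal(size=(6, 4))
        K = center_gram(compute_gram(X, KernelSpec("rbf"))).values
        Y = encode_labels(["a", "a", "b", "b", "c", "c"]).values
        comp = extract_component(K, Y, KplsConfig())
        w, V = eig(K @ Y @ Y.T)
        v = np.real(V[:, np.argmax(np.real(w))])
        v /= np.linalg.norm(v)
        diff = min(np.abs(comp.t - v).max(), np.abs(comp.t + v).max())
        assert diff < 1e-6

    def test_exhausted_response_signals(self, rng):
        K = np.eye(5)
        with pytest.raises(SignalExhausted):
            extract_component(K, np.zeros((5, 2)), KplsConfig())


class TestDeflate:
    def test_projector_idempotence(self, rng):
        K = rng.normal(size=(6, 6))
        K = K @ K.T
        Y = rng.normal(size=(6, 2))
        t = rng.normal(size=6)
        t /= np.linalg.norm(t)
        K1, Y1 = deflate(K, Y, t)
        K2, Y2 = deflate(K1, Y1, t)
        np.testing.assert_allclose(K1, K2, atol=1e-10)
        np.testing.assert_allclose(Y1, Y2, atol=1e-12)

    def test_t_orthogonal_to_deflated_response(self, rng):
        Y = rng.normal(size=(7, 3))
        t = rng.normal(size=7)
        t /= np.linalg.norm(t)
        _, Y1 = deflate(np.eye(7), Y, t)
        np.testing.assert_allclose(t @ Y1, 0.0, atol=1e-12)

    def test_identity_kernel_elementary_direction(self):
        # (I - e1 e1') I (I - e1 e1'): first row/col zeroed, rest identity
        t = np.zeros(4)
        t[0] = 1.0
        K1, _ = deflate(np.eye(4), np.zeros((4, 1)), t)
        expected = np.eye(4)
        expected[0, 0] = 0.0
        np.testing.assert_allclose(K1, expected, atol=1e-15)

    def test_t_in_nullspace_of_deflated_kernel(self, rng):
        K = rng.normal(size=(8, 8))
        K = K @ K.T
        t = rng.normal(size=8)
        t /= np.linalg.norm(t)
        K1, _ = deflate(K, np.zeros((8, 1)), t)
        assert np.linalg.norm(K1 @ t) < 1e-8


class TestRdContribution:
    def test_perfectly_aligned_score_gives_one(self):
        ind = encode_labels(["a"] * 5 + ["b"] * 5)
        t = ind.values[:, 0] / np.linalg.norm(ind.values[:, 0])
        assert rd_contribution(t, ind.values) == pytest.approx(1.0)

    def test_orthogonal_uncorrelated_score_gives_zero(self):
        Y = encode_labels(["a", "a", "b", "b"]).values
        t = np.array([1.0, -1.0, 1.0, -1.0]) / 2.0  # orthogonal to both columns
        assert rd_contribution(t, Y) == pytest.approx(0.0, abs=1e-15)

    def test_matches_per_column_pearson_oracle(self, rng):
        Y = encode_labels(["a", "a", "b", "b", "c", "c"]).values
        t = rng.normal(size=6)
        assert rd_contribution(t, Y) == pytest.approx(rd_oracle(t, Y), abs=1e-12)

    def test_zero_variance_score_warns_and_returns_zero(self):
        Y = encode_labels(["a", "a", "b", "b"]).values
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            assert rd_contribution(np.ones(4), Y) == 0.0


class TestFisherRatio:
    def test_perfect_separation_is_infinite(self):
        assert fisher_ratio([-1, -1, 1, 1], ["0", "0", "1", "1"]) == np.inf

    def test_identical_class_means_give_zero(self):
        assert fisher_ratio([1.0, -1.0, 1.0, -1.0], ["a", "a", "b", "b"]) == 0.0

    def test_hand_computed_scatter(self):
        # between = 2*(0.5-1.5)^2 + 2*(2.5-1.5)^2 = 4; within = 0.5+0.5 = 1
        assert fisher_ratio([0.0, 1.0, 2.0, 3.0], ["0", "0", "1", "1"]) == (
            pytest.approx(4.0)
        )


class TestFitComponents:
    @pytest.mark.parametrize("kernel", ["linear", "rbf", "polynomial"])
    def test_separable_data_discriminates(self, two_class_toy, kernel):
        X, labels = two_class_toy
        cset, _, _ = fit_components(X, labels, KernelSpec(kernel))
        assert cset.kappa >= 1
        assert cset.components[0].fisher_j > 0
        assert cset.components[0].rd > 0.5

    @pytest.mark.parametrize("kernel", ["linear", "rbf", "polynomial"])
    def test_scores_pairwise_orthonormal(self, three_class_toy, kernel):
        X, labels = three_class_toy
        cset, _, _ = fit_components(
            X, labels, KernelSpec(kernel), KplsConfig(lambda_rel=1e-12)
        )
        T = cset.scores()
        G = T.T @ T
        np.testing.assert_allclose(G, np.eye(T.shape[1]), atol=1e-8)

    def test_deflation_exactness(self, three_class_toy):
        # span{t_1..t_h} orthogonal to the residual K and Y after fitting
        X, labels = three_class_toy
        K = center_gram(compute_gram(X, KernelSpec("rbf"))).values
        Y = encode_labels(labels).values
        cset, _, _ = fit_components(
            X, labels, KernelSpec("rbf"), KplsConfig(lambda_rel=1e-12)
        )
        norms = []
        for comp in cset.components:
            norms.append(np.linalg.norm(Y))
            K, Y = deflate(K, Y, comp.t)
            assert np.linalg.norm(K @ comp.t) < 1e-8
            assert np.abs(comp.t @ Y).max() < 1e-8
        # monotone exhaustion of the response residual
        norms.append(np.linalg.norm(Y))
        assert all(b <= a + 1e-12 for a, b in zip(norms, norms[1:]))

    def test_permuted_label_null_keeps_few_components(self):
        # stopping rule terminates early when labels carry no signal
        kappas = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(30, 100))
            labels = rng.permutation(np.array(["a"] * 15 + ["b"] * 15))
            cset, _, _ = fit_components(X, labels, KernelSpec("rbf"))
            kappas.append(cset.kappa)
        assert np.median(kappas) <= 2

    def test_fit_is_deterministic(self, two_class_toy):
        X, labels = two_class_toy
        a = KernelPLS(kernel="rbf").fit(X, labels)
        b = KernelPLS(kernel="rbf").fit(X, labels)
        assert np.array_equal(a.scores_, b.scores_)
        assert np.array_equal(a.rd_, b.rd_)

    def test_retained_fisher_ratios_respect_threshold(self, three_class_toy):
        X, labels = three_class_toy
        model = KernelPLS(kernel="linear", lambda_rel=0.05).fit(X, labels)
        finite = model.fisher_j_[np.isfinite(model.fisher_j_)]
        if finite.size:
            assert (model.fisher_j_ >= 0.05 * finite.max() - 1e-12).all() or (
                ~np.isfinite(model.fisher_j_)
            ).any()

    def test_rejects_tiny_sample(self):
        with pytest.raises(ValueError, match="at least 4 samples"):
            fit_components(np.ones((3, 2)), ["a", "a", "b"], KernelSpec("linear"))


class TestSklearnContract:
    def test_get_set_params_roundtrip(self):
        est = KernelPLS(kernel="linear", lambda_rel=0.1)
        params = est.get_params()
        assert params["lambda_rel"] == 0.1
        est2 = KernelPLS().set_params(**params)
        assert est2.kernel == "linear"

    def test_transform_returns_scores(self, two_class_toy):
        X, labels = two_class_toy
        model = KernelPLS(kernel="linear").fit(X, labels)
        assert model.transform().shape == (X.shape[0], model.n_components_)
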