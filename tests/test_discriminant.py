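"""Scatter matrices and the two-stage (PCA-then-LDA) discriminant."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enosekit import discriminant, eigenodour
from enosekit.discriminant import DiscriminantError
from oracles import naive_scatter


class TestScatterMatrices:
    def test_single_class_has_zero_between_scatter(self, rng):
        X = rng.normal(size=(6, 3))
        S_B, S_W, S_T = discriminant.scatter_matrices(X, ["a"] * 6)
        assert np.allclose(S_B, 0.0)
        assert np.allclose(S_W, S_T)

    def test_hand_arithmetic_1d(self):
        X = np.array([[0.0], [0.0], [2.0], [2.0]])
        S_B, S_W, S_T = discriminant.scatter_matrices(X, ["a", "a", "b", "b"])
        assert S_B[0, 0] == pytest.approx(4.0)
        assert S_W[0, 0] == pytest.approx(0.0)
        assert S_T[0, 0] == pytest.approx(4.0)

    def test_matches_naive_double_loop(self, rng):
        X = rng.normal(size=(30, 4))
        labels = list(rng.choice(["x", "y", "z"], size=30))
        S_B, S_W, S_T = discriminant.scatter_matrices(X, labels)
        nB, nW, nT = naive_scatter(X, labels)
        assert np.allclose(S_B, nB, atol=1e-10)
        assert np.allclose(S_W, nW, atol=1e-10)
        assert np.allclose(S_T, nT, atol=1e-10)
        assert np.allclose(S_T, S_B + S_W, atol=1e-10)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_scatter_decomposition_identity(self, seed):
        g = np.random.default_rng(seed)
        M = int(g.integers(4, 25))
        p = int(g.integers(1, 6))
        X = g.normal(size=(M, p)) * g.uniform(0.1, 10)
        labels = list(g.integers(0, min(3, M - 1), size=M))
        S_B, S_W, S_T = discriminant.scatter_matrices(X, labels)
        assert np.linalg.norm(S_T - (S_B + S_W)) <= 1e-8 * max(
            np.linalg.norm(S_T), 1e-30
        )
        for S in (S_B, S_W, S_T):
            assert np.allclose(S, S.T)
            assert np.linalg.eigvalsh(S).min() >= -1e-8 * max(
                np.linalg.norm(S), 1.0
            )


class TestFitDiscriminant:
    def test_two_class_direction_matches_fisher_closed_form(self, rng):
        # two well-separated spherical Gaussians in 5-D: the single
        # discriminant direction is parallel to S_W^{-1} (mu1 - mu2)
        X = np.vstack([
            rng.normal(0.0, 1.0, size=(40, 5)),
            rng.normal(0.0, 1.0, size=(40, 5)) + np.array([8, 0, 0, 0, 0]),
        ])
        labels = ["a"] * 40 + ["b"] * 40
        model = discriminant.fit_discriminant(X, labels, p=5, q=1)
        scores = eigenodour.project(model.eigen, X)
        _, S_W, _ = discriminant.scatter_matrices(scores, labels)
        mu1 = scores[:40].mean(axis=0)
        mu2 = scores[40:].mean(axis=0)
        w_closed = np.linalg.solve(S_W, mu1 - mu2)
        w = model.w_lda[:, 0]
        cos = abs(w @ w_closed) / (
            np.linalg.norm(w) * np.linalg.norm(w_closed)
        )
        assert cos > 0.999

    def test_identical_class_means_give_zero_eigenvalues(self, rng):
        base = rng.normal(size=(10, 4))
        X = np.vstack([base, base, base])  # three classes, same mean cloud
        labels = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        model = discriminant.fit_discriminant(X, labels, p=4)
        assert np.all(model.eigenvalues < 1e-6)

    def test_lda_improves_fisher_ratio_over_pca_space(self, small_dataset):
        _, labels, raw = small_dataset
        from enosekit import preprocess

        rm = preprocess.autoscale(raw, labels)
        model = discriminant.fit_discriminant(rm.values, labels)
        scores = eigenodour.project(model.eigen, rm.values)
        Z = scores @ model.w_lda
        bZ, wZ, _ = discriminant.scatter_matrices(Z, labels)
        bS, wS, _ = discriminant.scatter_matrices(scores, labels)
        ratio_lda = np.trace(bZ) / np.trace(wZ)
        ratio_pca = np.trace(bS) / np.trace(wS)
        assert ratio_lda > ratio_pca

    def test_rank_bound_violations_rejected(self, rng):
        X = rng.normal(size=(12, 20))
        labels = list("aaaabbbbcccc")
        with pytest.raises(DiscriminantError, match="singular"):
            discriminant.fit_discriminant(X, labels, p=10)  # p > M - c = 9
        with pytest.raises(DiscriminantError, match="c - 1"):
            discriminant.fit_discriminant(X, labels, q=3)

    def test_generalized_eigenvalues_nonnegative_descending(self, small_dataset):
        _, labels, raw = small_dataset
        from enosekit import preprocess

        rm = preprocess.autoscale(raw, labels)
        model = discriminant.fit_discriminant(rm.values, labels)
        assert np.all(model.eigenvalues >= 0)
        assert np.all(np.diff(model.eigenvalues) <= 1e-9)
        assert model.w_lda.shape[1] <= len(model.class_labels) - 1


class TestTransform:
    def test_mean_maps_to_zero(self, rng):
        X = rng.normal(size=(12, 20))
        labels = list("aaaabbbbcccc")
        model = discriminant.fit_discriminant(X, labels, p=6)
        assert np.allclose(
            discriminant.transform(model, model.eigen.mean), 0.0, atol=1e-10
        )

    def test_composition_equals_staged_application(self, rng):
        X = rng.normal(size=(15, 25))
        labels = list(rng.choice(["a", "b", "c"], size=15))
        model = discriminant.fit_discriminant(X, labels, p=8)
        probes = rng.normal(size=(100, 25))
        direct = discriminant.transform(model, probes)
        staged = eigenodour.project(model.eigen, probes) @ model.w_lda
        assert np.allclose(direct, staged, atol=1e-10)

    def test_classes_separate_along_every_direction_without_noise(self):
        from enosekit import preprocess, simulate

        cfg = simulate.dataset1_config(seed=11, n_sensors=96, noise_sd=0.0,
                                       concentration_jitter=0.02)
        recs, labels = simulate.simulate_dataset(cfg, simulate.DATASET1_DESIGN)
        raw = preprocess.build_response_matrix(recs, scale=False)
        rm = preprocess.autoscale(raw, labels)
        model = discriminant.fit_discriminant(rm.values, labels)
        Z = discriminant.transform(model, rm.values)
        bZ, wZ, _ = discriminant.scatter_matrices(Z, labels)
        # per retained direction, between-class variance dominates within
        assert np.all(np.diag(bZ)[0] > np.diag(wZ)[0])
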