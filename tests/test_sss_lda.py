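import numpy as np
import pytest

import oracles
from nirdisc.sss_lda import (
    ExtractorNotApplicableError,
    ProjectionModel,
    compute_scatter,
    fit_alda,
    fit_clda,
    fit_extractor,
    fit_mlda,
    fit_nlda,
    principal_angles,
    project,
)

RNG_SEEDS = list(range(20))


def well_separated(rng, n_per_class=30, p=4, K=3, spread=8.0):
    """Nonsingular (n >> p), well-separated Gaussian classes."""
    return oracles.random_sss_instance(rng, p, n_per_class, K, spread=spread)


class TestScatter:
    def test_hand_listed_oracle(self):
        X = np.array(
            [[0.0, 0.0], [1.0, 1.0], [2.0, 0.0],
             [5.0, 5.0], [6.0, 7.0], [7.0, 6.0]]
        )
        y = ["a", "a", "a", "b", "b", "b"]
        s = compute_scatter(X, y)
        Sw, Sb, St = oracles.scatter_double_loop(X, y)
        assert np.allclose(s.Sw, Sw, atol=1e-12)
        assert np.allclose(s.Sb, Sb, atol=1e-12)
        assert np.allclose(s.St, St, atol=1e-12)

    def test_decomposition_and_psd(self):
        rng = np.random.default_rng(0)
        X, y = oracles.random_sss_instance(rng, p=8, n_per_class=5, K=3)
        s = compute_scatter(X, y)
        norm = np.linalg.norm(s.St)
        assert np.allclose(s.St, s.Sw + s.Sb, atol=1e-6 * norm)
        for M in (s.Sw, s.Sb, s.St):
            assert np.allclose(M, M.T, atol=1e-8)
            assert np.linalg.eigvalsh(M).min() > -1e-8 * norm

    def test_one_sample_per_class_zero_within(self):
        X = np.array([[0.0, 1.0], [2.0, 3.0], [4.0, 0.0]])
        s = compute_scatter(X, ["a", "b", "c"])
        assert np.allclose(s.Sw, 0.0)

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="2 classes"):
            compute_scatter(np.eye(3), ["a", "a", "a"])


class TestALDA:
    def test_equals_fisher_on_nonsingular_data(self):
        rng = np.random.default_rng(1)
        X, y = well_separated(rng)
        model = fit_alda(X, y, d=2)
        W_ref = oracles.fisher_lda_dense(X, y, 2)
        assert oracles.subspace_angle(model.W, W_ref) < 1e-6
        assert model.diagnostics["n_replaced"] == 0

    def test_isotropic_within_scatter_gives_between_eigvecs(self):
        # two classes, within-class deviations +-e1, +-e2 -> Sw = c*I
        muA, muB = np.array([0.0, 0.0]), np.array([10.0, 4.0])
        devs = np.array([[1.0, 0], [-1.0, 0], [0, 1.0], [0, -1.0]])
        X = np.vstack([muA + devs, muB + devs])
        y = ["a"] * 4 + ["b"] * 4
        model = fit_alda(X, y, d=1)
        s = compute_scatter(X, y)
        assert np.allclose(s.Sw, s.Sw[0, 0] * np.eye(2))
        top_sb = np.linalg.eigh(s.Sb)[1][:, -1]
        assert oracles.subspace_angle(model.W, top_sb[:, None]) < 1e-6

    def test_alpha_equals_independent_svd(self):
        rng = np.random.default_rng(2)
        X, y = oracles.random_sss_instance(rng, p=20, n_per_class=3, K=3)
        model = fit_alda(X, y)
        # independent: reduce to range(St) densely, SVD the reduced Sw
        mu = X.mean(axis=0)
        _, _, St = oracles.scatter_double_loop(X, y)
        w_t, V_t = np.linalg.eigh(St)
        Ut = V_t[:, w_t > 1e-10 * w_t.max()]
        Sw_h, _, _ = oracles.scatter_double_loop((X - mu) @ Ut, y)
        alpha_ref = np.sqrt(np.linalg.svd(Sw_h, compute_uv=False).max())
        assert model.diagnostics["alpha"] == pytest.approx(alpha_ref, rel=1e-8)

    @pytest.mark.parametrize("seed", RNG_SEEDS)
    def test_matches_dense_step_list_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X, y = oracles.random_sss_instance(rng, p=20, n_per_class=3, K=3)
        model = fit_alda(X, y, d=2)
        W_ref = oracles.alda_dense(X, y, 2)
        assert oracles.subspace_angle(model.W, W_ref) < 1e-6


class TestCLDA:
    @pytest.mark.parametrize("seed", RNG_SEEDS[:5])
    def test_common_vector_theorem(self, seed):
        """Every sample of a class has the same null-space image."""
        rng = np.random.default_rng(seed)
        X, y = oracles.random_sss_instance(rng, p=30, n_per_class=4, K=3)
        model = fit_clda(X, y)
        Sw, _, _ = oracles.scatter_double_loop(X, y)
        w, V = np.linalg.eigh(Sw)
        Q = V[:, w > 1e-9 * w.max()]
        for cls in np.unique(np.asarray(y)):
            Xc = X[np.asarray(y) == cls]
            com = Xc - (Xc @ Q) @ Q.T
            dists = np.linalg.norm(com[:, None, :] - com[None, :, :], axis=-1)
            assert dists.max() < 1e-6

    def test_two_singleton_classes_difference_direction(self):
        X = np.array([[1.0, 0.0, 0.0], [0.0, 2.0, 0.0]])
        model = fit_clda(X, ["a", "b"])
        direction = (X[0] - X[1]) / np.linalg.norm(X[0] - X[1])
        assert oracles.subspace_angle(model.W, direction[:, None]) < 1e-10
        assert model.d == 1

    def test_projected_training_data_has_zero_within_class_variance(self):
        rng = np.random.default_rng(3)
        X, y = oracles.random_sss_instance(rng, p=30, n_per_class=4, K=3)
        model = fit_clda(X, y)
        Z = project(model, X)
        for cls in np.unique(np.asarray(y)):
            assert Z[np.asarray(y) == cls].std(axis=0).max() < 1e-8
        # nearest projected common vector classifies training data perfectly
        coms = project(model, np.stack(model.diagnostics["common_vectors"]))
        pred = np.argmin(
            np.linalg.norm(Z[:, None, :] - coms[None, :, :], axis=-1), axis=1
        )
        classes = np.unique(np.asarray(y))
        assert np.all(classes[pred] == np.asarray(y))

    def test_not_applicable_on_nonsingular_data(self):
        rng = np.random.default_rng(4)
        X, y = well_separated(rng)
        with pytest.raises(ExtractorNotApplicableError):
            fit_clda(X, y)


class TestMLDA:
    def test_equal_eigenvalues_reduce_to_fisher(self):
        # isotropic within-class scatter: clamping is the identity
        muA, muB, muC = (np.zeros(2), np.array([8.0, 1.0]), np.array([2.0, 9.0]))
        devs = np.array([[1.0, 0], [-1.0, 0], [0, 1.0], [0, -1.0]])
        X = np.vstack([muA + devs, muB + devs, muC + devs])
        y = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        model = fit_mlda(X, y, d=2)
        W_ref = oracles.fisher_lda_dense(X, y, 2)
        assert oracles.subspace_angle(model.W, W_ref) < 1e-6

    def test_clamping_floor_makes_sw_star_nonsingular(self):
        rng = np.random.default_rng(5)
        X, y = oracles.random_sss_instance(rng, p=10, n_per_class=3, K=3)
        n, K = X.shape[0], 3
        model = fit_mlda(X, y)
        lam_bar = model.diagnostics["lambda_bar"]
        # dense reconstruction of Sw*
        Sw, _, _ = oracles.scatter_double_loop(X, y)
        lam, V = np.linalg.eigh(Sw / (n - K))
        Sw_star = V @ np.diag(np.maximum(lam, lam.mean())) @ V.T * (n - K)
        assert np.linalg.eigvalsh(Sw_star).min() >= lam_bar * (n - K) - 1e-10
        assert lam_bar == pytest.approx(lam.mean(), rel=1e-9)

    @pytest.mark.parametrize("seed", RNG_SEEDS)
    def test_matches_dense_clamp_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        X, y = oracles.random_sss_instance(rng, p=10, n_per_class=3, K=3)
        model = fit_mlda(X, y, d=2)
        W_ref = oracles.mlda_dense(X, y, 2)
        assert oracles.subspace_angle(model.W, W_ref) < 1e-6

    def test_zero_within_scatter_errors(self):
        X = np.array([[0.0, 0], [0, 0], [1, 1], [1, 1]])
        with pytest.raises(ValueError):
            fit_mlda(X, ["a", "a", "b", "b"])


class TestNLDA:
    @pytest.mark.parametrize("seed", RNG_SEEDS[:5])
    def test_null_space_annihilation(self, seed):
        rng = np.random.default_rng(seed)
        X, y = oracles.random_sss_instance(rng, p=25, n_per_class=3, K=4)
        model = fit_nlda(X, y, d=3)
        Sw, _, _ = oracles.scatter_double_loop(X, y)
        assert np.abs(model.W.T @ Sw @ model.W).max() < 1e-8

    def test_zero_within_scatter_uses_between_eigvecs(self):
        X = np.array([[1.0, 0, 0, 0], [0, 2.0, 0, 0], [0, 0, 3.0, 0]])
        y = ["a", "b", "c"]
        model = fit_nlda(X, y, d=2)
        _, Sb, _ = oracles.scatter_double_loop(X, y)
        w, V = np.linalg.eigh(Sb)
        W_ref = V[:, np.argsort(w)[::-1][:2]]
        assert oracles.subspace_angle(model.W, W_ref) < 1e-8

    @pytest.mark.parametrize("seed", RNG_SEEDS)
    def test_matches_dense_null_space_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        X, y = oracles.random_sss_instance(rng, p=25, n_per_class=3, K=4)
        model = fit_nlda(X, y, d=3)
        W_ref = oracles.nlda_dense(X, y, 3)
        assert oracles.subspace_angle(model.W, W_ref) < 1e-6
        # orthonormal columns
        assert np.allclose(model.W.T @ model.W, np.eye(model.d), atol=1e-10)

    def test_full_rank_fallback_equals_fisher_subspace(self):
        rng = np.random.default_rng(6)
        X, y = well_separated(rng)
        model = fit_nlda(X, y, d=2)
        assert model.diagnostics.get("full_rank_fallback")
        W_ref = oracles.fisher_lda_dense(X, y, 2)
        assert oracles.subspace_angle(model.W, W_ref) < 1e-4


class TestProjectAndConventions:
    def test_projecting_grand_mean_gives_zero(self):
        rng = np.random.default_rng(7)
        X, y = oracles.random_sss_instance(rng, p=15, n_per_class=3, K=3)
        model = fit_nlda(X, y)
        assert np.allclose(project(model, X.mean(axis=0)), 0.0, atol=1e-10)

    def test_orthonormal_projection_is_contraction(self):
        rng = np.random.default_rng(8)
        X, y = oracles.random_sss_instance(rng, p=15, n_per_class=3, K=3)
        model = fit_nlda(X, y)
        Z = project(model, X)
        centered = X - model.grand_mean
        assert np.all(
            np.linalg.norm(Z, axis=1) <= np.linalg.norm(centered, axis=1) + 1e-10
        )

    def test_scores_equal_explicit_multiply(self):
        rng = np.random.default_rng(9)
        X, y = oracles.random_sss_instance(rng, p=15, n_per_class=3, K=3)
        for method in ("ALDA", "CLDA", "MLDA", "NLDA"):
            model = fit_extractor(method, X, y)
            Z = project(model, X)
            manual = np.array([(x - model.grand_mean) @ model.W for x in X])
            assert np.allclose(Z, manual, atol=1e-10)

    def test_deterministic_including_signs(self):
        rng = np.random.default_rng(10)
        X, y = oracles.random_sss_instance(rng, p=12, n_per_class=3, K=3)
        for method in ("ALDA", "CLDA", "MLDA", "NLDA"):
            W1 = fit_extractor(method, X, y).W
            W2 = fit_extractor(method, X, y).W
            assert np.array_equal(W1, W2)
            idx = np.argmax(np.abs(W1), axis=0)
            assert np.all(W1[idx, np.arange(W1.shape[1])] > 0)

    def test_dimension_mismatch_raises(self):
        rng = np.random.default_rng(11)
        X, y = oracles.random_sss_instance(rng, p=12, n_per_class=3, K=3)
        model = fit_nlda(X, y)
        with pytest.raises(ValueError, match="features"):
            project(model, np.zeros((2, 5)))


def test_all_fisher_equivalent_methods_agree_on_easy_data():
    """With nonsingular, exactly isotropic within-class scatter, ALDA,
    MLDA and NLDA's fallback all recover the classical Fisher subspace
    (MLDA's eigenvalue clamping is the identity only in that limit)."""
    rng = np.random.default_rng(12)
    p, K = 4, 3
    centers = rng.normal(scale=10.0, size=(K, p))
    devs = np.vstack([np.eye(p), -np.eye(p)])  # Sw = c*I exactly
    X = np.vstack([c + devs for c in centers])
    y = np.repeat([f"c{k}" for k in range(K)], 2 * p)
    W_ref = oracles.fisher_lda_dense(X, y, 2)
    for fitter in (fit_alda, fit_mlda, fit_nlda):
        model = fitter(X, y, d=2)
        assert oracles.subspace_angle(model.W, W_ref) < 1e-4


def test_default_components_is_n_classes_minus_one(default_data, default_plan):
    """On a default-size training fold every extractor returns K-1 = 4
    components, and the singular-scatter methods run without error."""
    tr = default_plan.assignments != 0
    X = default_data.absorbance[tr]
    y = default_data.labels[tr]
    for method in ("ALDA", "CLDA", "MLDA", "NLDA"):
        model = fit_extractor(method, X, y)
        assert model.d == 4
        assert model.W.shape == (1577, 4)
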