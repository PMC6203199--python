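"""Core scoring math: whitening, Mahalanobis length, cosine, score."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pines.scoring import (
    BackgroundModel,
    DegenerateModelError,
    UndefinedAngleError,
    WeightVector,
    cosine_to_ones,
    estimate_background_model,
    load_model,
    mahalanobis,
    pines_score,
    save_model,
    score_matrix,
    whiten,
)


def identity_model(d: int, mu: float = 0.0) -> BackgroundModel:
    """Model with Σ = I (k = d) and constant mean, built directly."""
    return BackgroundModel(
        variant_class="pooled",
        mu=np.full(d, mu),
        eigenvalues=np.ones(d),
        eigenvectors=np.eye(d),
        variance_explained=1.0,
    )


class TestEstimation:
    def test_full_rank_reconstruction(self, rng):
        X = (rng.random((60, 10)) < 0.4).astype(float)
        model = estimate_background_model(X, k=10)
        recon = (model.eigenvectors * model.eigenvalues) @ model.eigenvectors.T
        np.testing.assert_allclose(recon, np.cov(X, rowvar=False, ddof=1), atol=1e-8)

    def test_independent_bernoulli_eigenvalues(self):
        """iid Bernoulli(0.3) columns: every eigenvalue near p(1−p) = 0.21."""
        rng = np.random.default_rng(42)
        X = (rng.random((5000, 10)) < 0.3).astype(float)
        model = estimate_background_model(X, k=10)
        dense = np.sort(np.linalg.eigvalsh(np.cov(X, rowvar=False, ddof=1)))[::-1]
        np.testing.assert_allclose(model.eigenvalues, dense, atol=1e-10)
        assert np.all(np.abs(model.eigenvalues - 0.21) < 0.03)

    def test_variance_explained_monotone_in_k(self, rng):
        X = (rng.random((500, 25)) < 0.4).astype(float)
        fracs = [estimate_background_model(X, k=k).variance_explained for k in range(1, 26)]
        assert all(0 < f <= 1 + 1e-12 for f in fracs)
        assert np.all(np.diff(fracs) >= -1e-12)

    def test_constant_matrix_is_degenerate(self):
        with pytest.raises(DegenerateModelError):
            estimate_background_model(np.ones((50, 5)), k=3)

    def test_invalid_k(self, rng):
        X = (rng.random((50, 5)) < 0.4).astype(float)
        with pytest.raises(ValueError, match="k must be"):
            estimate_background_model(X, k=0)

    def test_missing_entries_imputed_to_column_mean(self, rng):
        X = (rng.random((200, 6)) < 0.4).astype(float)
        Xm = X.copy()
        Xm[5, 2] = np.nan
        model = estimate_background_model(Xm, k=6)
        # imputation uses the observed-column mean, so mu stays close
        assert abs(model.mu[2] - np.nanmean(Xm[:, 2])) < 1e-12

    def test_roundtrip_persistence(self, rng, tmp_path):
        X = (rng.random((100, 8)) < 0.4).astype(float)
        model = estimate_background_model(X, k=5)
        save_model(model, tmp_path / "m.npz")
        loaded = load_model(tmp_path / "m.npz")
        np.testing.assert_array_equal(loaded.eigenvectors, model.eigenvectors)
        assert loaded.variance_explained == model.variance_explained


class TestWhitening:
    def test_x_equals_mu_maps_to_zero(self, random_instance):
        _, model, _ = random_instance()
        np.testing.assert_allclose(whiten(model.mu, model), 0.0, atol=1e-12)

    def test_identity_covariance_preserves_unit_length(self):
        model = identity_model(4)
        z = whiten(np.eye(4)[0], model)
        assert np.linalg.norm(z) == pytest.approx(1.0)

    def test_quadratic_form_matches_dense_pseudo_inverse(self, random_instance, rng):
        X, model, oracle = random_instance(n=150, d=8)
        for _ in range(10):
            x = (rng.random(8) < 0.5).astype(float)
            w = rng.uniform(0.5, 3.0, 8)
            z = whiten(x, model, w)
            assert z @ z == pytest.approx(oracle.quad(x, x, w), abs=1e-8)

    def test_dimension_mismatch(self, random_instance):
        _, model, _ = random_instance(d=8)
        with pytest.raises(ValueError, match="length"):
            whiten(np.ones(5), model)


class TestScoreFormulas:
    def test_mahalanobis_euclidean_reduction(self):
        """Σ = I₂, W = I, x − μ = (3, 4) → length 5."""
        model = identity_model(2)
        assert mahalanobis(np.array([3.0, 4.0]), model) == pytest.approx(5.0)

    def test_mahalanobis_zero_at_mean(self, random_instance):
        _, model, _ = random_instance()
        assert mahalanobis(model.mu, model) == pytest.approx(0.0, abs=1e-12)

    def test_cosine_self_angle_is_one(self, random_instance):
        _, model, _ = random_instance()
        assert cosine_to_ones(np.ones(model.n_columns), model) == pytest.approx(1.0)

    def test_cosine_orthogonal_construction(self):
        """With Σ = I and μ = 0 the whitened space is the raw space, so a
        vector orthogonal to 𝟙 has cosine 0."""
        model = identity_model(4)
        x = np.array([1.0, -1.0, 1.0, -1.0])
        assert cosine_to_ones(x, model) == pytest.approx(0.0, abs=1e-12)

    def test_score_zero_at_ones(self, random_instance):
        _, model, _ = random_instance()
        assert pines_score(np.ones(model.n_columns), model) == pytest.approx(0.0, abs=1e-12)

    def test_undefined_angle_at_mean(self, random_instance):
        _, model, _ = random_instance()
        with pytest.raises(UndefinedAngleError):
            pines_score(model.mu, model)

    @pytest.mark.parametrize("seed", range(12))
    def test_oracle_equivalence_random_instances(self, random_instance, seed):
        """Whitening-route score equals the explicit-pseudo-inverse formula."""
        local = np.random.default_rng(seed)
        n = int(local.integers(40, 200))
        d = int(local.integers(4, 20))
        X, model, oracle = random_instance(n=n, d=d, seed=seed + 1000)
        for _ in range(5):
            x = (local.random(model.n_columns) < 0.5).astype(float)
            if abs(mahalanobis(x, model)) < 1e-9:
                continue
            w = local.uniform(0.2, 4.0, model.n_columns)
            assert mahalanobis(x, model, w) == pytest.approx(oracle.mahalanobis(x, w), abs=1e-8)
            assert cosine_to_ones(x, model, w) == pytest.approx(oracle.cosine(x, w), abs=1e-8)
            assert pines_score(x, model, w) == pytest.approx(oracle.score(x, w), abs=1e-8)

    def test_low_rank_oracle_equivalence(self, random_instance, rng):
        """Rank-truncated model (k < d) still matches the rank-k oracle."""
        X, model, oracle = random_instance(n=300, d=15, k=6)
        for _ in range(10):
            x = (rng.random(15) < 0.5).astype(float)
            w = rng.uniform(0.5, 2.0, 15)
            assert pines_score(x, model, w) == pytest.approx(oracle.score(x, w), abs=1e-8)


class TestInvariants:
    def test_score_nonnegative_and_ones_is_minimum(self, random_instance, rng):
        _, model, _ = random_instance(n=300, d=10)
        d = model.n_columns
        w = rng.uniform(0.1, 5.0, d)
        s_ones = pines_score(np.ones(d), model, w)
        assert s_ones == pytest.approx(0.0, abs=1e-12)
        for _ in range(50):
            x = (rng.random(d) < 0.5).astype(float)
            if np.all(x == 1) or mahalanobis(x, model, w) < 1e-9:
                continue
            assert pines_score(x, model, w) >= 0.0
            assert pines_score(x, model, w) > s_ones

    @given(c=st.floats(min_value=0.05, max_value=50.0))
    @settings(max_examples=25, deadline=None)
    def test_weight_rescaling_scales_scores_by_inverse_c_squared(self, c):
        rng = np.random.default_rng(3)
        X = (rng.random((200, 9)) < 0.4).astype(float)
        model = estimate_background_model(X, k=9)
        w = rng.uniform(0.5, 2.0, 9)
        x = (rng.random(9) < 0.5).astype(float)
        s1 = pines_score(x, model, w)
        s2 = pines_score(x, model, c * w)
        assert s2 == pytest.approx(s1 / c**2, rel=1e-9)

    def test_weight_rescaling_preserves_empirical_pvalues(self, rng):
        from pines.background import score_with_background

        bg = (rng.random((400, 8)) < 0.4).astype(float)
        q = (rng.random((50, 8)) < 0.5).astype(float)
        _, p1, _ = score_with_background(q, bg, np.ones(8))
        _, p2, _ = score_with_background(q, bg, 3.7 * np.ones(8))
        np.testing.assert_allclose(p1, p2)

    def test_column_permutation_invariance(self, rng):
        X = (rng.random((250, 10)) < 0.4).astype(float)
        perm = rng.permutation(10)
        w = rng.uniform(0.5, 2.0, 10)
        x = (rng.random(10) < 0.5).astype(float)
        s1 = pines_score(x, estimate_background_model(X, k=10), w)
        s2 = pines_score(x[perm], estimate_background_model(X[:, perm], k=10), w[perm])
        assert s2 == pytest.approx(s1, rel=1e-8)

    def test_missing_query_entries_contribute_zero_deviation(self, random_instance):
        _, model, _ = random_instance(d=8)
        x = np.ones(8)
        x_missing = x.copy()
        x_missing[3] = np.nan
        x_imputed = x.copy()
        x_imputed[3] = model.mu[3]
        np.testing.assert_allclose(
            whiten(x_missing, model), whiten(x_imputed, model), atol=1e-12
        )

    def test_batch_scores_match_scalar_route(self, random_instance, rng):
        _, model, _ = random_instance(d=10)
        Q = (rng.random((30, 10)) < 0.5).astype(float)
        scores, undefined = score_matrix(Q, model)
        for i in range(30):
            if undefined[i]:
                continue
            assert scores[i] == pytest.approx(pines_score(Q[i], model), abs=1e-10)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            WeightVector(np.array([1.0, -0.5]))
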