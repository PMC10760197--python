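import numpy as np
import pytest
from scipy.stats import ortho_group

import tnvae as tv
from tnvae.exceptions import ShapeError, UndefinedMetricError, ValidationError
from tnvae.metrics import LatentTrajectory


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def silhouette_bruteforce(Z, labels):
    """Double-loop reference implementation of the per-sample silhouette."""
    Z = np.asarray(Z, dtype=float)
    labels = np.asarray(labels)
    n = len(Z)
    s = np.zeros(n)
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            continue  # singleton: s = 0
        a = np.mean([np.linalg.norm(Z[i] - Z[j]) for j in own])
        b = np.inf
        for c in set(labels) - {labels[i]}:
            other = [j for j in range(n) if labels[j] == c]
            b = min(b, np.mean([np.linalg.norm(Z[i] - Z[j]) for j in other]))
        s[i] = (b - a) / max(a, b)
    return s.mean(), s


def procrustes_grid_oracle(A, B, n_angles=100_000, n_scales=20_000):
    """Grid search over rotation angle x reflection x scale in 2-D."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    A0 = A - A.mean(axis=0)
    B0 = B - B.mean(axis=0)
    A0 /= np.linalg.norm(A0)
    B0 /= np.linalg.norm(B0)
    angles = np.linspace(0, 2 * np.pi, n_angles, endpoint=False)
    scales = np.linspace(0.0, 2.0, n_scales)
    best = np.inf
    for refl in (1.0, -1.0):
        c, s = np.cos(angles), np.sin(angles)
        # residual^2 = |A|^2 - 2 s * tr(A^T B R) + s^2 |B|^2, with unit norms
        # tr(A^T B R) for rotation angle t (optionally reflected)
        M = A0.T @ B0  # 2x2
        tr = (M[0, 0] + refl * M[1, 1]) * c + (refl * M[0, 1] - M[1, 0]) * s
        # evaluate every trace against its nearest scale grid points
        si = np.clip(np.searchsorted(scales, tr), 1, n_scales - 1)
        for cand in (scales[si - 1], scales[si]):
            res = 1.0 - 2.0 * cand * tr + cand**2
            best = min(best, res.min())
    return float(np.sqrt(max(best, 0.0)))


def rotation(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


# ---------------------------------------------------------------------------
# neighbor loss
# ---------------------------------------------------------------------------


class TestNeighborLoss:
    def test_constant_nonzero_trajectory_is_zero(self):
        Z = np.tile([1.0, 2.0], (10, 1))
        assert tv.neighbor_loss(LatentTrajectory(Z=Z)) == 0.0

    def test_hand_computed_two_point_instance(self):
        Z = np.array([[0.0, 0.0], [3.0, 4.0]])
        # step 5; mean norm (0 + 5)/2 = 2.5; value 5/2.5 = 2
        assert tv.neighbor_loss(LatentTrajectory(Z=Z)) == pytest.approx(2.0, abs=1e-14)

    def test_scale_invariance(self, rng):
        Z = rng.standard_normal((50, 3))
        base = tv.neighbor_loss(LatentTrajectory(Z=Z))
        for c in (0.01, 7.3, 1e4):
            assert tv.neighbor_loss(LatentTrajectory(Z=c * Z)) == pytest.approx(
                base, abs=1e-10 * max(1, base)
            )

    def test_rotation_reflection_invariance(self, rng):
        Z = rng.standard_normal((60, 3))
        base = tv.neighbor_loss(LatentTrajectory(Z=Z))
        for seed in range(5):
            Q = ortho_group.rvs(3, random_state=seed)
            assert tv.neighbor_loss(LatentTrajectory(Z=Z @ Q)) == pytest.approx(
                base, abs=1e-10
            )

    def test_all_zero_trajectory_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            tv.neighbor_loss(LatentTrajectory(Z=np.zeros((5, 2))))

    def test_gap_transitions_excluded(self):
        Z = np.array([[0.0, 0.0], [3.0, 4.0], [3.0, 4.0]])
        traj = LatentTrajectory(Z=Z, gaps={0})
        assert tv.neighbor_loss(traj) == 0.0  # only the flat 1->2 step counts


class TestNeighborLossNormalized:
    def test_two_point_instance(self):
        Z = np.array([[0.0, 0.0], [3.0, 4.0]])
        assert tv.neighbor_loss_normalized(LatentTrajectory(Z=Z)) == pytest.approx(2.0)

    def test_duplicating_transitions_invariant(self, rng):
        Z = rng.standard_normal((21, 2)) + 5.0
        n = len(Z)
        # replay the same trajectory twice; the junction is a recorded gap,
        # so both the step multiset and the mean latent norm are unchanged
        Z2 = np.concatenate([Z, Z])
        a = tv.neighbor_loss_normalized(LatentTrajectory(Z=Z))
        b = tv.neighbor_loss_normalized(LatentTrajectory(Z=Z2, gaps={n - 1}))
        assert b == pytest.approx(a, abs=1e-12)

    def test_raw_grows_with_n_normalized_stabilizes(self, rng):
        def walk(n):
            return np.cumsum(rng.standard_normal((n, 2)), axis=0) + 100.0

        raw_small = tv.neighbor_loss(LatentTrajectory(Z=walk(1000)))
        raw_big = tv.neighbor_loss(LatentTrajectory(Z=walk(10_000)))
        norm_small = tv.neighbor_loss_normalized(LatentTrajectory(Z=walk(1000)))
        norm_big = tv.neighbor_loss_normalized(LatentTrajectory(Z=walk(10_000)))
        assert raw_big > 5 * raw_small
        assert norm_big == pytest.approx(norm_small, rel=0.25)


class TestRandomWalkRankingLink:
    def test_step_distance_ranks_like_random_walk_likelihood(self, rng):
        # candidate trajectories differing in step scale: the summed step
        # distance must rank them exactly like the Gaussian random-walk
        # log-likelihood at fixed step variance
        sigma = 1.0
        trajs = []
        for scale in (0.3, 0.6, 1.0, 1.7, 2.8, 4.0):
            steps = scale * rng.standard_normal((200, 2))
            trajs.append(np.cumsum(steps, axis=0))
        sum_abs = [np.linalg.norm(np.diff(Z, axis=0), axis=1).sum() for Z in trajs]
        loglik = [
            -np.sum(np.diff(Z, axis=0) ** 2) / (2 * sigma**2) for Z in trajs
        ]
        # lower summed distance <=> higher likelihood
        assert np.array_equal(np.argsort(sum_abs), np.argsort(loglik)[::-1])


# ---------------------------------------------------------------------------
# silhouette
# ---------------------------------------------------------------------------


class TestSilhouette:
    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(100):
            n = rng.integers(4, 50)
            d = rng.integers(1, 6)
            k = rng.integers(2, 5)
            labels = rng.integers(0, k, size=n)
            if len(np.unique(labels)) < 2:
                labels[0] = (labels[1] + 1) % k
            Z = rng.standard_normal((n, d))
            score, per = tv.silhouette(Z, labels)
            oracle_score, oracle_s = silhouette_bruteforce(Z, labels)
            assert score == pytest.approx(oracle_score, abs=1e-12)
            np.testing.assert_allclose(per.s, oracle_s, atol=1e-12)

    def test_hand_four_point_instance(self):
        Z = np.array([[0, 0], [0, 1], [10, 0], [10, 1]], dtype=float)
        labels = np.array([0, 0, 1, 1])
        score, per = tv.silhouette(Z, labels)
        np.testing.assert_allclose(per.a, 1.0)
        b = np.mean([10.0, np.sqrt(101.0)])
        np.testing.assert_allclose(per.b, b, atol=1e-12)
        assert score == pytest.approx((b - 1) / b, abs=1e-12)

    def test_distant_tight_clusters_approach_one(self, rng):
        Z = np.concatenate(
            [rng.normal(0, 1e-3, (20, 2)), rng.normal(1e6, 1e-3, (20, 2))]
        )
        labels = np.repeat([0, 1], 20)
        score, _ = tv.silhouette(Z, labels)
        assert score > 0.999999

    def test_label_renaming_invariance(self, rng):
        Z = rng.standard_normal((30, 2))
        labels = rng.integers(0, 3, 30)
        labels[:3] = [0, 1, 2]
        a, _ = tv.silhouette(Z, labels)
        b, _ = tv.silhouette(Z, (labels + 5) * 7)
        assert a == pytest.approx(b, abs=1e-14)

    def test_single_label_raises(self, rng):
        with pytest.raises(ValidationError, match="one cluster"):
            tv.silhouette(rng.standard_normal((10, 2)), np.zeros(10, dtype=int))

    def test_singleton_cluster_scores_zero(self):
        Z = np.array([[0.0, 0.0], [1.0, 0.0], [5.0, 5.0]])
        labels = np.array([0, 0, 1])
        _, per = tv.silhouette(Z, labels)
        assert per.s[2] == 0.0
        assert -1 <= per.s.min() and per.s.max() <= 1


# ---------------------------------------------------------------------------
# shape distance
# ---------------------------------------------------------------------------


class TestProcrustesDistance:
    def test_identity(self, rng):
        A = rng.standard_normal((8, 2))
        assert tv.procrustes_distance(A, A) <= 1e-12

    def test_similarity_transform_invariance(self, rng):
        A = rng.standard_normal((10, 2))
        for theta, refl in [(0.3, 1), (2.1, -1), (5.0, 1)]:
            R = rotation(theta) @ np.diag([1.0, refl])
            B = 3.0 * (A @ R) + np.array([7.0, -2.0])
            assert tv.procrustes_distance(A, B) <= 1e-10

    def test_matches_grid_search_oracle(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            A = r.standard_normal((5, 2))
            B = r.standard_normal((5, 2))
            ours = tv.procrustes_distance(A, B)
            oracle = procrustes_grid_oracle(A, B)
            assert ours == pytest.approx(oracle, abs=1e-6)

    def test_symmetry(self, rng):
        for _ in range(20):
            A = rng.standard_normal((12, 3))
            B = rng.standard_normal((12, 3))
            assert tv.procrustes_distance(A, B) == pytest.approx(
                tv.procrustes_distance(B, A), abs=1e-12
            )

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ShapeError):
            tv.procrustes_distance(rng.standard_normal((5, 2)), rng.standard_normal((6, 2)))

    def test_zero_variance_input_is_undefined(self):
        A = np.ones((5, 2))
        with pytest.raises(UndefinedMetricError):
            tv.procrustes_distance(A, A)


class TestEncodingDistance:
    @pytest.fixture
    def toy_data(self, rng):
        X = rng.standard_normal((40, 6))
        return tv.LabeledTimeSeries(X=X, t=np.arange(40))

    @pytest.fixture
    def model(self):
        cfg = tv.VAEConfig(n_layers=2, layer_dim=16, latent_dim=2, seed=0)
        return tv.VAE(cfg, input_dim=6)

    def test_same_model_zero(self, model, toy_data):
        assert tv.encoding_distance(model, model, toy_data) <= 1e-12

    def test_rotated_latent_clone_zero(self, model, toy_data):
        clone = model.copy()
        R = rotation(1.1)
        clone.params["W_mu"] = model.params["W_mu"] @ R
        clone.params["b_mu"] = model.params["b_mu"] @ R
        assert tv.encoding_distance(model, clone, toy_data) <= 1e-8

    def test_independent_initializations_positive(self, toy_data):
        cfg_a = tv.VAEConfig(n_layers=2, layer_dim=16, latent_dim=2, seed=1)
        cfg_b = tv.VAEConfig(n_layers=2, layer_dim=16, latent_dim=2, seed=2)
        a = tv.VAE(cfg_a, input_dim=6)
        b = tv.VAE(cfg_b, input_dim=6)
        assert tv.encoding_distance(a, b, toy_data) > 0.0


# ---------------------------------------------------------------------------
# cluster moments
# ---------------------------------------------------------------------------


class TestClusterMoments:
    def test_mirror_symmetric_cluster_has_zero_skew(self):
        pts = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        _, table = tv.cluster_moments(pts, np.zeros(4, dtype=int))
        assert table[0]["skew"][0] == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_sample_within_three_se(self, rng):
        n = 20_000
        Z = rng.standard_normal((n, 2))
        _, table = tv.cluster_moments(Z, np.zeros(n, dtype=int))
        se_skew = np.sqrt(6.0 / n)
        se_kurt = np.sqrt(24.0 / n)
        assert np.all(np.abs(table[0]["skew"]) < 3 * se_skew)
        assert np.all(np.abs(table[0]["kurtosis"]) < 3 * se_kurt)

    def test_exponential_sample_skew_near_two(self, rng):
        Z = rng.exponential(1.0, (50_000, 1))
        _, table = tv.cluster_moments(Z, np.zeros(50_000, dtype=int))
        assert table[0]["skew"][0] == pytest.approx(2.0, abs=0.15)

    def test_small_cluster_reported_missing(self, rng):
        Z = rng.standard_normal((10, 2))
        labels = np.array([0] * 8 + [1] * 2)
        summary, table = tv.cluster_moments(Z, labels)
        assert table[1] is None
        assert np.isfinite(summary["abs_skew"])
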