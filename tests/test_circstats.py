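import numpy as np
import pytest

from cyclepos import (
    aligned_circular_rho,
    angular_silhouette,
    circular_corr,
    periodic_loess,
    proliferation_fraction,
)
from cyclepos.circstats import _loess, circular_rank_rho

TWO_PI = 2 * np.pi

# Reference values from R: loess(y ~ x, span=0.3, degree=2,
# control=loess.control(surface="direct")) fitted on the tripled data of the
# fixture below and predicted at 9 equispaced points on [0, 2*pi].
R_LOESS_FIT = [
    0.868955, 0.630705, 0.001690, -0.712503, -0.978635,
    -0.693961, -0.096585, 0.553463, 0.868955,
]


def _nonuniform_angles(n=200, seed=0):
    """Angles concentrated enough for the von Mises mean to be identified."""
    rng = np.random.default_rng(seed)
    return np.mod(rng.vonmises(1.0, 2.0, n), TWO_PI)


class TestPeriodicLoess:
    def test_matches_r_loess_on_frozen_fixture(self):
        rng = np.random.default_rng(42)
        t = np.sort(rng.uniform(0, TWO_PI, 60))
        y = np.cos(t) + rng.normal(0, 0.3, 60)
        x3 = np.concatenate([t - TWO_PI, t, t + TWO_PI])
        y3 = np.concatenate([y, y, y])
        eval_pts = np.linspace(0, TWO_PI, 9)
        mine = _loess(x3, y3, eval_pts, span=0.3, degree=2)
        np.testing.assert_allclose(mine, R_LOESS_FIT, atol=2e-6)

    def test_noiseless_cosine_r2(self):
        rng = np.random.default_rng(0)
        t = rng.uniform(0, TWO_PI, 500)
        fit = periodic_loess(t, np.cos(t))
        assert fit.r_squared >= 0.99

    def test_independent_noise_r2_near_zero(self):
        rng = np.random.default_rng(1)
        t = rng.uniform(0, TWO_PI, 500)
        fit = periodic_loess(t, rng.normal(size=500))
        assert fit.r_squared <= 0.1

    def test_seam_continuity(self):
        rng = np.random.default_rng(2)
        t = rng.uniform(0, TWO_PI, 500)
        fit = periodic_loess(t, np.cos(t), n_grid=2048)
        left = np.interp(0.01, fit.grid, fit.grid_fitted)
        right = np.interp(TWO_PI - 0.01, fit.grid, fit.grid_fitted)
        assert abs(left - right) < 0.05

    def test_wrap_relabeling_invariance(self):
        rng = np.random.default_rng(3)
        t = rng.uniform(0, TWO_PI, 120)
        y = np.sin(t) + rng.normal(0, 0.1, 120)
        shifted = t.copy()
        shifted[::3] += TWO_PI  # relabel a subset by one full period
        a = periodic_loess(t, y)
        b = periodic_loess(shifted, y)
        np.testing.assert_allclose(a.grid_fitted, b.grid_fitted, atol=1e-10)
        assert a.r_squared == pytest.approx(b.r_squared, abs=1e-12)

    def test_constant_response_flagged(self):
        rng = np.random.default_rng(4)
        t = rng.uniform(0, TWO_PI, 50)
        with pytest.warns(UserWarning, match="constant"):
            fit = periodic_loess(t, np.ones(50))
        assert np.isnan(fit.r_squared)
        np.testing.assert_allclose(fit.grid_fitted, 1.0, atol=1e-9)

    def test_nan_pairs_dropped_with_warning(self):
        rng = np.random.default_rng(5)
        t = rng.uniform(0, TWO_PI, 60)
        y = np.cos(t)
        t[0] = np.nan
        with pytest.warns(UserWarning, match="dropped 1"):
            fit = periodic_loess(t, y)
        assert len(fit.theta) == 59

    def test_peak_location_of_shifted_cosine(self):
        rng = np.random.default_rng(6)
        t = rng.uniform(0, TWO_PI, 400)
        fit = periodic_loess(t, np.cos(t - 2.0))
        assert abs(fit.peak_location() - 2.0) < 0.1


class TestCircularCorr:
    def test_identity_is_one(self):
        t = _nonuniform_angles()
        assert circular_corr(t, t).rho == pytest.approx(1.0, abs=1e-12)

    def test_rotation_of_one_vector_keeps_one(self):
        t = _nonuniform_angles()
        for c in (0.5, 2.0, 5.5):
            rho = circular_corr(t, np.mod(t + c, TWO_PI)).rho
            assert rho == pytest.approx(1.0, abs=1e-12)

    def test_reflection_is_minus_one(self):
        t = _nonuniform_angles()
        assert circular_corr(t, np.mod(-t, TWO_PI)).rho == pytest.approx(-1.0, abs=1e-12)

    def test_symmetric_and_joint_rotation_invariant(self):
        rng = np.random.default_rng(7)
        a = _nonuniform_angles(seed=8)
        b = np.mod(a + rng.normal(0, 0.4, a.size), TWO_PI)
        r_ab = circular_corr(a, b).rho
        assert circular_corr(b, a).rho == pytest.approx(r_ab, abs=1e-12)
        r_rot = circular_corr(np.mod(a + 1.1, TWO_PI), np.mod(b + 1.1, TWO_PI)).rho
        assert r_rot == pytest.approx(r_ab, abs=1e-10)

    def test_degenerate_vector_flagged(self):
        t = _nonuniform_angles(n=10)
        with pytest.warns(UserWarning, match="degenerate"):
            res = circular_corr(t, np.full(10, 1.2))
        assert np.isnan(res.rho)

    def test_nan_pairs_dropped(self):
        t = _nonuniform_angles(n=50)
        u = t.copy()
        u[0] = np.nan
        assert circular_corr(t, u).n == 49


class TestAlignedRho:
    def test_rotated_copy_scores_one(self):
        rng = np.random.default_rng(9)
        t = rng.uniform(0, TWO_PI, 500)
        res = aligned_circular_rho(t, np.mod(t + 2.5, TWO_PI))
        assert res.rho == pytest.approx(1.0, abs=1e-9)
        assert not res.reflected

    def test_reflection_detected(self):
        rng = np.random.default_rng(10)
        t = rng.uniform(0, TWO_PI, 500)
        res = aligned_circular_rho(t, np.mod(-t + 1.0, TWO_PI))
        assert res.rho == pytest.approx(1.0, abs=1e-9)
        assert res.reflected

    def test_monotone_circular_distortion_scores_one(self):
        # the rank statistic is invariant to any circular order-preserving map
        rng = np.random.default_rng(11)
        t = rng.uniform(0, TWO_PI, 400)
        distorted = np.mod(t + 0.5 * np.sin(t), TWO_PI)  # monotone for |a|<1
        assert aligned_circular_rho(t, distorted).rho == pytest.approx(1.0, abs=1e-9)

    def test_independent_angles_score_near_zero(self):
        rng = np.random.default_rng(12)
        t = rng.uniform(0, TWO_PI, 2000)
        u = rng.uniform(0, TWO_PI, 2000)
        assert abs(aligned_circular_rho(t, u).rho) < 0.1

    def test_grid_method_on_concentrated_angles(self):
        t = _nonuniform_angles(n=300, seed=13)
        res = aligned_circular_rho(t, np.mod(t + 1.0, TWO_PI), method="grid")
        assert res.rho == pytest.approx(1.0, abs=1e-6)

    def test_rank_rho_equals_one_for_rotated_grid(self):
        t = np.arange(100) * TWO_PI / 100
        assert circular_rank_rho(t, np.mod(t + 1.7, TWO_PI)) == pytest.approx(1.0, abs=1e-12)


class TestSilhouette:
    def test_singleton_stage_scores_exactly_zero(self):
        theta = np.array([0.1, 0.2, 0.3, 3.0])
        labels = np.array(["a", "a", "a", "b"], dtype=object)
        res = angular_silhouette(theta, labels)
        assert res.s[3] == 0.0
        assert res.a[3] == 0.0

    def test_antipodal_clusters_score_high(self):
        rng = np.random.default_rng(14)
        theta = np.concatenate([
            rng.normal(0, 0.05, 50) % TWO_PI,
            rng.normal(np.pi, 0.05, 50),
        ])
        labels = np.array(["g1"] * 50 + ["g2"] * 50, dtype=object)
        res = angular_silhouette(theta, labels)
        assert res.mean_s >= 0.9

    def test_mixed_labels_score_negative(self):
        # each label group straddles both antipodal clusters, so every cell
        # is on average closer to the other group than to its own
        rng = np.random.default_rng(15)
        theta = np.concatenate([
            rng.normal(0, 0.05, 50) % TWO_PI,
            rng.normal(np.pi, 0.05, 50),
        ])
        labels = np.array(
            ["g1"] * 25 + ["g2"] * 25 + ["g1"] * 25 + ["g2"] * 25, dtype=object
        )
        res = angular_silhouette(theta, labels)
        assert np.all(res.s < 0)

    def test_global_rotation_invariance(self):
        rng = np.random.default_rng(16)
        theta = rng.uniform(0, TWO_PI, 80)
        labels = np.array(["a", "b"] * 40, dtype=object)
        base = angular_silhouette(theta, labels)
        rotated = angular_silhouette(np.mod(theta + 1.3, TWO_PI), labels)
        np.testing.assert_allclose(base.s, rotated.s, atol=1e-10)

    def test_values_bounded(self):
        rng = np.random.default_rng(17)
        theta = rng.uniform(0, TWO_PI, 60)
        labels = rng.choice(["a", "b", "c"], 60)
        res = angular_silhouette(theta, np.asarray(labels, dtype=object))
        assert np.all(res.s >= -1) and np.all(res.s <= 1)

    def test_single_label_fatal(self):
        with pytest.raises(ValueError, match="2 distinct"):
            angular_silhouette(np.array([0.1, 0.2, 0.3]), np.array(["a"] * 3, dtype=object))


class TestProliferation:
    def test_interval_membership(self):
        res = proliferation_fraction(np.array([np.pi, 0.0, 1.75 * np.pi]))
        assert list(res.flags) == [True, False, False]
        assert res.fraction == pytest.approx(1 / 3)

    def test_uniform_fraction_matches_interval_length(self):
        rng = np.random.default_rng(18)
        theta = rng.uniform(0, TWO_PI, 100_000)
        res = proliferation_fraction(theta)
        assert res.fraction == pytest.approx(0.625, abs=0.01)

    def test_endpoints_excluded(self):
        res = proliferation_fraction(np.array([0.25 * np.pi, 1.5 * np.pi, np.pi]))
        assert list(res.flags) == [False, False, True]

    def test_nan_excluded_from_denominator(self):
        with pytest.warns(UserWarning, match="excluded 1"):
            res = proliferation_fraction(np.array([np.pi, np.nan]))
        assert res.fraction == 1.0
        assert res.n_defined == 1
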