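"""Mahalanobis scoring: residual model, ensemble, and distance properties."""

import numpy as np
import pytest

from mgmv.distance import (ReferenceDistribution, build_reference_ensemble,
                           fit_residual_model, mahalanobis, residualize,
                           score_patients)


def _ref(mu, cov):
    mu = np.asarray(mu, dtype=float)
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    return ReferenceDistribution(member_ids=np.arange(len(mu)), mu=mu,
                                 cov=cov, cov_inv=np.linalg.inv(cov),
                                 condition_number=float(np.linalg.cond(cov)))


class TestResidualModel:
    def test_two_point_exact_line(self):
        values = np.array([[1.0], [3.0]])
        m = fit_residual_model(np.vstack([values, [[2.0]]]),
                               np.array([50.0, 60.0, 55.0]))
        assert m.slope[0] == pytest.approx(0.2, rel=1e-10)
        assert m.intercept[0] == pytest.approx(-9.0, rel=1e-10)

    def test_control_residual_means_vanish(self, rng):
        values = rng.normal(0.01, 0.001, (50, 6))
        ages = rng.uniform(40, 85, 50)
        m = fit_residual_model(values, ages)
        resid = residualize(m, values, ages)
        np.testing.assert_allclose(resid.mean(axis=0), 0.0, atol=1e-12)

    def test_zero_slope_generator_recovered(self, rng):
        values = np.tile([0.01, 0.02], (200, 1)) + rng.normal(
            0, 1e-4, (200, 2))
        ages = rng.uniform(40, 85, 200)
        m = fit_residual_model(values, ages)
        np.testing.assert_allclose(m.slope, 0.0, atol=5e-6)

    def test_constant_age_rejected(self):
        with pytest.raises(ValueError):
            fit_residual_model(np.zeros((5, 2)), np.full(5, 60.0))

    def test_subject_on_the_line_has_zero_residual(self):
        ages = np.array([40.0, 50.0, 60.0])
        values = (2.0 + 0.1 * ages)[:, None]
        m = fit_residual_model(values, ages)
        out = residualize(m, np.array([[2.0 + 0.1 * 70.0]]),
                          np.array([70.0]))
        assert out[0, 0] == pytest.approx(0.0, abs=1e-10)

    def test_residualize_is_linear_in_shift(self, rng):
        values = rng.normal(0.01, 0.001, (30, 4))
        ages = rng.uniform(40, 85, 30)
        m = fit_residual_model(values, ages)
        x = rng.normal(0.01, 0.001, (3, 4))
        a = rng.uniform(45, 80, 3)
        r1 = residualize(m, x, a)
        r2 = residualize(m, x + 0.005, a)
        np.testing.assert_allclose(r2 - r1, 0.005, rtol=1e-10)

    def test_matches_longhand_prediction_subtraction(self, rng):
        values = rng.normal(0.01, 0.001, (30, 3))
        ages = rng.uniform(40, 85, 30)
        m = fit_residual_model(values, ages)
        x = rng.normal(0.01, 0.001, (5, 3))
        a = rng.uniform(45, 80, 5)
        expected = np.array([[x[i, j] - (m.intercept[j] + m.slope[j] * a[i])
                              for j in range(3)] for i in range(5)])
        np.testing.assert_allclose(residualize(m, x, a), expected,
                                   rtol=1e-12)


class TestMahalanobis:
    def test_zero_at_the_mean(self):
        ref = _ref([1.0, 2.0], np.eye(2))
        assert mahalanobis(np.array([1.0, 2.0]), ref) == 0.0

    def test_univariate_reduces_to_abs_z(self):
        ref = _ref([0.0], [[4.0]])
        assert mahalanobis(np.array([4.0]), ref) == pytest.approx(2.0)

    def test_2d_hand_inversion(self):
        # C = [[2,1],[1,2]], C^-1 = 1/3 [[2,-1],[-1,2]]; d = (1,1)
        ref = _ref([0.0, 0.0], [[2.0, 1.0], [1.0, 2.0]])
        expected = np.sqrt((2 - 1 - 1 + 2) / 3.0)
        assert mahalanobis(np.array([1.0, 1.0]), ref) == pytest.approx(
            expected, rel=1e-12)

    def test_dimension_mismatch(self):
        ref = _ref([0.0, 0.0], np.eye(2))
        with pytest.raises(ValueError, match="dimension"):
            mahalanobis(np.array([1.0]), ref)


class TestEnsemble:
    def test_same_seed_identical_memberships(self, rng):
        pool = rng.normal(0, 1, (30, 4))
        a = build_reference_ensemble(pool, m=10, B=20, seed=5)
        b = build_reference_ensemble(pool, m=10, B=20, seed=5)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.member_ids, rb.member_ids)

    def test_degenerate_pool_equals_single_reference(self, rng):
        pool = rng.normal(0, 1, (15, 3))
        ensemble = build_reference_ensemble(pool, m=15, B=8, seed=0)
        mu = pool.mean(axis=0)
        cov = np.cov(pool, rowvar=False, ddof=1)
        naive = _ref(mu, cov)
        s = rng.normal(0, 1, 3)
        expected = float(np.sqrt((s - mu) @ np.linalg.inv(cov) @ (s - mu)))
        results = score_patients(s[None, :], ["p"], ensemble)
        assert results[0].m_gmv == pytest.approx(expected, rel=1e-10)
        assert mahalanobis(s, naive) == pytest.approx(expected, rel=1e-10)

    def test_pool_smaller_than_m_rejected(self, rng):
        with pytest.raises(ValueError, match="pool"):
            build_reference_ensemble(rng.normal(0, 1, (5, 2)), m=10, B=2)

    def test_membership_frequency_binomial(self, rng):
        pool = rng.normal(0, 1, (120, 5))
        ensemble = build_reference_ensemble(pool, m=100, B=300, seed=1)
        counts = np.zeros(120)
        for ref in ensemble:
            counts[ref.member_ids] += 1
        freq = counts / 300
        expect = 100 / 120
        se = np.sqrt(expect * (1 - expect) / 300)
        assert np.all(np.abs(freq - expect) < 5 * se)


class TestScoring:
    def test_patient_at_global_mean_scores_near_zero(self, rng):
        pool = rng.normal(0, 1, (60, 5))
        ensemble = build_reference_ensemble(pool, m=40, B=50, seed=2)
        center = pool.mean(axis=0)
        res = score_patients(center[None, :], ["p"], ensemble)[0]
        # subsample means jitter around the global mean: small, nonzero
        assert 0 < res.m_gmv < 1.5

    def test_quadratic_form_homogeneity(self, rng):
        pool = rng.normal(0, 1, (40, 4))
        ensemble = build_reference_ensemble(pool, m=20, B=30, seed=3)
        s = rng.normal(0, 1, 4)
        k = 3.7
        base = [mahalanobis(r.mu + (s - r.mu), r) for r in ensemble]
        scaled = [mahalanobis(r.mu + k * (s - r.mu), r) for r in ensemble]
        np.testing.assert_allclose(scaled, k * np.array(base), rtol=1e-10)
        assert np.median(scaled) == pytest.approx(k * np.median(base))

    def test_affine_invariance(self, rng):
        """Any fixed invertible linear map + offset leaves distances alone."""
        pool = rng.normal(0, 1, (80, 6))
        patients = rng.normal(0, 1, (5, 6))
        A = rng.normal(0, 1, (6, 6)) + 3 * np.eye(6)
        b = rng.normal(0, 2, 6)
        e1 = build_reference_ensemble(pool, m=40, B=25, seed=9)
        e2 = build_reference_ensemble(pool @ A.T + b, m=40, B=25, seed=9)
        r1 = score_patients(patients, list("abcde"), e1)
        r2 = score_patients(patients @ A.T + b, list("abcde"), e2)
        for x, y in zip(r1, r2):
            np.testing.assert_allclose(x.distances, y.distances, atol=1e-8)

    def test_held_out_mean_squared_distance(self, rng):
        """Held-out MVN subjects: E[MD^2] ~ p(m-1)/(m-p-2) (small version)."""
        p, m = 10, 30
        pool = rng.normal(0, 1, (60, p))
        held = rng.normal(0, 1, (400, p))
        ensemble = build_reference_ensemble(pool, m=m, B=60, seed=4)
        res = score_patients(held, [f"h{i}" for i in range(400)], ensemble)
        msd = np.mean([np.mean(r.distances ** 2) for r in res])
        expect = p * (m - 1) / (m - p - 2)
        assert abs(msd - expect) / expect < 0.10

    def test_median_stability_across_seeds(self, rng):
        """Per-patient score SD over reruns is <5% of its mean at B=1000."""
        pool = rng.normal(0, 1, (120, 10))
        patients = rng.normal(0.5, 1, (10, 10))
        scores = []
        for seed in range(10):
            ens = build_reference_ensemble(pool, m=100, B=1000, seed=seed)
            res = score_patients(patients, [f"p{i}" for i in range(10)], ens)
            scores.append([r.m_gmv for r in res])
        scores = np.array(scores)
        ratio = scores.std(axis=0) / scores.mean(axis=0)
        assert np.all(ratio < 0.05)

    def test_severity_monotonicity_on_synthetic_cohort(self, default_cohort):
        from scipy.stats import spearmanr

        from mgmv.pipeline import harmonized_gmvn, mgmv_scores
        subjects, volumes, _, truth = default_cohort
        harmonized, _ = harmonized_gmvn(subjects, volumes)
        res = mgmv_scores(subjects, harmonized, volumes.subject_ids,
                          m=100, B=200, seed=11)
        d = np.array([truth.severity[r.subject_id] for r in res])
        mg = np.array([r.m_gmv for r in res])
        assert spearmanr(d, mg).statistic > 0.8
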