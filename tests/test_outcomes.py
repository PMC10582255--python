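"""TIV normalization, motor subscores/deltas and demographic statistics."""

import numpy as np
import pytest
from scipy import stats

from mgmv.cohort import MotorAssessment, ROIVolumeTable
from mgmv.outcomes import (chi_square_2x2, compute_deltas, normalize_tiv,
                           subscore, welch_t)
from mgmv.roi import ITEM_IDS


def _table(vol, tiv):
    vol = np.atleast_2d(np.asarray(vol, dtype=float))
    return ROIVolumeTable(
        subject_ids=[f"s{i}" for i in range(vol.shape[0])],
        roi_names=[f"r{j}" for j in range(vol.shape[1])],
        volumes=vol, tiv=np.asarray(tiv, dtype=float))


class TestNormalizeTIV:
    def test_exact_arithmetic(self):
        out = normalize_tiv(_table([[12.5, 1250.0]], [1250.0]))
        np.testing.assert_allclose(out.volumes, [[0.01, 1.0]])

    def test_matches_elementwise_division(self, rng):
        vol = rng.uniform(1, 50, size=(7, 5))
        tiv = rng.uniform(1300, 1700, size=7)
        out = normalize_tiv(_table(vol, tiv))
        expected = np.array([[vol[i, j] / tiv[i] for j in range(5)]
                             for i in range(7)])
        np.testing.assert_allclose(out.volumes, expected, rtol=1e-15)

    def test_scale_equivariance(self, rng):
        vol = rng.uniform(1, 50, size=(4, 3))
        tiv = rng.uniform(1300, 1700, size=4)
        a = normalize_tiv(_table(vol, tiv))
        b = normalize_tiv(_table(vol * 2.5, tiv * 2.5))
        np.testing.assert_allclose(a.volumes, b.volumes, rtol=1e-12)

    def test_nonpositive_tiv_rejected(self):
        with pytest.raises(ValueError):
            normalize_tiv(_table([[1.0]], [0.0]))


class TestSubscore:
    # independent statement of the symptom-family item map, used as oracle
    ORACLE = {
        "rigidity": ["3.3_neck", "3.3_RUE", "3.3_LUE", "3.3_RLE", "3.3_LLE"],
        "bradykinesia": ["3.4_R", "3.4_L", "3.5_R", "3.5_L", "3.6_R",
                         "3.6_L", "3.7_R", "3.7_L", "3.8_R", "3.8_L"],
        "pig": ["3.10", "3.11", "3.12", "3.13"],
        "postural_kinetic": ["3.15_R", "3.15_L", "3.16_R", "3.16_L"],
        "rest": ["3.17_neck", "3.17_RUE", "3.17_LUE", "3.17_RLE",
                 "3.17_LLE"],
    }

    def test_all_zero_items(self):
        items = {i: 0 for i in ITEM_IDS}
        for fam in self.ORACLE:
            assert subscore(items, fam) == 0
        assert subscore(items, "total") == 0

    def test_rigidity_direct_sum(self):
        items = {i: 0 for i in ITEM_IDS}
        for item, v in zip(self.ORACLE["rigidity"], (1, 1, 0, 2, 0)):
            items[item] = v
        assert subscore(items, "rigidity") == 4

    def test_random_items_match_oracle_sets(self, rng):
        items = {i: int(rng.integers(0, 5)) for i in ITEM_IDS}
        for fam, ids in self.ORACLE.items():
            assert subscore(items, fam) == sum(items[i] for i in ids)
        assert subscore(items, "total") == sum(items.values())

    def test_missing_item_named_in_error(self):
        items = {i: 0 for i in ITEM_IDS if i != "3.3_RUE"}
        with pytest.raises(ValueError, match="3.3_RUE"):
            subscore(items, "rigidity")


class TestDeltas:
    def _pair(self, sid, base_total, m48_total):
        base = {i: 0 for i in ITEM_IDS}
        m48 = {i: 0 for i in ITEM_IDS}
        for k, i in enumerate(ITEM_IDS):
            if k < base_total:
                base[i] = 1
            if k < m48_total:
                m48[i] = 1
        return [MotorAssessment(sid, "baseline", base),
                MotorAssessment(sid, "month48", m48)]

    def test_simple_total_delta(self):
        deltas = compute_deltas(self._pair("p1", 19, 30))
        assert deltas[0].delta_total == 11

    def test_identical_assessments_zero_deltas(self):
        a = self._pair("p1", 10, 10)
        d = compute_deltas(a)[0]
        assert all(v == 0 for v in d.as_dict().values())

    def test_unpaired_subject_excluded(self):
        a = self._pair("p1", 5, 9)[:1]
        assert compute_deltas(a) == []

    def test_generator_bookkeeping_matches(self, small_cohort):
        _, _, assessments, truth = small_cohort
        for d in compute_deltas(assessments):
            t = truth.deltas[d.subject_id]
            assert d.delta_total == t["total"]
            assert d.delta_rigidity == t["rigidity"]
            assert d.delta_bradykinesia == t["bradykinesia"]
            assert d.delta_pig == t["pig"]
            assert d.delta_postural_kinetic == t["postural_kinetic"]
            assert d.delta_rest == t["rest"]

    def test_total_delta_equals_sum_of_item_deltas(self, small_cohort):
        _, _, assessments, _ = small_cohort
        by = {}
        for a in assessments:
            by.setdefault(a.subject_id, {})[a.timepoint] = a
        deltas = {d.subject_id: d for d in compute_deltas(assessments)}
        for sid, tps in by.items():
            item_delta = sum(tps["month48"].items[i] - tps["baseline"].items[i]
                             for i in ITEM_IDS)
            assert deltas[sid].delta_total == item_delta


class TestWelchT:
    def test_reproduces_published_age_comparison(self):
        t, df, p = welch_t(61.46, 11.11, 120, 60.18, 9.38, 88)
        assert round(t, 2) == 0.90
        assert p == pytest.approx(0.37, abs=0.01)

    def test_identical_groups_zero(self):
        t, _, p = welch_t(5.0, 2.0, 30, 5.0, 2.0, 30)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_matches_raw_data_oracle(self, rng):
        x = rng.normal(0, 1, 15)
        y = rng.normal(0.5, 2, 12)
        t, df, p = welch_t(x.mean(), x.std(ddof=1), len(x),
                           y.mean(), y.std(ddof=1), len(y))
        ref = stats.ttest_ind(x, y, equal_var=False)
        assert t == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_antisymmetric_in_group_order(self):
        t1, _, p1 = welch_t(10, 2, 20, 8, 3, 25)
        t2, _, p2 = welch_t(8, 3, 25, 10, 2, 20)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)


class TestChiSquare:
    def test_reproduces_published_sex_comparison(self):
        chi2, p = chi_square_2x2(80, 40, 60, 28)
        assert round(chi2, 2) == 0.05
        assert p == pytest.approx(0.82, abs=0.01)

    def test_proportional_table_is_zero(self):
        chi2, _ = chi_square_2x2(20, 10, 40, 20)
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_matches_longhand_expected_counts(self, rng):
        a, b, c, d = (int(v) for v in rng.integers(5, 60, 4))
        chi2, _ = chi_square_2x2(a, b, c, d)
        obs = np.array([[a, b], [c, d]], dtype=float)
        total = obs.sum()
        exp = np.outer(obs.sum(1), obs.sum(0)) / total
        assert chi2 == pytest.approx(((obs - exp) ** 2 / exp).sum(),
                                     rel=1e-12)

    def test_transpose_invariance(self):
        assert chi_square_2x2(7, 13, 21, 9) == pytest.approx(
            chi_square_2x2(7, 21, 13, 9))

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2(0, 0, 5, 5)
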