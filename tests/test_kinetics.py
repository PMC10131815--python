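"""Time-course peaks, contrasts and the nonparametric test battery."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vesikin.kinetics import (
    TimeCourse,
    compartment_contrast,
    find_peak,
    friedman_dunn,
    kruskal_dunn,
    mann_whitney,
    significance_stars,
)


def make_timecourse(means_by_compartment, n_reps=3):
    rows = []
    for compartment, means in means_by_compartment.items():
        for t, mean in means.items():
            for rep in range(n_reps):
                rows.append((t, compartment, f"r{rep}", float(mean), "copies"))
    return TimeCourse.from_records(rows)


def exact_mw_p_value(x, y):
    """Full permutation enumeration of the two-sided Mann-Whitney p-value."""
    pooled = list(x) + list(y)
    n, m = len(x), len(y)
    observed = sum(1 for xi in x for yj in y if xi > yj) + 0.5 * sum(
        1 for xi in x for yj in y if xi == yj
    )
    mu = n * m / 2.0
    count = total = 0
    for idx in itertools.combinations(range(n + m), n):
        gx = [pooled[i] for i in idx]
        gy = [pooled[i] for i in range(n + m) if i not in idx]
        u = sum(1 for xi in gx for yj in gy if xi > yj) + 0.5 * sum(
            1 for xi in gx for yj in gy if xi == yj
        )
        if abs(u - mu) >= abs(observed - mu) - 1e-12:
            count += 1
        total += 1
    return count / total


class TestTimeCourse:
    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            TimeCourse(pd.DataFrame({"timepoint_h": [1.0]}))

    def test_unknown_compartment_rejected(self):
        with pytest.raises(ValueError, match="unknown compartments"):
            TimeCourse.from_records([(1.0, "nucleus", "r1", 2.0, "copies")])

    def test_mixed_units_rejected(self):
        with pytest.raises(ValueError, match="mixed units"):
            TimeCourse.from_records(
                [(1.0, "cell", "r1", 2.0, "copies"), (2.0, "cell", "r1", 2.0, "ng")]
            )

    def test_negative_timepoint_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            TimeCourse.from_records([(-1.0, "cell", "r1", 2.0, "copies")])


class TestFindPeak:
    CELL = {0.5: 400.0, 1.0: 1355.0, 5.0: 434.0, 24.0: 100.0}
    EV = {0.5: 2.0, 1.0: 6.0, 5.0: 31.0, 24.0: 12.0}

    def test_cellular_peak_at_one_hour(self):
        tc = make_timecourse({"cell": self.CELL})
        peak = find_peak(tc, "cell")
        assert (peak.timepoint_h, peak.mean_value) == (1.0, 1355.0)
        assert not peak.tied

    def test_ev_peak_at_five_hours(self):
        tc = make_timecourse({"EV": self.EV})
        peak = find_peak(tc, "EV")
        assert (peak.timepoint_h, peak.mean_value) == (5.0, 31.0)

    def test_constant_series_ties_to_earliest(self):
        tc = make_timecourse({"cell": {0.5: 7.0, 1.0: 7.0, 5.0: 7.0}})
        peak = find_peak(tc, "cell")
        assert peak.timepoint_h == 0.5
        assert peak.tied

    def test_invariant_to_record_order(self, rng):
        tc = make_timecourse({"cell": self.CELL})
        shuffled = TimeCourse(
            tc.records.sample(frac=1.0, random_state=7).reset_index(drop=True)
        )
        assert find_peak(shuffled, "cell") == find_peak(tc, "cell")

    def test_missing_compartment_errors(self):
        tc = make_timecourse({"cell": self.CELL})
        with pytest.raises(ValueError, match="no records"):
            find_peak(tc, "EV")


class TestCompartmentContrast:
    def test_cell_vs_ev_at_peak(self):
        tc = make_timecourse({"cell": {1.0: 1355.0}, "EV": {1.0: 6.0}})
        assert compartment_contrast(tc, "cell", "EV", 1.0) == pytest.approx(225.83, abs=0.01)

    def test_self_contrast_is_unity(self):
        tc = make_timecourse({"cell": {1.0: 50.0}})
        assert compartment_contrast(tc, "cell", "cell", 1.0) == 1.0

    def test_random_series_matches_division(self, rng):
        a = rng.uniform(1, 100, size=4)
        b = rng.uniform(1, 100, size=4)
        rows = [(1.0, "cell", f"r{i}", v, "copies") for i, v in enumerate(a)]
        rows += [(1.0, "EV", f"r{i}", v, "copies") for i, v in enumerate(b)]
        tc = TimeCourse.from_records(rows)
        assert compartment_contrast(tc, "cell", "EV", 1.0) == pytest.approx(
            a.mean() / b.mean()
        )


class TestMannWhitney:
    def test_identical_multisets_give_p_one(self):
        res = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)

    def test_fully_separated_small_samples(self):
        res = mann_whitney([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)  # 2 / C(6,3)
        assert res.method == "mann-whitney-exact"

    def test_matches_permutation_oracle(self, rng):
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        res = mann_whitney(x, y)
        assert res.p_value == pytest.approx(exact_mw_p_value(x, y), abs=1e-9)

    def test_exhaustive_agreement_for_small_groups(self, rng):
        for n, m in [(2, 3), (3, 3), (4, 5), (6, 6)]:
            x = rng.normal(size=n)
            y = rng.normal(size=m)
            assert mann_whitney(x, y).p_value == pytest.approx(
                exact_mw_p_value(x, y), abs=1e-9
            )

    def test_large_or_tied_samples_use_asymptotic(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        assert mann_whitney(x, y).method == "mann-whitney-asymptotic"
        assert mann_whitney([1, 1, 2], [2, 3, 3]).method == "mann-whitney-asymptotic"

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=5)
        y = rng.normal(size=7)
        res = mann_whitney(x, y)
        res_t = mann_whitney(np.exp(x), np.exp(y))
        assert res_t.p_value == pytest.approx(res.p_value)


class TestKruskalDunn:
    def test_identical_groups_null(self):
        g = [1.0, 2.0]
        res = kruskal_dunn([g, g, g])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_h_matches_rank_arithmetic(self):
        # ranks 1..6: H = 12/(6*7) * sum(R_i^2 / n_i) - 3*7 = 32/7
        res = kruskal_dunn([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        expected = 12.0 / 42.0 * (9.0 / 2 + 49.0 / 2 + 121.0 / 2) - 21.0
        assert res.statistic == pytest.approx(expected, rel=1e-12)

    def test_two_groups_redirected_to_mann_whitney(self):
        with pytest.raises(ValueError, match="mann_whitney"):
            kruskal_dunn([[1.0], [2.0]])

    def test_null_calibration(self, rng):
        """Monte-Carlo type-I error of the omnibus test near nominal 5%."""
        reps = 10_000
        rejections = 0
        for _ in range(reps):
            groups = [rng.normal(size=10) for _ in range(3)]
            rejections += kruskal_dunn(groups, adjust="none").p_value < 0.05
        assert 0.04 <= rejections / reps <= 0.06

    def test_dunn_adjustment_bounds(self, rng):
        groups = [rng.normal(loc=mu, size=6) for mu in (0.0, 0.5, 2.0)]
        res = kruskal_dunn(groups, adjust="holm")
        for comp in res.comparisons:
            assert comp.p_adjusted >= comp.p_value
            assert comp.p_adjusted <= 1.0

    def test_dunn_z_matches_hand_formula(self):
        groups = [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]
        res = kruskal_dunn(groups, adjust="none")
        # mean ranks 1.5, 3.5, 5.5; var term N(N+1)/12 = 3.5; se = sqrt(3.5)
        z01 = (1.5 - 3.5) / np.sqrt(3.5 * (0.5 + 0.5))
        first = res.comparisons[0]
        assert first.statistic == pytest.approx(z01, rel=1e-12)
        assert first.p_value == pytest.approx(2 * stats.norm.sf(abs(z01)), rel=1e-12)

    def test_monotone_transform_invariance(self, rng):
        groups = [rng.normal(size=5) for _ in range(3)]
        res = kruskal_dunn(groups)
        res_t = kruskal_dunn([np.exp(g) for g in groups])
        assert res_t.statistic == pytest.approx(res.statistic)
        assert res_t.p_value == pytest.approx(res.p_value)


class TestFriedmanDunn:
    def test_identical_columns_null(self):
        mat = np.tile([[1.0], [2.0], [3.0], [4.0]], (1, 3))
        res = friedman_dunn(mat)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_toy_matrix_matches_hand_ranks(self):
        mat = np.array(
            [[1.0, 2.0, 3.0], [1.0, 3.0, 2.0], [1.0, 2.0, 3.0], [2.0, 1.0, 3.0]]
        )
        res = friedman_dunn(mat)
        # within-block ranks; chi2 = 12n/(k(k+1)) * sum (Rbar_j - (k+1)/2)^2
        ranks = np.apply_along_axis(stats.rankdata, 1, mat)
        rbar = ranks.mean(axis=0)
        expected = 12.0 * 4 / (3 * 4) * np.sum((rbar - 2.0) ** 2)
        assert res.statistic == pytest.approx(expected, rel=1e-12)

    def test_missing_cells_rejected(self):
        mat = np.array([[1.0, 2.0, 3.0], [1.0, np.nan, 2.0]])
        with pytest.raises(ValueError, match="missing cells"):
            friedman_dunn(mat)

    def test_null_calibration(self, rng):
        reps = 10_000
        rejections = 0
        for _ in range(reps):
            mat = rng.normal(size=(15, 5))
            rejections += friedman_dunn(mat, adjust="none").p_value < 0.05
        assert 0.04 <= rejections / reps <= 0.06

    def test_dunn_adjustment_bounds(self, rng):
        mat = rng.normal(size=(8, 4)) + np.array([0.0, 0.2, 0.8, 1.5])
        res = friedman_dunn(mat)
        for comp in res.comparisons:
            assert comp.p_value <= comp.p_adjusted <= 1.0


def test_significance_stars():
    assert significance_stars(0.2) == "ns"
    assert significance_stars(0.03) == "*"
    assert significance_stars(0.005) == "**"
    assert significance_stars(5e-4) == "***"
    assert significance_stars(5e-5) == "****"
    with pytest.raises(ValueError):
        significance_stars(1.5)
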