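import math
from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from occlucontact.cohort_stats import (
    CohortContentError,
    SubjectRecord,
    best_strategy,
    column_strategy,
    exclude_outliers,
    frame_to_records,
    mann_whitney_u,
    pearson_profile,
    records_to_frame,
    strategy_column,
    summarize_groups,
)
from occlucontact.synthetic_data import CohortSimParams, simulate_cohort


def _record(sid, x50, oca_values, group="normal_occlusion"):
    keys = [(100.0, "3d"), (200.0, "3d"), (200.0, "2d")]
    return SubjectRecord(subject_id=sid, group=group, x50=x50,
                         oca=dict(zip(keys, oca_values)))


class TestExcludeOutliers:
    def test_two_sd_rule_hand_computed(self):
        """{4.5, 4.6, 4.7, 4.4, 4.5, 9.0}: only 9.0 deviates > 2 sample SD."""
        vals = [4.5, 4.6, 4.7, 4.4, 4.5, 9.0]
        records = [_record(f"s{i}", v, [1, 2, 1.5]) for i, v in enumerate(vals)]
        kept, excluded = exclude_outliers(records)
        assert excluded == ["s5"]
        assert len(kept) == 5

    def test_all_equal_values_keep_everything(self):
        records = [_record(f"s{i}", 4.5, [1, 2, 1.5]) for i in range(5)]
        kept, excluded = exclude_outliers(records)
        assert excluded == [] and len(kept) == 5

    def test_infinite_k_is_identity(self):
        records = [_record(f"s{i}", v, [1, 2, 1.5])
                   for i, v in enumerate([1.0, 2.0, 50.0])]
        kept, excluded = exclude_outliers(records, k_sd=math.inf)
        assert excluded == [] and len(kept) == 3

    def test_groupwise_application(self):
        normal = [_record(f"n{i}", v, [1, 2, 1.5])
                  for i, v in enumerate([4.5, 4.6, 4.7, 4.4, 4.5, 9.0])]
        mal = [_record(f"m{i}", v, [1, 2, 1.5], group="malocclusion")
               for i, v in enumerate([5.3, 5.4, 5.5, 5.2])]
        kept, excluded = exclude_outliers(normal + mal)
        assert excluded == ["n5"]
        assert sum(r.group == "malocclusion" for r in kept) == 4


class TestPearsonProfile:
    def test_perfect_negative_linear_relation(self):
        records = [_record(f"s{i}", 10.0 - oca, [oca, oca, oca])
                   for i, oca in enumerate([1.0, 2.0, 3.0, 4.0])]
        prof = pearson_profile(records)
        for entry in prof.entries.values():
            assert entry.r == pytest.approx(-1.0, abs=1e-12)

    def test_hand_computed_three_point_value(self):
        """x50 (1,2,3) vs oca (1,3,2): r = cov/sd_x/sd_y = 0.5/1 = 0.5."""
        records = [_record("a", 1.0, [1, 1, 1]), _record("b", 2.0, [3, 3, 3]),
                   _record("c", 3.0, [2, 2, 2])]
        prof = pearson_profile(records)
        entry = prof.entries[(200.0, "3d")]
        assert entry.r == pytest.approx(0.5, abs=1e-12)

    def test_constant_strategy_is_undefined_not_zero(self):
        records = [_record(f"s{i}", float(i + 1), [5.0, float(i), float(i)])
                   for i in range(4)]
        prof = pearson_profile(records)
        assert not prof.entries[(100.0, "3d")].defined
        assert math.isnan(prof.entries[(100.0, "3d")].r)

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(5, 0.5, 10)
        y = rng.normal(40, 8, 10)
        base = [_record(f"s{i}", xi, [yi, yi, yi])
                for i, (xi, yi) in enumerate(zip(x, y))]
        scaled = [_record(f"s{i}", xi, [7.3 * yi + 120.0] * 3)
                  for i, (xi, yi) in enumerate(zip(x, y))]
        r0 = pearson_profile(base).entries[(200.0, "3d")].r
        r1 = pearson_profile(scaled).entries[(200.0, "3d")].r
        assert r1 == pytest.approx(r0, abs=1e-12)

    def test_too_few_records_rejected(self):
        records = [_record("a", 1.0, [1, 2, 3]), _record("b", 2.0, [2, 3, 4])]
        with pytest.raises(CohortContentError):
            pearson_profile(records)


class TestBestStrategy:
    def _profile(self, r_by_key):
        records = []
        rng = np.random.default_rng(0)
        # build an exact-profile stub via direct entry injection
        from occlucontact.cohort_stats import CorrelationEntry, CorrelationProfile

        entries = {k: CorrelationEntry(r=v, p=0.01, n=20)
                   for k, v in r_by_key.items()}
        return CorrelationProfile(entries=entries)

    def test_planted_minimum_found(self):
        prof = self._profile({(100.0, "3d"): -0.3, (200.0, "3d"): -0.9,
                              (200.0, "2d"): -0.5})
        key, r = best_strategy(prof)
        assert key == (200.0, "3d") and r == -0.9

    def test_tie_breaks_to_smaller_offset(self):
        prof = self._profile({(150.0, "3d"): -0.8, (300.0, "3d"): -0.8})
        key, _ = best_strategy(prof)
        assert key == (150.0, "3d")

    def test_tie_breaks_3d_before_2d(self):
        prof = self._profile({(150.0, "2d"): -0.8, (150.0, "3d"): -0.8})
        key, _ = best_strategy(prof)
        assert key == (150.0, "3d")

    def test_positive_expectation_on_all_negative_profile(self):
        prof = self._profile({(100.0, "3d"): -0.3, (200.0, "3d"): -0.9})
        key, r = best_strategy(prof, expected_sign="positive")
        assert key == (100.0, "3d") and r == -0.3

    def test_either_sign_picks_largest_magnitude(self):
        prof = self._profile({(100.0, "3d"): 0.85, (200.0, "3d"): -0.6})
        key, _ = best_strategy(prof, expected_sign="either")
        assert key == (100.0, "3d")


class TestMannWhitney:
    def test_separated_pairs_enumeration(self):
        """{1,2} vs {3,4}: U = 0 and exact two-sided p = 2/6."""
        comp = mann_whitney_u([1, 2], [3, 4])
        assert comp.u_stat == 0.0
        assert comp.p_value == pytest.approx(1.0 / 3.0)
        assert comp.method == "exact"

    def test_identical_groups_give_p_one(self):
        comp = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert comp.p_value == pytest.approx(1.0)

    def test_exact_matches_scipy_on_tie_free_data(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a = rng.normal(size=rng.integers(2, 6))
            b = rng.normal(size=rng.integers(2, 6))
            ours = mann_whitney_u(a, b, mode="exact")
            ref = stats.mannwhitneyu(a, b, alternative="two-sided",
                                     method="exact")
            assert ours.u_stat == pytest.approx(ref.statistic)
            assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approximation_close_to_exact(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(size=6), rng.normal(size=6)
        exact = mann_whitney_u(a, b, mode="exact").p_value
        approx = mann_whitney_u(a, b, mode="normal_approx").p_value
        assert abs(exact - approx) < 0.05

    def test_exact_handles_ties_with_midranks(self):
        comp = mann_whitney_u([1, 2, 2], [2, 3, 4], mode="exact")
        assert 0 <= comp.u_stat <= 9
        assert 0 < comp.p_value <= 1

    def test_empty_group_rejected(self):
        with pytest.raises(CohortContentError):
            mann_whitney_u([], [1.0])


class TestSummarizeGroups:
    def test_quartiles_linear_interpolation_convention(self):
        """Quartiles of 1..8 under type-7 interpolation: 2.75 and 6.25."""
        records = [_record(f"s{i}", float(i + 1), [1, 2, 1.5])
                   for i in range(8)]
        comp = summarize_groups(records)
        row = comp.descriptives.query("variable == 'x50_mm'").iloc[0]
        assert row["q1"] == pytest.approx(2.75)
        assert row["q3"] == pytest.approx(6.25)
        assert row["median_range"] == "4.50 (1.00-8.00)"

    def test_single_record_group(self):
        records = [_record("a", 4.2, [1, 2, 1.5]),
                   _record("b", 5.0, [1, 2, 1.5], group="malocclusion")]
        comp = summarize_groups(records)
        row = comp.descriptives.query(
            "variable == 'x50_mm' and group == 'normal_occlusion'").iloc[0]
        assert row["mean"] == row["median"] == 4.2
        assert math.isnan(row["sd"])

    def test_simulated_group_means_recovered(self):
        records = simulate_cohort(CohortSimParams(
            n_normal=400, n_malocclusion=400, seed=21))
        comp = summarize_groups(records)
        d = comp.descriptives
        m_norm = d.query("group == 'normal_occlusion' and variable == 'x50_mm'"
                         ).iloc[0]["mean"]
        m_mal = d.query("group == 'malocclusion' and variable == 'x50_mm'"
                        ).iloc[0]["mean"]
        assert m_norm == pytest.approx(4.58, abs=3 * 0.37 / 20)
        assert m_mal == pytest.approx(5.35, abs=3 * 0.43 / 20)
        assert comp.p_value < 1e-6


class TestFrameRoundTrip:
    def test_column_naming(self):
        assert strategy_column((200.0, "3d")) == "oca_200um_3d_mm2"
        assert column_strategy("oca_200um_3d_mm2") == (200.0, "3d")

    def test_records_survive_frame_round_trip(self):
        records = simulate_cohort(CohortSimParams(n_normal=4,
                                                  n_malocclusion=3, seed=2))
        back = frame_to_records(records_to_frame(records))
        assert len(back) == len(records)
        assert back[0].oca == records[0].oca
        assert back[0].x50 == records[0].x50

    def test_missing_strategy_column_rejected(self):
        df = records_to_frame(simulate_cohort(CohortSimParams(
            n_normal=4, n_malocclusion=3, seed=2)))
        with pytest.raises(CohortContentError):
            frame_to_records(df.drop(columns=["x50_mm"]))
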