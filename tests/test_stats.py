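"""Exact tests vs enumeration oracles and scipy, percentiles, comparisons."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

from dischargesat import (
    bonferroni_threshold,
    compare_arms,
    compare_items_within,
    fisher_exact,
    mann_whitney,
    percentile_table,
    wilcoxon_signed_rank,
)
from oracles import fisher_oracle, mann_whitney_oracle, signed_rank_oracle


class TestFisher:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ([[5, 5], [5, 5]], 1.0),
            ([[2, 0], [0, 2]], 1 / 3),
            ([[3, 0], [0, 3]], 0.1),
        ],
    )
    def test_enumerated_values(self, table, expected):
        assert fisher_exact(table).p_value == pytest.approx(expected, abs=1e-12)

    def test_strong_association_is_tiny(self):
        assert fisher_exact([[168, 262], [381, 56]]).p_value < 1e-3

    def test_negative_counts_error(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, -1], [2, 3]])

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            t = rng.integers(0, 30, size=(2, 2))
            ours = fisher_exact(t).p_value
            ref = scipy.stats.fisher_exact(t).pvalue
            assert ours == pytest.approx(ref, abs=1e-10)


class TestMannWhitney:
    def test_fully_separated_small_samples(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.method == "exact_enumeration"
        assert res.p_value == pytest.approx(0.1)

    def test_identical_samples_give_p_one(self):
        res = mann_whitney([1, 2, 2, 3], [1, 2, 2, 3])
        assert res.p_value == 1.0

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_symmetry_in_sample_order(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.choice([0, 0.5, 1.0], rng.integers(2, 6))
            y = rng.choice([0, 0.5, 1.0], rng.integers(2, 6))
            assert mann_whitney(x, y).p_value == pytest.approx(
                mann_whitney(y, x).p_value, abs=1e-12
            )

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            x = rng.permutation(20)[: rng.integers(2, 6)].astype(float)
            pool = [v for v in range(20, 45)]
            y = rng.permutation(pool)[: rng.integers(2, 6)].astype(float)
            xy = np.concatenate([x, y])
            if len(np.unique(xy)) < len(xy):
                continue
            ours = mann_whitney(x, y).p_value
            ref = scipy.stats.mannwhitneyu(x, y, method="exact").pvalue
            assert ours == pytest.approx(ref, abs=1e-10)

    def test_approx_agrees_with_exact_in_significance_region(self):
        """Tie-corrected normal approximation tracks the exact permutation
        p within 0.02 wherever the exact p is at or below 0.05 (score-like
        lattice data, m = n = 8)."""
        rng = np.random.default_rng(42)
        checked = 0
        gaps = []
        while checked < 50:
            x = rng.choice([0, 0.25, 0.5, 0.75, 1.0], 8)
            y = rng.choice([0, 0.25, 0.5, 0.75, 1.0], 8)
            p_exact = mann_whitney(x, y).p_value
            if p_exact > 0.05:
                continue
            p_approx = mann_whitney(x, y, exact_threshold=0).p_value
            gaps.append(abs(p_exact - p_approx))
            checked += 1
        assert max(gaps) <= 0.02

    def test_degenerate_constant_data(self):
        res = mann_whitney([1.0] * 30, [1.0] * 30)
        assert res.degenerate and res.p_value == 1.0


class TestSignedRank:
    def test_all_positive_small(self):
        res = wilcoxon_signed_rank([1, 2, 3])
        assert res.p_value == pytest.approx(0.25)
        assert res.statistic == 6.0

    def test_symmetric_diffs_give_p_one(self):
        assert wilcoxon_signed_rank([-2, -1, 1, 2]).p_value == 1.0

    def test_all_zero_flagged_degenerate(self):
        res = wilcoxon_signed_rank([0, 0])
        assert res.degenerate and res.p_value == 1.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([])

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            n = rng.integers(3, 10)
            d = rng.permutation(np.arange(1, 30))[:n] * rng.choice([-1.0, 1.0], n)
            ours = wilcoxon_signed_rank(d).p_value
            ref = scipy.stats.wilcoxon(d, mode="exact").pvalue
            assert ours == pytest.approx(ref, abs=1e-10)


class TestOracleEquivalence:
    """Exact paths vs independent brute-force enumeration, total n <= 8."""

    def test_fisher_sweep(self):
        rng = np.random.default_rng(100)
        for _ in range(400):
            a, b, c, d = rng.multinomial(rng.integers(1, 9), [0.25] * 4)
            assert fisher_exact([[a, b], [c, d]]).p_value == pytest.approx(
                fisher_oracle(a, b, c, d), abs=1e-12
            )

    def test_mann_whitney_sweep(self):
        rng = np.random.default_rng(101)
        for _ in range(300):
            m = int(rng.integers(1, 7))
            n = int(rng.integers(1, 9 - m)) if m < 8 else 1
            x = rng.choice([0.0, 1.0, 2.0], m)
            y = rng.choice([0.0, 1.0, 2.0], n)
            assert mann_whitney(x, y).p_value == pytest.approx(
                mann_whitney_oracle(x, y), abs=1e-12
            )

    def test_signed_rank_sweep(self):
        rng = np.random.default_rng(102)
        for _ in range(300):
            n = int(rng.integers(1, 9))
            d = rng.choice([-2.0, -1.0, 0.0, 1.0, 2.0], n)
            if np.all(d == 0):
                continue
            assert wilcoxon_signed_rank(d).p_value == pytest.approx(
                signed_rank_oracle(d), abs=1e-12
            )


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha, k, expected", [(0.05, 2, 0.025), (0.05, 1, 0.05), (0.06, 3, 0.02)]
    )
    def test_threshold(self, alpha, k, expected):
        assert bonferroni_threshold(alpha, k) == pytest.approx(expected)

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestPercentiles:
    def test_two_point_median(self):
        t = percentile_table([0, 1], levels=[50])
        assert t.values == (0.5,)

    def test_interpolated_low_level(self):
        t = percentile_table([0.25, 0.25, 0.5], levels=[10])
        assert t.values[0] == pytest.approx(0.25)

    def test_constant_sample(self):
        t = percentile_table([0.7] * 5)
        assert all(v == 0.7 for v in t.values)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            percentile_table([])

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30))
    def test_order_invariant_and_nondecreasing(self, xs):
        t1 = percentile_table(xs)
        t2 = percentile_table(list(reversed(xs)))
        assert t1.values == t2.values
        assert all(b >= a for a, b in zip(t1.values, t1.values[1:]))


def _score_frame(rng, n, arms=("telephone", "internet")):
    rows = []
    for arm in arms:
        for _ in range(n):
            sub = rng.choice([0, 0.25, 0.5, 0.75, 1.0], 3)
            rows.append(
                {
                    "arm": arm,
                    "logistics": sub[0],
                    "continuity": sub[1],
                    "impressions": sub[2],
                    "total": sub.mean(),
                }
            )
    return pd.DataFrame(rows)


class TestCompareArms:
    def test_shared_dataset_gives_p_one(self):
        rng = np.random.default_rng(1)
        half = _score_frame(rng, 8, arms=("telephone",))
        mirrored = pd.concat(
            [half, half.assign(arm="internet")], ignore_index=True
        )
        rep = compare_arms(mirrored, comparisons=[("telephone", "internet")])
        for t in rep.tests:
            assert t["result"].p_value == 1.0
            assert t["result"].method == "exact_enumeration"

    def test_adjusted_threshold_and_flags(self):
        rng = np.random.default_rng(2)
        frame = _score_frame(rng, 50, arms=("telephone", "internet", "noneligible"))
        rep = compare_arms(frame, alpha=0.05)
        assert rep.adjusted_alpha == 0.025
        for t in rep.tests:
            assert t["significant"] == (t["result"].p_value <= 0.025)

    def test_absent_arm_lists_available(self):
        frame = _score_frame(np.random.default_rng(3), 10, arms=("telephone",))
        with pytest.raises(ValueError, match="telephone"):
            compare_arms(frame, comparisons=[("telephone", "internet")])

    def test_percentile_tables_cover_all_groups(self):
        rng = np.random.default_rng(4)
        frame = _score_frame(rng, 30, arms=("telephone", "internet", "noneligible"))
        rep = compare_arms(frame)
        for col in ("total", "logistics", "continuity", "impressions"):
            assert set(rep.percentiles[col]) == {"all", "telephone", "internet", "noneligible"}
            for t in rep.percentiles[col].values():
                assert all(b >= a - 1e-12 for a, b in zip(t.values, t.values[1:]))


class TestCompareItemsWithin:
    def test_constructed_strict_ordering(self):
        # every patient: continuity < logistics < impressions
        rng = np.random.default_rng(5)
        base = rng.uniform(0.1, 0.6, 40)
        frame = pd.DataFrame(
            {
                "arm": "telephone",
                "continuity": base,
                "logistics": base + 0.2,
                "impressions": base + 0.35,
            }
        )
        frame["total"] = frame[["logistics", "continuity", "impressions"]].mean(axis=1)
        rep = compare_items_within(frame)
        by_pair = {p["pair"]: p for p in rep.pairs}
        assert by_pair["logistics-continuity"]["direction"] == 1
        assert by_pair["impressions-logistics"]["direction"] == 1
        assert all(p["result"].p_value < 1e-6 for p in rep.pairs)

    def test_identical_items_degenerate(self):
        frame = pd.DataFrame(
            {"arm": "x", "logistics": [0.5] * 5, "continuity": [0.5] * 5,
             "impressions": [0.5] * 5, "total": [0.5] * 5}
        )
        rep = compare_items_within(frame)
        assert all(p["result"].degenerate for p in rep.pairs)

    def test_too_few_pairs_errors(self):
        frame = pd.DataFrame(
            {"arm": "x", "logistics": [0.5], "continuity": [0.4],
             "impressions": [0.6], "total": [0.5]}
        )
        with pytest.raises(ValueError):
            compare_items_within(frame)


class TestNullCalibration:
    """Type-I error of the exact tests near the nominal level."""

    def test_fisher_size(self):
        rng = np.random.default_rng(1000)
        rej = 0
        reps = 1000
        for _ in range(reps):
            a = rng.binomial(200, 0.5)
            c = rng.binomial(200, 0.5)
            if fisher_exact([[a, 200 - a], [c, 200 - c]]).p_value <= 0.05:
                rej += 1
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rej / reps - 0.05) <= 3 * se

    def test_signed_rank_size(self):
        rng = np.random.default_rng(2000)
        rej = 0
        reps = 1000
        for _ in range(reps):
            d = rng.normal(0, 1, 60)
            if wilcoxon_signed_rank(d).p_value <= 0.05:
                rej += 1
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rej / reps - 0.05) <= 3 * se
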