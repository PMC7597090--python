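"""Directional splits, the Monte Carlo weight-sum test, BH adjustment, run_tmea."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmea import (
    AnnotationCatalog,
    bh_adjust,
    monte_carlo_pvalue,
    plant_catalog,
    run_tmea,
    split_directional,
)


def enumeration_pvalue(pool, s, observed, direction):
    """Independent exhaustive-enumeration oracle for the permutation p-value."""
    hits = total = 0
    for combo in combinations(pool, s):
        w = sum(combo)
        hits += (w >= observed) if direction == "positive" else (w <= observed)
        total += 1
    return hits / total


class TestSplitDirectional:
    def test_zero_weights_belong_to_neither_subset(self):
        weights = {"a": 1.0, "b": 2.0, "c": -3.0, "d": 0.0}
        split = split_directional(weights, weights, "f", 1)
        assert split.s_plus == 2 and split.w_hat_plus == pytest.approx(3.0)
        assert split.s_minus == 1 and split.w_hat_minus == pytest.approx(-3.0)

    def test_all_positive_weights_leave_negative_subset_empty(self):
        weights = {"a": 1.0, "b": 0.5}
        split = split_directional(weights, weights, "f", 1)
        assert split.s_minus == 0 and split.w_hat_minus == 0.0

    def test_unmeasured_members_dropped(self):
        split = split_directional({"a": 1.0}, ["a", "ghost"], "f", 1)
        assert split.s_plus == 1

    def test_empty_member_set_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            split_directional({"a": 1.0}, [], "f", 1)

    @given(
        st.lists(
            st.floats(-5, 5, allow_nan=False, allow_infinity=False),
            min_size=1,
            max_size=20,
        )
    )
    @settings(deadline=None, max_examples=50)
    def test_directional_sums_partition_the_nonzero_total(self, values):
        weights = {f"e{i}": v for i, v in enumerate(values)}
        split = split_directional(weights, weights, "f", 1)
        nonzero_total = sum(v for v in values if v != 0)
        assert split.w_hat_plus + split.w_hat_minus == pytest.approx(
            nonzero_total, abs=1e-9
        )
        n_zero = sum(v == 0 for v in values)
        assert split.s_plus + split.s_minus + n_zero == len(values)


class TestMonteCarloPValue:
    def test_worked_example_exact_third(self):
        # subsets of {1,2,3} of size 2 sum to 3, 4, 5; one of three reaches 5
        assert enumeration_pvalue([1, 2, 3], 2, 5, "positive") == pytest.approx(1 / 3)
        result = monte_carlo_pvalue([1, 2, 3], 2, 5.0, 10_000, "positive", seed=0)
        # 99% binomial interval around 1/3 at b = 10,000
        assert abs(result.p - 1 / 3) < 2.58 * np.sqrt((1 / 3) * (2 / 3) / 10_000)

    def test_degenerate_pool_ties_count_as_extreme(self):
        result = monte_carlo_pvalue([1.0, 1, 1], 2, 2.0, 500, "positive", seed=1)
        assert result.p == 1.0

    def test_observed_at_support_minimum_gives_p_one(self):
        pool = [0.5, 1.0, 2.0, 4.0]
        observed = 0.5 + 1.0  # the two smallest
        result = monte_carlo_pvalue(pool, 2, observed, 500, "positive", seed=2)
        assert result.p == 1.0

    def test_negative_direction_mirrors_positive(self):
        pool = [-1.0, -2.0, -3.0]
        assert enumeration_pvalue(pool, 2, -5, "negative") == pytest.approx(1 / 3)
        result = monte_carlo_pvalue(pool, 2, -5.0, 10_000, "negative", seed=3)
        assert abs(result.p - 1 / 3) < 2.58 * np.sqrt((1 / 3) * (2 / 3) / 10_000)

    def test_p_monotone_in_observed_sum(self):
        pool = np.random.default_rng(4).uniform(0.1, 1, size=30)
        ps = [
            monte_carlo_pvalue(pool, 5, w, 2000, "positive", seed=5).p
            for w in np.linspace(0.5, 5, 8)
        ]
        assert all(b <= a for a, b in zip(ps, ps[1:]))

    def test_reproducible_given_seed(self):
        pool = np.random.default_rng(6).uniform(0.1, 1, size=50)
        r1 = monte_carlo_pvalue(pool, 8, 4.0, 3000, "positive", seed=42)
        r2 = monte_carlo_pvalue(pool, 8, 4.0, 3000, "positive", seed=42)
        assert r1.p == r2.p and r1.n_extreme == r2.n_extreme

    def test_p_is_a_multiple_of_the_resolution(self):
        result = monte_carlo_pvalue([1.0, 2, 3, 4], 2, 5.0, 777, "positive", seed=7)
        assert result.resolution == pytest.approx(1 / 777)
        assert result.p * 777 == pytest.approx(round(result.p * 777))

    def test_add_one_estimator(self):
        r = monte_carlo_pvalue(
            [1.0, 2, 3], 2, 6.0, 100, "positive", seed=8, estimator="add_one"
        )
        assert r.p == pytest.approx((r.n_extreme + 1) / 101)

    def test_bootstrap_mode_runs_and_differs_in_support(self):
        # with replacement, a subset can repeat the largest weight
        pool = [1.0, 10.0]
        r = monte_carlo_pvalue(
            pool, 2, 15.0, 2000, "positive", seed=9, replace=True
        )
        assert r.p > 0  # {10,10} sums to 20 >= 15; impossible without replacement

    @pytest.mark.parametrize(
        "kwargs,match",
        [
            (dict(pool=[1.0], subset_size=2, b=10), "pool of size"),
            (dict(pool=[1.0, 2], subset_size=1, b=0), "b must be"),
            (dict(pool=[1.0, -2], subset_size=1, b=10), "strictly positive"),
        ],
    )
    def test_precondition_violations(self, kwargs, match):
        with pytest.raises(ValueError, match=match):
            monte_carlo_pvalue(
                kwargs["pool"], kwargs["subset_size"], 1.0, kwargs["b"], "positive", 0
            )


class TestBhAdjust:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.01, 0.04, 0.9], [0.03, 0.06, 0.9]),
            ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
        ],
    )
    def test_step_up_hand_examples(self, p, expected):
        np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    def test_order_preserved(self):
        q = bh_adjust([0.9, 0.01, 0.04])
        np.testing.assert_allclose(q, [0.9, 0.03, 0.06], atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_empty_input(self):
        assert bh_adjust([]) == []


class TestRunTmea:
    def catalog(self, decomp, sizes, seed=0):
        rng = np.random.default_rng(seed)
        ids = np.asarray(decomp.entity_ids)
        return AnnotationCatalog(
            {
                f"set{j}": set(ids[rng.choice(len(ids), size=s, replace=False)])
                for j, s in enumerate(sizes)
            }
        )

    def test_small_sets_filtered_out(self, synthetic_study):
        _, _, decomp = synthetic_study
        catalog = self.catalog(decomp, [4, 12])
        records = run_tmea(decomp, catalog, [1], b=200, min_set_size=5, seed=0)
        assert {r.fas_id for r in records} == {"set1"}

    def test_two_directional_descriptors_per_constraint(self, synthetic_study):
        _, _, decomp = synthetic_study
        catalog = self.catalog(decomp, [20])
        records = run_tmea(decomp, catalog, [1, 2], b=200, seed=0)
        assert {(r.constraint, r.direction) for r in records} == {
            (1, "positive"),
            (1, "negative"),
            (2, "positive"),
            (2, "negative"),
        }

    def test_records_reproducible_and_sorted(self, synthetic_study):
        _, _, decomp = synthetic_study
        catalog = self.catalog(decomp, [10, 15, 25], seed=3)
        r1 = run_tmea(decomp, catalog, [1, 2], b=500, seed=7)
        r2 = run_tmea(decomp, catalog, [1, 2], b=500, seed=7)
        assert [(a.fas_id, a.p_empirical, a.q_bh) for a in r1] == [
            (a.fas_id, a.p_empirical, a.q_bh) for a in r2
        ]
        keys = [(r.constraint, r.direction, r.q_bh, r.fas_id) for r in r1]
        assert keys == sorted(keys)

    def test_q_dominates_p_and_lies_in_unit_interval(self, synthetic_study):
        _, _, decomp = synthetic_study
        catalog = self.catalog(decomp, [10, 20, 30, 40], seed=4)
        for r in run_tmea(decomp, catalog, [1], b=500, seed=1):
            assert 0 <= r.p_empirical <= r.q_bh <= 1

    def test_results_independent_of_catalog_insertion_order(self, synthetic_study):
        _, _, decomp = synthetic_study
        catalog = self.catalog(decomp, [10, 15, 20], seed=5)
        reversed_catalog = AnnotationCatalog(dict(reversed(list(catalog.sets.items()))))
        r1 = run_tmea(decomp, catalog, [1], b=500, seed=9)
        r2 = run_tmea(decomp, reversed_catalog, [1], b=500, seed=9)
        assert [(a.fas_id, a.p_empirical) for a in r1] == [
            (a.fas_id, a.p_empirical) for a in r2
        ]

    def test_no_qualifying_set_yields_empty_result(self, synthetic_study):
        _, _, decomp = synthetic_study
        catalog = self.catalog(decomp, [5, 6])
        assert run_tmea(decomp, catalog, [1], b=200, min_set_size=50, seed=0) == []

    def test_disjoint_catalog_is_an_error(self, synthetic_study):
        _, _, decomp = synthetic_study
        catalog = AnnotationCatalog({"s": {"nope1", "nope2"}})
        with pytest.raises(ValueError, match="measured"):
            run_tmea(decomp, catalog, [1], b=200, seed=0)

    def test_planted_shift_set_detected(self, synthetic_study):
        truth, _, decomp = synthetic_study
        catalog = plant_catalog(
            truth,
            n_null_sets=20,
            archetype_params=[
                {"archetype": "shift", "constraint": 1, "size": 30}
            ],
            seed=21,
        )
        records = run_tmea(decomp, catalog, [1], b=5000, seed=22)
        planted = [
            r
            for r in records
            if r.fas_id.startswith("planted_shift") and r.direction == "positive"
        ]
        assert planted and planted[0].q_bh < 0.05
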