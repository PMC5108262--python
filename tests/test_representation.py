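"""Accumulation curves, optimal and random baselines, SAI."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prwr.core_data import OccurrenceMatrix
from prwr.errors import CapabilityError, ConsistencyError, EvaluationError
from prwr.representation import (
    AccumulationCurve,
    accumulation_curve,
    exact_optimal_curve,
    expected_random_curve,
    fraction_steps,
    greedy_optimal_curve,
    monte_carlo_random_curve,
    sai,
)
from prwr.rwr import SiteScores

from conftest import random_occurrence


def scores_of(occ, values):
    return SiteScores(dict(zip(map(str, occ.site_ids), values)), "PRWR")


class TestAccumulationCurve:
    def test_nested_sets_hand_count(self, tiny_occ):
        curve = accumulation_curve(tiny_occ, scores_of(tiny_occ, [3.0, 2.0, 1.0]))
        assert curve.ordered_sites == ("a", "b", "c")
        assert curve.S_k.tolist() == [4, 4, 4]
        curve2 = accumulation_curve(tiny_occ, scores_of(tiny_occ, [1.0, 2.0, 3.0]))
        assert curve2.ordered_sites == ("c", "b", "a")
        assert curve2.S_k.tolist() == [1, 3, 4]

    def test_all_equal_scores_follow_seeded_shuffle(self, tiny_occ):
        a = accumulation_curve(tiny_occ, scores_of(tiny_occ, [1, 1, 1]), seed=5)
        b = accumulation_curve(tiny_occ, scores_of(tiny_occ, [1, 1, 1]), seed=5)
        assert a.ordered_sites == b.ordered_sites
        orders = {
            accumulation_curve(tiny_occ, scores_of(tiny_occ, [1, 1, 1]), seed=s).ordered_sites
            for s in range(20)
        }
        assert len(orders) > 1  # ties genuinely shuffle across seeds

    def test_matches_set_union_oracle(self):
        rng = np.random.default_rng(61)
        for _ in range(20):
            occ = random_occurrence(rng, 12, 15, ensure_occupied=False)
            vals = rng.random(12)
            curve = accumulation_curve(occ, scores_of(occ, vals), seed=0)
            index = {str(s): i for i, s in enumerate(occ.site_ids)}
            for k in (1, 4, 12):
                rows = [index[s] for s in curve.ordered_sites[:k]]
                union = occ.presence[rows].any(axis=0).sum()
                assert curve.at(k) == union

    def test_score_site_mismatch_rejected(self, tiny_occ):
        with pytest.raises(ConsistencyError):
            accumulation_curve(tiny_occ, SiteScores({"a": 1.0}, "PRWR"))


class TestGreedyOptimal:
    def test_disjoint_sets_picked_largest_first(self, disjoint_occ):
        curve = greedy_optimal_curve(disjoint_occ)
        assert curve.ordered_sites == ("s1", "s2", "s3")
        assert curve.S_k.tolist() == [5, 8, 9]

    def test_single_site_with_all_species(self):
        presence = np.array([[1, 1, 1], [1, 0, 0], [0, 1, 0]])
        occ = OccurrenceMatrix(
            np.array(["all", "p", "q"], dtype=object),
            np.array(["x", "y", "z"], dtype=object),
            presence,
        )
        curve = greedy_optimal_curve(occ)
        assert curve.ordered_sites[0] == "all"
        assert curve.at(1) == 3

    def test_greedy_against_exhaustive_oracle(self):
        """On small instances greedy respects the (1 - 1/e) guarantee and is
        usually exactly optimal."""
        rng = np.random.default_rng(62)
        exact_hits = 0
        n_trials = 40
        for _ in range(n_trials):
            occ = random_occurrence(rng, 8, 10, density=0.25, ensure_occupied=False)
            greedy = greedy_optimal_curve(occ)
            exact = exact_optimal_curve(occ, occ.n_sites)
            assert np.all(greedy.S_k >= (1 - 1 / np.e) * exact.S_k - 1e-9)
            assert np.all(greedy.S_k <= exact.S_k + 1e-9)
            if np.allclose(greedy.S_k, exact.S_k):
                exact_hits += 1
        assert exact_hits >= 0.9 * n_trials


class TestExactOptimal:
    def test_matches_greedy_on_disjoint_sets(self, disjoint_occ):
        exact = exact_optimal_curve(disjoint_occ, 3)
        assert exact.S_k.tolist() == [5, 8, 9]

    def test_crafted_instance_where_greedy_suboptimal(self):
        # site A covers 5 species; B and C jointly cover 8 disjoint ones.
        # Greedy opens with A (largest gain) and can only reach 7 by k=2.
        species = [f"t{i}" for i in range(1, 10)]
        rows = {
            "A": {"t1", "t2", "t3", "t4", "t9"},
            "B": {"t1", "t2", "t5", "t6"},
            "C": {"t3", "t4", "t7", "t8"},
        }
        presence = np.array(
            [[1 if sp in rows[s] else 0 for sp in species] for s in ("A", "B", "C")]
        )
        occ = OccurrenceMatrix(
            np.array(["A", "B", "C"], dtype=object),
            np.array(species, dtype=object),
            presence,
        )
        greedy = greedy_optimal_curve(occ)
        exact = exact_optimal_curve(occ, 3)
        assert greedy.ordered_sites[0] == "A"
        assert greedy.at(2) == 7
        assert exact.at(2) == 8
        assert exact.at(2) > greedy.at(2)

    def test_full_depth_reaches_total_species(self, occ_factory):
        occ = occ_factory(np.random.default_rng(63), 7, 9)
        exact = exact_optimal_curve(occ, 7)
        assert exact.at(7) == occ.n_species

    def test_too_many_sites_rejected(self, occ_factory):
        occ = occ_factory(np.random.default_rng(64), 21, 5)
        with pytest.raises(CapabilityError):
            exact_optimal_curve(occ, 2)


class TestExpectedRandom:
    def test_all_sites_represent_everything(self, occ_factory):
        occ = occ_factory(np.random.default_rng(65), 9, 12)
        curve = expected_random_curve(occ)
        assert curve.at(9) == pytest.approx(occ.n_species)

    def test_single_endemic_closed_form(self):
        n = 10
        presence = np.zeros((n, 1), dtype=int)
        presence[3, 0] = 1
        occ = OccurrenceMatrix(
            np.array([f"s{i}" for i in range(n)], dtype=object),
            np.array(["lonely"], dtype=object),
            presence,
        )
        curve = expected_random_curve(occ)
        for k in range(1, n + 1):
            assert curve.at(k) == pytest.approx(k / n)

    def test_within_monte_carlo_error(self, occ_factory):
        occ = occ_factory(np.random.default_rng(66), 20, 30, density=0.2)
        analytic = expected_random_curve(occ)
        mean, sd = monte_carlo_random_curve(occ, n_draws=4000, seed=1)
        se = sd / np.sqrt(4000)
        assert np.all(np.abs(analytic.S_k - mean) <= 3 * se + 1e-9)

    def test_random_never_beats_optimal(self, occ_factory):
        rng = np.random.default_rng(67)
        for _ in range(10):
            occ = random_occurrence(rng, 9, 14, ensure_occupied=False)
            R = expected_random_curve(occ)
            O = exact_optimal_curve(occ, 9)
            G = greedy_optimal_curve(occ)
            assert np.all(R.S_k <= O.S_k + 1e-9)
            assert np.all(G.S_k >= R.S_k - 1e-9)


class TestSai:
    def test_perfect_surrogacy_is_one(self, disjoint_occ):
        O = greedy_optimal_curve(disjoint_occ)
        R = expected_random_curve(disjoint_occ)
        S = AccumulationCurve(
            O.ordered_sites, O.S_k, "surrogate", O.n_sites, O.n_species
        )
        value = sai(S, O, R, fractions=(34, 67, 100))
        assert value.mean_sai == pytest.approx(1.0)
        assert all(v == pytest.approx(1.0) for v in value.sai_k.values())

    def test_random_performance_is_zero(self, disjoint_occ):
        O = greedy_optimal_curve(disjoint_occ)
        R = expected_random_curve(disjoint_occ)
        S = AccumulationCurve((), R.S_k, "surrogate", R.n_sites, R.n_species)
        value = sai(S, O, R, fractions=(34, 67, 100))
        assert value.mean_sai == pytest.approx(0.0, abs=1e-12)

    def test_single_step_arithmetic(self):
        mk = lambda s, kind: AccumulationCurve((), np.array([s], float), kind, 1, 12)
        value = sai(mk(7, "surrogate"), mk(10, "optimal"), mk(4, "random_expected"),
                    fractions=(100,))
        assert value.mean_sai == pytest.approx(0.5)

    def test_degenerate_steps_skipped(self):
        S = AccumulationCurve((), np.array([3.0, 5.75]), "surrogate", 2, 6)
        O = AccumulationCurve((), np.array([4.0, 6.0]), "optimal", 2, 6)
        R = AccumulationCurve((), np.array([4.0, 5.0]), "random_expected", 2, 6)
        value = sai(S, O, R, fractions=(50, 100))  # k=1 has O == R: skipped
        assert value.evaluated_steps == (2,)
        assert value.mean_sai == pytest.approx(0.75)

    def test_mismatched_landscapes_rejected(self, tiny_occ, disjoint_occ):
        with pytest.raises(ConsistencyError):
            sai(
                greedy_optimal_curve(tiny_occ),
                greedy_optimal_curve(disjoint_occ),
                expected_random_curve(disjoint_occ),
            )

    def test_all_steps_degenerate_rejected(self):
        S = AccumulationCurve((), np.array([2.0]), "surrogate", 1, 2)
        O = AccumulationCurve((), np.array([2.0]), "optimal", 1, 2)
        R = AccumulationCurve((), np.array([2.0]), "random_expected", 1, 2)
        with pytest.raises(EvaluationError):
            sai(S, O, R, fractions=(100,))

    def test_sai_never_exceeds_one_against_exact_optimum(self):
        rng = np.random.default_rng(68)
        for _ in range(15):
            occ = random_occurrence(rng, 8, 12, ensure_occupied=False)
            O = exact_optimal_curve(occ, 8)
            R = expected_random_curve(occ)
            for _ in range(3):
                S = accumulation_curve(occ, scores_of(occ, rng.random(8)), seed=0)
                value = sai(S, O, R, fractions=(25, 50, 75, 100))
                assert all(v <= 1 + 1e-9 for v in value.sai_k.values())

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_relabeling_invariance(self, seed):
        """SAI is unchanged by renaming species and permuting site ids."""
        rng = np.random.default_rng(seed)
        occ = random_occurrence(rng, 10, 8, ensure_occupied=False)
        vals = rng.random(10)
        v1 = sai(
            accumulation_curve(occ, scores_of(occ, vals), seed=3),
            greedy_optimal_curve(occ),
            expected_random_curve(occ),
            fractions=(20, 50, 100),
        )
        # permute species columns and rename everything
        perm = rng.permutation(occ.n_species)
        occ2 = OccurrenceMatrix(
            np.array([f"zz_{s}" for s in occ.site_ids], dtype=object),
            np.array([f"q{j}" for j in range(occ.n_species)], dtype=object),
            occ.presence[:, perm],
        )
        v2 = sai(
            accumulation_curve(occ2, SiteScores(
                {f"zz_{s}": v for s, v in zip(map(str, occ.site_ids), vals)}, "PRWR"
            ), seed=3),
            greedy_optimal_curve(occ2),
            expected_random_curve(occ2),
            fractions=(20, 50, 100),
        )
        assert v1.mean_sai == pytest.approx(v2.mean_sai, abs=1e-12)


def test_fraction_steps_round_half_up():
    assert fraction_steps(10, (5, 10, 50)) == [1, 5]  # 0.5 -> 1, dedup
    assert fraction_steps(1000, (5, 10)) == [50, 100]
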