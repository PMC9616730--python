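"""Tests of task-preference, categories, correlation analyses and the
silent-population simulation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from twotask2p import (
    PopulationActivity,
    categorize,
    compare_within_across,
    condition_correlation,
    correlation_matrix,
    cross_day_comparison,
    simulate_silent_population,
    task_preference,
)
from twotask2p.specificity import UndefinedCorrelationError, spearman


class TestTaskPreference:
    @pytest.mark.parametrize(
        "a, b, expected",
        [(2.0, 2.0, 0.0), (1.5, 0.0, 1.0), (0.0, 1.5, -1.0), (1.0, 3.0, -0.5)],
    )
    def test_examples(self, a, b, expected):
        assert task_preference(a, b) == pytest.approx(expected)

    def test_double_zero_is_missing(self):
        assert np.isnan(task_preference(0.0, 0.0))

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            task_preference(-1.0, 2.0)

    @settings(deadline=None, max_examples=100)
    @given(a=st.floats(0, 1e6), b=st.floats(0, 1e6))
    def test_bounded_and_consistent_with_categories(self, a, b):
        p = task_preference(a, b)
        if not np.isnan(p):
            assert -1.0 <= p <= 1.0
        if categorize(a, b, 0.0) == "TM-only":
            assert p > 0


class TestCategorize:
    @pytest.mark.parametrize(
        "a, b, thr, expected",
        [
            (0.5, 0.1, 0.3, "TM-only"),
            (0.1, 0.5, 0.3, "SW-only"),
            (0.31, 0.31, 0.3, "both"),
            (0.3, 0.3, 0.3, "neither"),  # strict inequality at the boundary
        ],
    )
    def test_examples(self, a, b, thr, expected):
        assert categorize(a, b, thr) == expected

    def test_vectorized_counts_sum_to_n(self, rng):
        a = rng.exponential(size=200)
        b = rng.exponential(size=200)
        cats = categorize(a, b, 0.5)
        counts = pd.Series(cats).value_counts()
        assert counts.sum() == 200


def _pop(data: dict) -> PopulationActivity:
    return PopulationActivity(activity=pd.DataFrame(data))


class TestConditionCorrelation:
    def test_monotone_transform_gives_unit_rho(self, rng):
        x = rng.exponential(size=30)
        pop = _pop({"TM": x, "SW": np.exp(x)})
        rho, p = condition_correlation(pop, "TM", "SW")
        assert rho == pytest.approx(1.0)
        assert p < 1e-6

    def test_reversed_ranks(self):
        x = np.arange(1.0, 9.0)
        pop = _pop({"TM": x, "SW": x[::-1]})
        rho, _ = condition_correlation(pop, "TM", "SW")
        assert rho == pytest.approx(-1.0)

    def test_tied_toy_matches_brute_force_ranks(self):
        """Six neurons with one tie: rho matches an explicit average-rank
        Pearson computation."""
        x = np.array([0.1, 0.4, 0.4, 0.7, 1.0, 1.3])
        y = np.array([0.2, 0.9, 0.3, 0.8, 1.1, 1.4])

        def avg_ranks(v):
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v))
            i = 0
            sv = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sv[j] == sv[i]:
                    j += 1
                ranks[order[i:j]] = (i + j - 1) / 2 + 1
                i = j
            return ranks

        rx, ry = avg_ranks(x), avg_ranks(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        rho, _ = condition_correlation(_pop({"TM": x, "SW": y}), "TM", "SW")
        assert rho == pytest.approx(expected, rel=1e-12)

    def test_constant_column_signaled(self):
        pop = _pop({"TM": [1.0, 1.0, 1.0, 1.0], "SW": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(UndefinedCorrelationError):
            condition_correlation(pop, "TM", "SW")

    def test_exact_p_matches_enumeration_oracle(self):
        """For n <= 10 the p-value equals the fraction of label pairings
        with |rho| at least as extreme, computed here independently with
        scipy's spearmanr per permutation."""
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0])
        y = np.array([2.0, 7.0, 1.0, 8.0, 2.0, 8.0])
        rho, p = spearman(x, y)
        rhos = [
            stats.spearmanr(x, np.array(perm)).statistic
            for perm in itertools.permutations(y)
        ]
        expected = np.mean(np.abs(rhos) >= abs(rho) - 1e-12)
        assert p == pytest.approx(expected, rel=1e-12)


class TestCorrelationMatrix:
    def test_identical_conditions_all_ones(self, rng):
        x = rng.exponential(size=20)
        rho, _ = correlation_matrix(_pop({"A": x, "B": x.copy()}))
        np.testing.assert_allclose(rho.to_numpy(), np.ones((2, 2)))

    def test_symmetric_unit_diagonal_and_matches_pairwise(self, rng):
        data = {c: rng.exponential(size=25) for c in ("TM", "SW", "PB")}
        pop = _pop(data)
        rho, pmat = correlation_matrix(pop)
        np.testing.assert_allclose(rho.to_numpy(), rho.to_numpy().T)
        np.testing.assert_allclose(np.diag(rho), 1.0)
        for ci, cj in itertools.combinations(data, 2):
            r, p = condition_correlation(pop, ci, cj)
            assert rho.loc[ci, cj] == pytest.approx(r)
            assert pmat.loc[ci, cj] == pytest.approx(p)

    def test_permuting_conditions_permutes_matrix(self, rng):
        data = {c: rng.exponential(size=15) for c in ("A", "B", "C")}
        rho1, _ = correlation_matrix(_pop(data))
        rho2, _ = correlation_matrix(
            _pop({c: data[c] for c in ("C", "A", "B")})
        )
        for ci in data:
            for cj in data:
                assert rho1.loc[ci, cj] == pytest.approx(rho2.loc[ci, cj])


class TestCompareWithinAcross:
    def test_identical_groups_t_zero_p_half(self):
        t, p = compare_within_across([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(0.5)

    def test_separated_groups_vs_permutation_oracle(self, rng):
        within = np.array([0.9, 0.8, 0.85])
        across = np.array([-0.1, 0.0, -0.2])
        t, p = compare_within_across(within, across)
        assert p < 0.01
        # permutation oracle on group labels: the observed split is the most
        # extreme of all 20 label assignments (p at the enumeration floor)
        pooled = np.concatenate([within, across])
        obs = within.mean() - across.mean()
        count = 0
        combos = list(itertools.combinations(range(6), 3))
        for idx in combos:
            sel = np.zeros(6, bool)
            sel[list(idx)] = True
            if pooled[sel].mean() - pooled[~sel].mean() >= obs - 1e-12:
                count += 1
        assert count == 1
        assert count / len(combos) == pytest.approx(1 / 20)

    def test_three_identical_groups_anova_f_zero(self):
        g = [0.1, 0.2, 0.3]
        f, p = compare_within_across(
            None, None, mode="anova", groups=[g, g, g]
        )
        assert f == pytest.approx(0.0)

    def test_degenerate_anova_group(self):
        with pytest.raises(ValueError):
            compare_within_across([0.1], [0.2], mode="anova")


class TestSimulateSilentPopulation:
    def test_shared_baseline_only_r_is_one(self):
        r = simulate_silent_population(
            500, 1.0, (0, 0, 0), shared_baseline_sd=1.0,
            independent_noise_sd=0.0, seed=0,
        )
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_exclusive_actives_without_baseline_anticorrelated(self):
        rs = [
            simulate_silent_population(
                1000, 0.0, (0.5, 0.5, 0.0), shared_baseline_sd=0.0,
                independent_noise_sd=0.3, seed=s,
            )
            for s in range(20)
        ]
        assert np.median(rs) < 0

    def test_monotone_in_silent_fraction(self):
        """Median r never decreases as the silent fraction grows, holding
        the shared baseline fixed."""
        fracs = [0.0, 0.5, 0.9, 0.97]
        medians = []
        for sf in fracs:
            act = (1 - sf) / 2
            rs = [
                simulate_silent_population(
                    2000, sf, (act, act, 0.0), shared_baseline_sd=1.0,
                    independent_noise_sd=0.1, seed=s,
                )
                for s in range(30)
            ]
            medians.append(np.median(rs))
        assert all(b >= a - 1e-9 for a, b in zip(medians, medians[1:]))

    def test_fraction_mismatch_rejected(self):
        with pytest.raises(ValueError):
            simulate_silent_population(200, 0.5, (0.3, 0.3, 0.0), 1.0, 0.1, 0)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            simulate_silent_population(50, 0.9, (0.05, 0.05, 0.0), 1.0, 0.1, 0)


class TestCrossDayComparison:
    def test_identical_days_same_task(self, rng):
        act = pd.DataFrame(
            {"TM": rng.exponential(size=20), "SW": rng.exponential(size=20)}
        )
        p1 = PopulationActivity(activity=act)
        p2 = PopulationActivity(activity=act.copy())
        out = cross_day_comparison(p1, p2, "same_task")
        for rho, _ in out.values():
            assert rho == pytest.approx(1.0)

    def test_cross_task_pairing_on_exclusive_population(self, rng):
        """Perfectly task-specific activity: cross-task pairing across days
        is anti-correlated."""
        n = 30
        tm = np.concatenate([rng.uniform(1, 2, n // 2), np.zeros(n - n // 2)])
        sw = np.concatenate([np.zeros(n // 2), rng.uniform(1, 2, n - n // 2)])
        act = pd.DataFrame({"TM": tm, "SW": sw})
        p1 = PopulationActivity(activity=act)
        p2 = PopulationActivity(activity=act.copy())
        out = cross_day_comparison(p1, p2, "cross_task")
        for rho, _ in out.values():
            assert rho <= 0

    def test_union_fill_with_zero(self, rng):
        a1 = pd.DataFrame({"TM": [1.0, 2.0, 3.0, 1.5]}, index=[0, 1, 2, 3])
        a2 = pd.DataFrame({"TM": [1.0, 2.0, 3.0, 2.5]}, index=[1, 2, 3, 4])
        out = cross_day_comparison(
            PopulationActivity(activity=a1), PopulationActivity(activity=a2)
        )
        assert ("TM", "TM") in out  # union of 5 cells, missing entries zero

    def test_disjoint_ids_rejected(self):
        a1 = pd.DataFrame({"TM": [1.0, 2.0, 3.0]}, index=[0, 1, 2])
        a2 = pd.DataFrame({"TM": [1.0, 2.0, 3.0]}, index=[10, 11, 12])
        with pytest.raises(ValueError):
            cross_day_comparison(
                PopulationActivity(activity=a1), PopulationActivity(activity=a2)
            )


def test_population_activity_rejects_negative_and_missing():
    with pytest.raises(ValueError):
        PopulationActivity(activity=pd.DataFrame({"TM": [1.0, -0.1]}))
    with pytest.raises(ValueError):
        PopulationActivity(activity=pd.DataFrame({"TM": [1.0, np.nan]}))
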