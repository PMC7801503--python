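import numpy as np
import pandas as pd
import pytest
from itertools import combinations
from scipy import stats

from exemplarscore.clinical_compare import (
    bonferroni_threshold,
    compare_strata,
    comparison_report,
    permutation_test_two_sample,
    randomization_chi_square,
)
from exemplarscore.data_model import ClinicalDataset, DataDictionary, Variable
from exemplarscore.errors import ValidationError


def exhaustive_oracle(x, y):
    """Independent enumeration of all label assignments for |mean diff|."""
    pooled = np.concatenate([x, y])
    nx, n = len(x), len(pooled)
    observed = abs(np.mean(x) - np.mean(y))
    hits = total = 0
    for idx in combinations(range(n), nx):
        mask = np.zeros(n, bool)
        mask[list(idx)] = True
        stat = abs(pooled[mask].mean() - pooled[~mask].mean())
        hits += stat >= observed - 1e-12
        total += 1
    return hits / total


class TestPermutationTest:
    def test_exhaustive_textbook_case(self):
        stat, p = permutation_test_two_sample([1, 2, 3], [4, 5, 6], exhaustive=True)
        assert stat == 3.0
        assert p == pytest.approx(2 / 20)

    def test_exhaustive_matches_enumeration_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            nx = int(rng.integers(2, 6))
            ny = int(rng.integers(2, 11 - nx))
            x, y = rng.normal(size=nx), rng.normal(size=ny)
            _, p = permutation_test_two_sample(x, y, exhaustive=True)
            assert p == pytest.approx(exhaustive_oracle(x, y))

    def test_identical_groups_give_p_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        _, p = permutation_test_two_sample(x, x, B=999, seed=0)
        assert p > 0.9

    def test_extreme_separation_hits_floor(self):
        x, y = np.zeros(20), np.full(20, 10.0)
        _, p = permutation_test_two_sample(x, y, B=10_000, seed=0, exhaustive=False)
        assert p == pytest.approx(1 / 10_001)

    def test_monte_carlo_agrees_with_exhaustive(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=5), rng.normal(0.5, 1, size=5)
        _, p_exact = permutation_test_two_sample(x, y, exhaustive=True)
        _, p_mc = permutation_test_two_sample(x, y, B=4000, seed=1, exhaustive=False)
        assert abs(p_mc - p_exact) < 2 * np.sqrt(p_exact * (1 - p_exact) / 4000) + 1e-3

    def test_missing_values_dropped(self):
        _, p = permutation_test_two_sample(
            [1.0, np.nan, 2.0, 3.0], [4.0, 5.0, np.nan, 6.0], exhaustive=True
        )
        assert p == pytest.approx(2 / 20)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            permutation_test_two_sample([], [1.0, 2.0])


class TestRandomizationChiSquare:
    def test_homogeneous_table_gives_p_near_one(self):
        _, p = randomization_chi_square([[5, 5], [5, 5]], B=999, seed=0)
        assert p > 0.5

    def test_perfect_association_hits_floor(self):
        stat, p = randomization_chi_square([[20, 0], [0, 20]], B=10_000, seed=0)
        assert stat == pytest.approx(40.0)
        assert p == pytest.approx(1 / 10_001)
        # Fisher-exact oracle confirms the association is genuinely extreme
        assert stats.fisher_exact([[20, 0], [0, 20]])[1] < 1e-4

    def test_statistic_is_pearson_chi_square(self):
        table = [[10, 5, 3], [2, 8, 9]]
        stat, _ = randomization_chi_square(table, B=99, seed=0)
        expected = stats.chi2_contingency(table, correction=False)[0]
        assert stat == pytest.approx(expected)

    def test_p_has_estimator_lower_bound(self):
        _, p = randomization_chi_square([[3, 2, 1], [2, 2, 2]], B=200, seed=0)
        assert p >= 1 / 201

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError):
            randomization_chi_square([[5, 0], [5, 0]], B=99)


class TestBonferroni:
    def test_study_thresholds(self):
        assert bonferroni_threshold(0.05, 116) == pytest.approx(0.000431, abs=5e-7)
        assert round(bonferroni_threshold(0.05, 116), 4) == 0.0004
        assert round(bonferroni_threshold(0.05, 3), 3) == 0.017
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_zero_comparisons_rejected(self):
        with pytest.raises(ValidationError):
            bonferroni_threshold(0.05, 0)


def build_dataset(n_per_group=30, effect=0.0, seed=0):
    """Two strata with one optionally shifted continuous variable and one
    optionally tilted categorical variable."""
    rng = np.random.default_rng(seed)
    dictionary = DataDictionary([
        Variable("v_cont", "continuous", None),
        Variable("v_null", "continuous", None),
        Variable("v_cat", "categorical", ["A", "B"]),
    ])
    n = 4 * n_per_group
    strata = (["LRBest"] * n_per_group + ["NRBest"] * n_per_group
              + ["LRPoor"] * n_per_group + ["NRPoor"] * n_per_group)
    y = ([1] * n_per_group + [0] * n_per_group) * 2
    shift = np.where(np.asarray(strata) == "LRBest", effect, 0.0)
    p_b = np.where(np.asarray(strata) == "LRBest", 0.5 + min(0.45, effect / 10), 0.5)
    df = pd.DataFrame({
        "site": "s1",
        "alda_total": np.where(np.asarray(y) == 1, 8.0, 2.0),
        "response": y,
        "v_cont": rng.normal(size=n) + shift,
        "v_null": rng.normal(size=n),
        "v_cat": np.where(rng.random(n) < p_b, "B", "A"),
    }, index=pd.Index([f"p{i:03d}" for i in range(n)], name="subject_id"))
    data = ClinicalDataset(df, dictionary)
    table = pd.DataFrame({"y": y, "E": 0.5, "stratum": strata}, index=df.index)
    return data, table


class TestCompareStrata:
    def test_planted_effect_flagged_null_not(self):
        data, table = build_dataset(n_per_group=40, effect=3.0, seed=1)
        results = compare_strata(data, table, "best", B=999, seed=0)
        by_name = {r.variable: r for r in results}
        assert by_name["v_cont"].significant
        assert by_name["v_cont"].test == "permutation"
        assert by_name["v_cat"].test == "randomization_chi2"
        assert not by_name["v_null"].significant

    def test_identical_strata_rarely_significant(self):
        data, table = build_dataset(n_per_group=30, effect=0.0, seed=2)
        results = compare_strata(data, table, "poor", B=499, seed=3)
        assert sum(r.significant for r in results) == 0

    def test_threshold_uses_number_of_testable_variables(self):
        data, table = build_dataset(n_per_group=20, effect=0.0, seed=4)
        results = compare_strata(data, table, "best", B=199, alpha=0.05, seed=0)
        m = sum(1 for r in results if r.test != "untestable")
        assert m == 3
        report = comparison_report(results)
        assert set(report.columns) >= {"variable", "test", "p", "significant"}

    def test_all_missing_variable_reported_untestable(self):
        data, table = build_dataset(n_per_group=10, seed=5)
        data.subjects.loc[table["stratum"] == "LRBest", "v_cont"] = np.nan
        results = compare_strata(data, table, "best", B=99, seed=0)
        by_name = {r.variable: r for r in results}
        assert by_name["v_cont"].test == "untestable"
        assert not by_name["v_cont"].significant


class TestPValueValidity:
    def test_permutation_type_one_error_controlled(self):
        # empirical P(p <= t) <= t + 2 MC SE under the null
        rng = np.random.default_rng(10)
        B, sims = 199, 400
        pvals = []
        for s in range(sims):
            x, y = rng.normal(size=12), rng.normal(size=12)
            _, p = permutation_test_two_sample(x, y, B=B, seed=s, exhaustive=False)
            pvals.append(p)
        pvals = np.asarray(pvals)
        for t in (0.01, 0.05):
            se = np.sqrt(t * (1 - t) / sims)
            assert (pvals <= t).mean() <= t + 2 * se
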