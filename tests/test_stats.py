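"""Contingency tables, exact Fisher test, ANOVA, regression, tertiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from boneqol.cohort import Cohort, default_spec, gen_cohort
from boneqol.stats import (
    ContingencyTable,
    anova_oneway,
    build_contingency,
    contingency_from_counts,
    fisher_exact,
    fit_linear,
    split_tertiles,
    summarize,
)


class TestContingency:
    def test_mobility_collapse_matches_published_counts(self, table2_counts):
        t = contingency_from_counts(table2_counts, "MO")
        assert t.counts.tolist() == [[22, 10, 11], [27, 8, 7], [13, 6, 5]]

    def test_self_care_collapse_matches_published_counts(self, table2_counts):
        t = contingency_from_counts(table2_counts, "SC")
        assert t.counts.tolist() == [[36, 3, 4], [37, 4, 1], [19, 1, 4]]

    def test_grand_total_equals_cohort_size_for_every_dimension(self):
        cohort = gen_cohort(default_spec(seed=2))
        for dim in ("MO", "SC", "UA", "PD", "AD"):
            assert build_contingency(cohort, dim).total == len(cohort)

    def test_single_patient_cohort(self):
        df = pd.DataFrame([{
            "id": "OI-001", "disease": "OI", "age": 30, "sex": "F",
            "mo": 3, "sc": 1, "ua": 1, "pd": 1, "ad": 1, "vas": 50,
            "utility": 0.9,
        }])
        t = build_contingency(Cohort(df), "MO")
        assert t.counts.sum() == 1
        assert t.counts[0, 1] == 1  # level 3 -> moderate

    def test_unknown_dimension_is_hard_error(self):
        cohort = gen_cohort(default_spec(seed=2))
        with pytest.raises(KeyError, match="unknown dimension"):
            build_contingency(cohort, "XX")


class TestFisherExact:
    def test_two_by_two_antidiagonal_is_one(self):
        # both tables with these margins have probability 0.5
        assert fisher_exact(np.array([[1, 0], [0, 1]])) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_classical_hypergeometric_on_2x2(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(1, 25, size=(2, 2))
        ours = fisher_exact(table)
        theirs = sps.fisher_exact(table)[1]
        assert ours == pytest.approx(theirs, rel=1e-9)

    def test_agrees_with_monte_carlo_oracle_on_3x3(self, table2_counts):
        """Exhaustive enumeration vs a seeded million-draw fixed-margin
        resampler on the mobility table."""
        t = contingency_from_counts(table2_counts, "MO")
        exact = fisher_exact(t)
        mc = fisher_exact(t, method="monte_carlo", n_draws=1_000_000, seed=99)
        assert mc == pytest.approx(exact, abs=1e-3)

    def test_row_and_column_permutation_symmetry(self, table2_counts):
        t = contingency_from_counts(table2_counts, "SC").counts
        p = fisher_exact(t)
        assert fisher_exact(t[::-1, :]) == pytest.approx(p, rel=1e-9)
        assert fisher_exact(t[:, ::-1]) == pytest.approx(p, rel=1e-9)
        assert fisher_exact(t.T) == pytest.approx(p, rel=1e-9)

    def test_budget_exceeded_advises_monte_carlo(self):
        big = np.full((3, 3), 40)
        with pytest.raises(RuntimeError, match="monte_carlo"):
            fisher_exact(big, max_tables=100)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margins"):
            fisher_exact(np.array([[0, 0], [1, 2]]))


class TestAnova:
    def test_hand_computed_example(self):
        # SSB = 16 (df 1), SSW = 4 (df 2) -> F = 8
        f, p = anova_oneway([0, 2], [4, 6])
        assert f == pytest.approx(8.0)
        assert 0 < p < 1

    def test_equal_group_means_give_zero_f(self):
        f, _ = anova_oneway([1.0, 3.0], [0.0, 4.0])
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_all_zero_within_variance_is_hard_error(self):
        with pytest.raises(ValueError, match="undefined"):
            anova_oneway([1, 1], [2, 2])

    def test_null_pvalues_are_uniform(self):
        """Three groups from one distribution: p-values over replicates
        should pass a Kolmogorov-Smirnov uniformity check."""
        rng = np.random.default_rng(8)
        pvals = [
            anova_oneway(*(rng.normal(size=30) for _ in range(3)))[1]
            for _ in range(300)
        ]
        assert sps.kstest(pvals, "uniform").pvalue > 1e-3


class TestLinearFit:
    def test_perfect_line_recovered_exactly(self):
        x = np.arange(20.0, 60.0)
        y = -0.005 * x + 0.9
        slope, intercept, r, _ = fit_linear(x, y)
        assert slope == pytest.approx(-0.005)
        assert intercept == pytest.approx(0.9)
        assert r == pytest.approx(-1.0)

    def test_independent_data_has_negligible_correlation(self):
        rng = np.random.default_rng(1)
        _, _, r, _ = fit_linear(rng.normal(size=10_000), rng.normal(size=10_000))
        assert abs(r) < 0.05

    def test_constant_x_is_hard_error(self):
        with pytest.raises(ValueError, match="constant"):
            fit_linear([1, 1, 1], [1, 2, 3])


class TestSummaries:
    def test_hand_arithmetic(self):
        df = pd.DataFrame({
            "id": ["a", "b"], "disease": ["OI", "OI"], "age": [30, 40],
            "sex": ["F", "F"], "mo": [1, 1], "sc": [1, 1], "ua": [1, 1],
            "pd": [1, 1], "ad": [1, 1], "vas": [50, 60], "utility": [0.0, 1.0],
        })
        (s,) = summarize(Cohort(df), "utility")
        assert s.mean == pytest.approx(0.5)
        assert s.sd == pytest.approx(np.sqrt(0.5), abs=1e-6)

    def test_single_member_group_flags_undefined_variance(self):
        df = pd.DataFrame([{
            "id": "x", "disease": "XLH", "age": 30, "sex": "M",
            "mo": 1, "sc": 1, "ua": 1, "pd": 1, "ad": 1, "vas": 40,
            "utility": 0.7,
        }])
        (s,) = summarize(Cohort(df), "utility")
        assert s.mean == 0.7 and s.sd == 0.0 and not s.sd_defined

    def test_generator_calibration_recovered(self):
        """Group summaries on a large default-mixture sample reproduce
        the generator's configured overall mean."""
        spec = default_spec(seed=3, n_by_disease={"OI": 20_000})
        (s,) = summarize(gen_cohort(spec), "utility")
        assert s.mean == pytest.approx(0.65, abs=0.01)

    def test_unknown_variable_rejected(self):
        cohort = gen_cohort(default_spec(seed=1))
        with pytest.raises(KeyError):
            summarize(cohort, "height")


class TestTertiles:
    def test_43_patients_split_15_14_14(self):
        df = pd.DataFrame({
            "id": [f"p{i:02d}" for i in range(43)],
            "utility": np.linspace(0, 1, 43),
        })
        split = split_tertiles(df)
        assert (len(split.lower), len(split.middle), len(split.upper)) == (15, 14, 14)

    def test_six_distinct_utilities_make_ordered_blocks(self):
        df = pd.DataFrame({"id": list("abcdef"),
                           "utility": [0.9, 0.1, 0.5, 0.3, 0.7, 0.2]})
        split = split_tertiles(df)
        assert split.lower.utility.tolist() == [0.1, 0.2]
        assert split.middle.utility.tolist() == [0.3, 0.5]
        assert split.upper.utility.tolist() == [0.7, 0.9]

    def test_ties_broken_by_id_order(self):
        df = pd.DataFrame({"id": [f"p{i:02d}" for i in range(43)],
                           "utility": np.zeros(43)})
        split = split_tertiles(df)
        assert split.lower.id.tolist() == [f"p{i:02d}" for i in range(15)]

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=3, max_size=60))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_split_is_an_ordered_partition(self, utilities):
        df = pd.DataFrame({"id": [f"p{i:03d}" for i in range(len(utilities))],
                           "utility": utilities})
        split = split_tertiles(df)
        parts = [split.lower, split.middle, split.upper]
        assert sum(map(len, parts)) == len(df)
        assert max(map(len, parts)) - min(map(len, parts)) <= 1
        assert sorted(pd.concat(parts).id) == sorted(df.id)
        if len(split.lower) and len(split.middle):
            assert split.lower.utility.max() <= split.middle.utility.min() + 1e-12
        if len(split.middle) and len(split.upper):
            assert split.middle.utility.max() <= split.upper.utility.min() + 1e-12

    def test_fewer_than_three_rejected(self):
        df = pd.DataFrame({"id": ["a", "b"], "utility": [0.1, 0.2]})
        with pytest.raises(ValueError, match="at least 3"):
            split_tertiles(df)
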