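import inspect
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import piloscore as ps
from piloscore import stats as pstats

from conftest import make_record
from oracles import chi2_2x2_closed_form, fisher_p_enumeration, mann_whitney_pair_count


def table(rows, row_labels=None, col_labels=None):
    rows = np.asarray(rows)
    return ps.ContingencyTable(
        rows,
        row_labels or [f"r{i}" for i in range(rows.shape[0])],
        col_labels or [f"c{j}" for j in range(rows.shape[1])],
    )


class TestDescribeContinuous:
    def test_symmetric_sequence(self):
        s = ps.describe_continuous([1, 2, 3, 4, 5])
        assert s.mean == 3 and s.median == 3
        assert s.sd == pytest.approx(math.sqrt(2.5))
        assert (s.min, s.max) == (1, 5)
        assert (s.iqr_low, s.iqr_high) == (2, 4)

    def test_constant(self):
        s = ps.describe_continuous([7.0] * 100)
        assert s.mean == 7 and s.sd == 0

    def test_single_value(self):
        s = ps.describe_continuous([4.2])
        assert s.n == 1 and s.sd == 0.0 and s.median == 4.2

    def test_empty_errors(self):
        with pytest.raises(ps.DegenerateDataError):
            ps.describe_continuous([])

    def test_fixture_bmi_recovers_cohort_moments(self, fixture_cohort):
        s = ps.describe_continuous([r.bmi for r in fixture_cohort.records])
        assert s.mean == pytest.approx(29.12, abs=0.5)
        assert s.sd == pytest.approx(4.63, abs=0.5)


class TestPearsonChiSquare:
    # published two-group tables: (rows x outcome) -> printed statistic
    PRINTED = [
        ([[90, 18], [47, 1]], 6.607),
        ([[11, 10], [126, 9]], 28.495),
        ([[15, 11], [122, 8]], 26.477),
        ([[0, 3], [137, 16]], 22.056),
        ([[79, 4], [47, 3], [11, 12]], 40.384),
        ([[27, 15], [110, 4]], 29.762),
        ([[48, 16], [89, 3]], 16.676),
        ([[23, 15], [114, 4]], 34.990),
        ([[35, 14], [102, 5]], 17.946),
    ]

    @pytest.mark.parametrize("rows,expected", PRINTED)
    def test_reproduces_published_statistics(self, rows, expected):
        result = ps.pearson_chi_square(table(rows))
        assert result.statistic == pytest.approx(expected, abs=5e-4)

    def test_balanced_table_is_zero(self):
        result = ps.pearson_chi_square(table([[10, 10], [10, 10]]))
        assert result.statistic == 0 and result.p_value == 1 and result.dof == 1

    def test_dof_3x2(self):
        assert ps.pearson_chi_square(table([[79, 4], [47, 3], [11, 12]])).dof == 2

    def test_zero_margin_errors(self):
        with pytest.raises(ps.DegenerateDataError, match="r1"):
            ps.pearson_chi_square(table([[5, 5], [0, 0]]))

    def test_matches_scipy_uncorrected(self):
        rows = [[12, 7], [30, 44], [8, 19]]
        mine = ps.pearson_chi_square(table(rows))
        ref = sps.chi2_contingency(np.asarray(rows), correction=False)
        assert mine.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    @given(st.lists(st.integers(1, 80), min_size=4, max_size=4))
    @settings(max_examples=100, deadline=None)
    def test_2x2_closed_form_identity(self, cells):
        a, b, c, d = cells
        result = ps.pearson_chi_square(table([[a, b], [c, d]]))
        assert result.statistic == pytest.approx(
            chi2_2x2_closed_form(a, b, c, d), abs=1e-9)


class TestFisherExact:
    def test_balanced_p_one(self):
        assert ps.fisher_exact_2x2(table([[5, 5], [5, 5]])).p_value == pytest.approx(1.0)

    def test_published_infection_table(self):
        result = ps.fisher_exact_2x2(table([[0, 3], [137, 16]]))
        assert result.p_value < 0.05
        assert result.p_value == pytest.approx(fisher_p_enumeration(0, 3, 137, 16),
                                               rel=1e-9)

    def test_example_matches_enumeration(self):
        result = ps.fisher_exact_2x2(table([[2, 7], [8, 2]]))
        assert result.p_value == pytest.approx(fisher_p_enumeration(2, 7, 8, 2),
                                               rel=1e-9)

    def test_statistic_is_observed_table_probability(self):
        result = ps.fisher_exact_2x2(table([[2, 7], [8, 2]]))
        expected = sps.hypergeom.pmf(2, 19, 9, 10)
        assert result.statistic == pytest.approx(expected, rel=1e-12)

    def test_non_2x2_directs_to_monte_carlo(self):
        with pytest.raises(ps.DegenerateDataError, match="monte_carlo"):
            ps.fisher_exact_2x2(table([[1, 2], [3, 4], [5, 6]]))

    @given(st.lists(st.integers(0, 15), min_size=4, max_size=4))
    @settings(max_examples=150, deadline=None)
    def test_matches_enumeration_for_small_tables(self, cells):
        a, b, c, d = cells
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            return
        assert a + b + c + d <= 60
        result = ps.fisher_exact_2x2(table([[a, b], [c, d]]))
        assert result.p_value == pytest.approx(fisher_p_enumeration(a, b, c, d),
                                               rel=1e-9)


class TestMonteCarlo:
    def test_zero_statistic_gives_p_one(self):
        result = ps.monte_carlo_p(table([[10, 10], [10, 10]]), reps=1000, seed=1)
        assert result.p_value == pytest.approx(1.0, abs=1 / 1001 + 1e-12)

    def test_published_pits_table_is_extreme(self):
        result = ps.monte_carlo_p(table([[79, 4], [47, 3], [11, 12]]),
                                  reps=10000, seed=3)
        assert result.p_value < 0.001

    def test_reproducible_under_seed(self):
        t = table([[8, 3], [5, 9], [2, 7]])
        a = ps.monte_carlo_p(t, reps=2000, seed=42)
        b = ps.monte_carlo_p(t, reps=2000, seed=42)
        assert a.p_value == b.p_value

    def test_agrees_with_asymptotic_on_well_populated_table(self):
        # note the Monte-Carlo p targets the exact conditional (fixed-margin)
        # tail, which only converges to the asymptotic tail as counts grow;
        # this table is populated enough for the two to coincide
        t = table([[63, 79], [78, 58]])
        assert (t.expected() >= 10).all()
        p_asym = ps.pearson_chi_square(t).p_value
        reps = 4000
        se = math.sqrt(p_asym * (1 - p_asym) / reps)
        for seed in range(20):
            p_mc = ps.monte_carlo_p(t, reps=reps, seed=seed).p_value
            assert abs(p_mc - p_asym) <= 3 * se + 1 / (reps + 1)

    def test_too_few_reps_errors(self):
        with pytest.raises(ps.DegenerateDataError):
            ps.monte_carlo_p(table([[5, 5], [5, 5]]), reps=10, seed=0)


class TestChooseCategoricalTest:
    def test_sex_table_keeps_chi_square(self):
        t = table([[90, 18], [47, 1]])
        assert (t.expected() >= 5).all()  # smallest E = 48*19/156 = 5.85
        assert ps.choose_categorical_test(t) == "chi_square"

    def test_infection_table_switches_to_fisher(self):
        t = table([[0, 3], [137, 16]])
        assert (t.expected() < 5).mean() == 0.5
        assert ps.choose_categorical_test(t) == "fisher_exact"

    def test_large_3x2_keeps_chi_square(self):
        assert ps.choose_categorical_test(table([[30, 30], [30, 30], [30, 30]])) \
            == "chi_square"

    def test_sparse_3x2_switches_to_monte_carlo(self):
        t = table([[1, 2], [2, 1], [3, 1]])
        assert ps.choose_categorical_test(t) == "monte_carlo_chi_square"

    def test_exactly_20_percent_stays_chi_square(self):
        # 1 of 6 cells below 5 (16.7% <= 20%): published pit-bin table
        t = table([[79, 4], [47, 3], [11, 12]])
        assert (t.expected() < 5).sum() == 1
        assert ps.choose_categorical_test(t) == "chi_square"


class TestStudentT:
    def test_published_bmi_summary(self):
        result = ps.student_t_from_summary(28.61, 4.43, 137, 32.79, 4.52, 19)
        # closed-form pooled-variance computation as oracle
        sp2 = (136 * 4.43 ** 2 + 18 * 4.52 ** 2) / 154
        expected = (28.61 - 32.79) / math.sqrt(sp2 * (1 / 137 + 1 / 19))
        assert result.statistic == pytest.approx(expected, rel=1e-12)
        assert abs(result.statistic) == pytest.approx(3.844, abs=2e-3)
        assert result.dof == 154

    def test_published_age_summary(self):
        result = ps.student_t_from_summary(27.29, 6.44, 137, 27.47, 6.88, 19)
        assert abs(result.statistic) == pytest.approx(0.114, abs=2e-3)

    def test_equal_means_zero_t(self):
        result = ps.student_t_from_summary(5.0, 1.0, 10, 5.0, 2.0, 10)
        assert result.statistic == 0 and result.p_value == pytest.approx(1.0)

    def test_zero_sds_equal_means(self):
        result = ps.student_t_from_summary(5.0, 0.0, 10, 5.0, 0.0, 10)
        assert result.statistic == 0 and result.p_value == 1

    def test_zero_sds_unequal_means_errors(self):
        with pytest.raises(ps.DegenerateDataError):
            ps.student_t_from_summary(5.0, 0.0, 10, 6.0, 0.0, 10)

    def test_identical_samples(self):
        result = ps.student_t([1, 2, 3], [1, 2, 3])
        assert result.statistic == 0 and result.p_value == pytest.approx(1.0)

    def test_manual_pooled_variance_example(self):
        result = ps.student_t([0, 0, 1, 1], [10, 10, 11, 11])
        # var = 1/3 each, pooled var = 1/3, se = sqrt(1/3 * 1/2) = 1/sqrt(6)
        assert abs(result.statistic) == pytest.approx(10 * math.sqrt(6), rel=1e-12)

    def test_type_one_error_rate(self):
        rng = np.random.default_rng(11)
        hits = 0
        n_sims = 1000
        for _ in range(n_sims):
            x = rng.normal(size=50)
            y = rng.normal(size=50)
            if ps.student_t(x, y).significant:
                hits += 1
        assert 0.03 <= hits / n_sims <= 0.07

    def test_too_small_groups_error(self):
        with pytest.raises(ps.DegenerateDataError):
            ps.student_t([1.0], [2.0, 3.0])


class TestMannWhitney:
    def test_identical_groups_u_is_half_product(self):
        result = ps.mann_whitney_u(range(1, 11), range(1, 11))
        assert result.statistic == 50  # n1*n2/2

    def test_complete_separation_u_zero(self):
        result = ps.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert result.statistic == 0

    def test_constant_data(self):
        result = ps.mann_whitney_u([3, 3, 3], [3, 3])
        assert result.statistic == 3 and result.p_value == 1.0

    def test_empty_group_errors(self):
        with pytest.raises(ps.DegenerateDataError):
            ps.mann_whitney_u([], [1, 2])

    def test_exact_branch_matches_scipy_exact(self):
        x, y = [1.5, 2.5, 9.0], [3.0, 4.0, 5.0, 8.0]
        mine = ps.mann_whitney_u(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert mine.p_value == pytest.approx(ref.pvalue)

    @given(
        x=st.lists(st.integers(0, 8), min_size=1, max_size=50),
        y=st.lists(st.integers(0, 8), min_size=1, max_size=50),
    )
    @settings(max_examples=150, deadline=None)
    def test_u_matches_pair_counting_oracle(self, x, y):
        result = ps.mann_whitney_u(x, y)
        assert result.statistic == pytest.approx(mann_whitney_pair_count(x, y))


class TestNormalityGate:
    def test_normal_draws_pass(self):
        rng = np.random.default_rng(0)
        passes = sum(ps.normality_gate(rng.normal(size=500)) == "normal"
                     for _ in range(100))
        assert passes >= 90

    def test_exponential_draws_fail(self):
        rng = np.random.default_rng(1)
        fails = sum(ps.normality_gate(rng.exponential(size=500)) == "non_normal"
                    for _ in range(100))
        assert fails >= 90

    def test_constant_vector_is_non_normal(self):
        assert ps.normality_gate([2.0] * 50) == "non_normal"

    @pytest.mark.parametrize("n", [2, 5001])
    def test_unsupported_n_errors(self, n):
        with pytest.raises(ps.DegenerateDataError):
            ps.normality_gate(np.arange(n, dtype=float))


class TestCompareGroups:
    PRINTED_CHI2 = {
        "sex": 6.607,
        "diabetes": 28.495,
        "prior_recurrence": 26.477,
        "postop_infection": 22.056,
        "midline_pits": 40.384,
        "lateral_pits": 29.762,
        "hairy_back": 16.676,
        "distance_lt_5cm": 34.990,
        "prior_abscess": 17.946,
    }

    def test_fixture_reproduces_all_published_chi_squares(self, fixture_cohort):
        report = ps.compare_groups(fixture_cohort.records, seed=5)
        got = {row.variable: row.chi_square_statistic for row in report.rows
               if row.kind == "categorical"}
        for name, expected in self.PRINTED_CHI2.items():
            assert got[name] == pytest.approx(expected, abs=5e-4), name

    def test_fisher_selected_where_expected_counts_small(self, fixture_cohort):
        report = ps.compare_groups(fixture_cohort.records, seed=5)
        selected = {row.variable: row.result.test_name for row in report.rows
                    if row.result is not None}
        assert selected["diabetes"] == "fisher_exact"
        assert selected["prior_recurrence"] == "fisher_exact"
        assert selected["postop_infection"] == "fisher_exact"
        assert selected["distance_lt_5cm"] == "fisher_exact"
        assert selected["sex"] == "chi_square"
        assert selected["midline_pits"] == "chi_square"

    def test_group_sizes(self, fixture_cohort):
        report = ps.compare_groups(fixture_cohort.records, seed=5)
        assert report.group_sizes == (137, 19)

    def test_constant_variable_flagged_degenerate(self):
        records = [make_record(recurrence=(i % 2 == 0)) for i in range(10)]
        plan = [ps.ContinuousVariable("bmi", lambda r: r.bmi),
                ps.CategoricalVariable("diabetes", [
                    ("yes", lambda r: r.diabetes), ("no", lambda r: not r.diabetes)])]
        report = ps.compare_groups(records, plan=plan)
        for row in report.rows:
            assert row.result.statistic == 0 and row.result.p_value == 1.0
            assert any("degenerate" in w for w in row.warnings)

    def test_empty_outcome_group_errors(self):
        records = [make_record(recurrence=False) for _ in range(5)]
        with pytest.raises(ps.DegenerateDataError):
            ps.compare_groups(records)

    def test_missing_values_excluded_and_counted(self):
        records = [make_record(recurrence=(i % 2 == 0),
                               operative_time_min=None if i < 3 else 40.0 + i)
                   for i in range(12)]
        plan = [ps.ContinuousVariable("operative_time_min",
                                      lambda r: r.operative_time_min)]
        report = ps.compare_groups(records, plan=plan)
        assert report.rows[0].n_excluded == 3

    def test_null_cohort_type_one_error(self):
        # continuous-only plan: t / Mann-Whitney keep nominal level; exact
        # categorical tests at small n are conservative by construction.
        rng = np.random.default_rng(2024)
        plan = [ps.ContinuousVariable(f"v{i}", lambda r, i=i: r._null_vars[i])
                for i in range(5)]
        flagged = total = 0
        for _ in range(200):
            records = []
            for j in range(100):
                r = make_record(recurrence=(j < 50))
                r._null_vars = rng.normal(size=5)
                records.append(r)
            report = ps.compare_groups(records, plan=plan)
            flagged += sum(row.result.significant for row in report.rows)
            total += len(report.rows)
        assert 0.03 <= flagged / total <= 0.07

    def test_report_renders_tsv_and_json(self, fixture_cohort):
        report = ps.compare_groups(fixture_cohort.records, seed=5)
        tsv = report.to_tsv()
        assert tsv.startswith("variable\t")
        assert "midline_pits" in tsv
        d = report.as_dict()
        assert len(d["rows"]) == len(report.rows)
        assert any("multiple-testing" in note for note in d["notes"])

    def test_statistics_layer_independent_of_weight_table(self):
        source = inspect.getsource(pstats)
        assert "WeightTable" not in source
        assert "default_weight_table" not in source
        assert "from .score" not in source
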