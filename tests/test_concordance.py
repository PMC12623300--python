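"""Concordance analysis: filtering, cross-tabulation, predictive values."""

import numpy as np
import pytest

from panometry.adjudicate import CCv4Label, adjudicate_diagnosis
from panometry.classify import (
    MotilityV1,
    MotilityV2,
    V1_TABLE,
    V2_TABLE,
    classify_motility,
    merge_cr_v2_to_v1,
)
from panometry.cohort import calibrate_joint_from_counts, sample_cohort
from panometry.concordance import (
    CohortRecord,
    adjudicate_patients,
    build_crosstab,
    chi_square_test,
    expand_counts_to_records,
    group_comparison_tests,
    predictive_values,
    primary_filter,
    proportion_within,
    round_half_away,
    version_reclassification,
)


@pytest.fixture(scope="module")
def fixture_records(table2):
    return expand_counts_to_records(table2)


@pytest.fixture(scope="module")
def conclusive(fixture_records):
    return primary_filter(fixture_records)[0]


@pytest.mark.parametrize(
    "value,expected",
    [(92.7, 93), (98.5, 99), (90.8, 91), (71.79, 72), (0.4, 0), (0.5, 1),
     (-2.5, -3)],
)
def test_rounding_is_half_away_from_zero(value, expected):
    assert round_half_away(value) == expected


class TestPrimaryFilter:
    def test_fixture_partition(self, fixture_records):
        conclusive, excluded = primary_filter(fixture_records)
        assert (len(conclusive), len(excluded)) == (704, 101)

    def test_all_conclusive_cohort_has_empty_exclusion(self, table2):
        conclusive_only = table2.drop(
            index=["inconclusive_egjoo", "inconclusive_other", "egjoo"]
        )
        records = expand_counts_to_records(conclusive_only)
        kept, excluded = primary_filter(records)
        assert excluded == [] and len(kept) == len(records)

    def test_empty_cohort(self):
        assert primary_filter([]) == ([], [])


class TestCrosstab:
    def test_fixture_cell_counts(self, conclusive):
        ct = build_crosstab(conclusive, "hrm", "flip_v2")
        assert ct.cell("achalasia_ii", "non_spastic_obstruction") == 76
        assert ct.cell("normal", "normal") == 111
        assert ct.total == 704

    def test_margins_match_brute_force_recount(self, conclusive):
        ct = build_crosstab(conclusive, "hrm", "flip_v2")
        for hrm_cat, total in ct.row_totals().items():
            assert total == sum(
                1 for r in conclusive if r.hrm_category == hrm_cat
            )
        for flip_code, total in ct.column_totals().items():
            assert total == sum(
                1 for r in conclusive if r.flip_v2.value == flip_code
            )

    def test_single_record_cohort(self, conclusive):
        ct = build_crosstab(conclusive[:1], "hrm", "flip_v2")
        assert ct.total == 1

    def test_unknown_variable_rejected(self, conclusive):
        with pytest.raises(KeyError):
            build_crosstab(conclusive, "hrm", "shoe_size")


class TestProportions:
    def test_normal_hrm_within_normal_flip(self, conclusive):
        ct = build_crosstab(conclusive, "hrm", "flip_v2")
        p = proportion_within(ct, ["normal"], "normal")
        assert (p.numerator, p.denominator, p.percent) == (111, 137, 81)

    def test_absent_or_iem_within_hypocontractility(self, conclusive):
        ct = build_crosstab(conclusive, "hrm", "flip_v2")
        p = proportion_within(ct, ["absent_contractility", "iem"],
                              "hypocontractility")
        assert (p.numerator, p.denominator, p.percent) == (56, 78, 72)

    def test_column_against_all_rows_is_100_percent(self, conclusive):
        ct = build_crosstab(conclusive, "hrm", "flip_v2")
        p = proportion_within(ct, list(ct.counts.index), "normal")
        assert p.percent == 100

    def test_zero_denominator_is_undefined_not_a_crash(self, conclusive):
        ct = build_crosstab(conclusive, "hrm", "flip_v2")
        empty = ct.counts.columns[0]
        ct.counts[empty] = 0
        p = proportion_within(ct, ["normal"], empty)
        assert not p.defined and p.percent is None and p.fraction is None


class TestPredictiveValues:
    def test_fixture_npv_and_ppv(self, conclusive):
        pv = predictive_values(
            conclusive,
            positive_classes={MotilityV2.NON_SPASTIC_OBSTRUCTION},
            negative_classes={MotilityV2.NORMAL},
        )
        assert (pv.npv.numerator, pv.npv.denominator) == (135, 137)
        assert pv.npv.percent == 99
        assert (pv.ppv.numerator, pv.ppv.denominator) == (148, 163)
        assert pv.ppv.percent == 91

    def test_condition_never_occurs_gives_npv_one(self):
        records = [
            CohortRecord(
                patient_id=str(i), flip_v2=MotilityV2.NORMAL,
                adjudicated=adjudicate_diagnosis(CCv4Label.NORMAL),
                hrm_category="normal",
            )
            for i in range(5)
        ]
        pv = predictive_values(records, negative_classes={MotilityV2.NORMAL})
        assert pv.npv.fraction == 1.0

    def test_inconclusive_cohort_rejected(self, fixture_records):
        with pytest.raises(ValueError):
            predictive_values(fixture_records,
                              negative_classes={MotilityV2.NORMAL})


def _v1_reachable_v2_classes():
    """From the shipped tables: v2 classes reachable from each v1 class."""
    reachable = {}
    for (cr1, egjo), (mot1, _) in V1_TABLE.cells.items():
        for (cr2, egjo2), (mot2, _) in V2_TABLE.cells.items():
            if egjo2 is egjo and merge_cr_v2_to_v1(cr2) is cr1:
                reachable.setdefault(mot1, set()).add(mot2)
    return reachable


@pytest.fixture(scope="module")
def records(table2):
    spec = calibrate_joint_from_counts(table2)
    patients = sample_cohort(spec, 1500, seed=3)

    def v1_of(p):
        return classify_motility(merge_cr_v2_to_v1(p.cr), p.egjo, V1_TABLE)

    return adjudicate_patients(patients, flip_v1_of=v1_of)


class TestVersionReclassification:
    def test_flow_table_conserves_cohort_size(self, records):
        flow, breakdown = version_reclassification(records)
        assert flow.total == len(records)
        assert sum(sum(cell.values()) for cell in breakdown.values()) \
            == len(records)

    def test_splits_follow_scheme_reachability(self, records):
        flow, _ = version_reclassification(records)
        reachable = _v1_reachable_v2_classes()
        for v1_code in flow.counts.index:
            for v2_code in flow.counts.columns:
                if flow.cell(v1_code, v2_code) > 0:
                    assert MotilityV2(v2_code) in \
                        reachable[MotilityV1(v1_code)]

    def test_single_patient_flow(self, records):
        flow, _ = version_reclassification(records[:1])
        assert flow.total == 1

    def test_missing_v1_labels_rejected(self, fixture_records):
        with pytest.raises(ValueError):
            version_reclassification(fixture_records[:5])


class TestGroupComparisons:
    def test_chi_square_closed_form(self):
        res = chi_square_test(np.array([[10, 20], [20, 10]]))
        assert res.statistic == pytest.approx(6.667, abs=0.001)

    def test_identical_groups_t_test_p_near_one(self):
        g = np.arange(20, dtype=float)
        res = group_comparison_tests([g, g.copy()])
        assert res.test == "t_test"
        assert res.pvalue == pytest.approx(1.0)

    def test_degenerate_groups_are_undefined(self):
        assert not group_comparison_tests([np.array([1.0])]).defined

    def test_nonparametric_variants(self):
        rng = np.random.default_rng(0)
        groups = [rng.normal(size=30), rng.normal(1.0, size=30)]
        assert group_comparison_tests(groups, parametric=False).test \
            == "mann_whitney_u"
        groups3 = groups + [rng.normal(size=30)]
        assert group_comparison_tests(groups3, parametric=False).test \
            == "kruskal_wallis"

    def test_chi_square_p_matches_permutation_null(self):
        """Asymptotic p agrees with a label-permutation Monte-Carlo null."""
        table = np.array([[80, 60, 60], [60, 80, 60], [60, 60, 80]])
        res = chi_square_test(table)
        x = np.repeat(np.arange(3), table.sum(axis=1))
        y = np.concatenate([np.repeat(np.arange(3), row) for row in table])
        row_tot = table.sum(axis=1)
        n = table.sum()
        rng = np.random.default_rng(1)
        exceed = 0
        n_perm = 20_000
        for _ in range(n_perm):
            yp = rng.permutation(y)
            obs = np.bincount(x * 3 + yp, minlength=9).reshape(3, 3)
            exp = np.outer(row_tot, np.bincount(yp, minlength=3)) / n
            if ((obs - exp) ** 2 / exp).sum() >= res.statistic - 1e-9:
                exceed += 1
        assert abs(exceed / n_perm - res.pvalue) < 0.01
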