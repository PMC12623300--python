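"""Rule layers: CR patterns, EGJ opening, decision tables, scheme coherence."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panometry.classify import (
    CRPatternV1,
    CRPatternV2,
    DecisionTable,
    EGJOpening,
    MotilityV2,
    V1_TABLE,
    V2_TABLE,
    classify_cr_v1,
    classify_cr_v2,
    classify_egj_opening,
    classify_motility,
    merge_cr_v2_to_v1,
    validate_decision_table,
)
from panometry.features import FlipMetrics


def metrics(
    n_qual=0, any_c=False, occluding=False, les=False, pressure=30.0,
    di=3.0, dmax=17.0,
):
    return FlipMetrics(
        egj_di_60=di, max_egj_diameter=dmax, pressure_60=pressure,
        n_qualifying_antegrade=n_qual, any_contractility=any_c,
        sustained_occluding=occluding, sustained_les=les,
    )


class TestCrV2:
    @pytest.mark.parametrize(
        "m,expected",
        [
            (metrics(), CRPatternV2.ABSENT),
            (metrics(occluding=True, any_c=True, pressure=55.0),
             CRPatternV2.SPASTIC),
            (metrics(les=True, any_c=True), CRPatternV2.SPASTIC),
            (metrics(n_qual=1, any_c=True, pressure=30.0),
             CRPatternV2.DIMINISHED),
            (metrics(n_qual=1, any_c=True, pressure=40.0),
             CRPatternV2.DIMINISHED),   # boundary: <= 40 mmHg
            (metrics(n_qual=1, any_c=True, pressure=40.1),
             CRPatternV2.DISORDERED),
            (metrics(n_qual=2, any_c=True), CRPatternV2.NORMAL),
        ],
    )
    def test_pattern(self, m, expected):
        assert classify_cr_v2(m) is expected

    def test_exactly_two_contractions_is_normal_one_is_not(self):
        assert classify_cr_v2(metrics(n_qual=2, any_c=True)) \
            is CRPatternV2.NORMAL
        assert classify_cr_v2(metrics(n_qual=1, any_c=True)) \
            is not CRPatternV2.NORMAL

    def test_spastic_precedence_over_normal_count(self):
        m = metrics(n_qual=3, any_c=True, occluding=True)
        assert classify_cr_v2(m) is CRPatternV2.SPASTIC


class TestCrV1:
    @pytest.mark.parametrize("pressure", [30.0, 80.0])
    def test_pressure_is_irrelevant_in_v1(self, pressure):
        m = metrics(n_qual=1, any_c=True, pressure=pressure)
        assert classify_cr_v1(m) is CRPatternV1.IMPAIRED_DISORDERED

    def test_absent(self):
        assert classify_cr_v1(metrics()) is CRPatternV1.ABSENT

    @settings(max_examples=300, derandomize=True, deadline=None)
    @given(
        n_qual=st.integers(0, 4),
        any_c=st.booleans(),
        occluding=st.booleans(),
        les=st.booleans(),
        pressure=st.floats(5.0, 90.0, allow_nan=False),
    )
    def test_merging_v2_reproduces_v1_on_random_metrics(
        self, n_qual, any_c, occluding, les, pressure
    ):
        m = metrics(n_qual=n_qual, any_c=any_c or n_qual > 0,
                    occluding=occluding, les=les, pressure=pressure)
        assert merge_cr_v2_to_v1(classify_cr_v2(m)) is classify_cr_v1(m)


class TestEgjOpening:
    @pytest.mark.parametrize(
        "di,dmax,expected",
        [
            (3.5, 18.0, EGJOpening.NORMAL),
            (1.0, 10.0, EGJOpening.REDUCED),
            (2.5, 13.0, EGJOpening.INCONCLUSIVE),
            (1.5, 17.0, EGJOpening.INCONCLUSIVE),
            (2.0, 16.0, EGJOpening.NORMAL),      # boundary: >= thresholds
        ],
    )
    def test_classes(self, di, dmax, expected):
        assert classify_egj_opening(di, dmax) is expected

    def test_non_positive_inputs_rejected(self):
        with pytest.raises(ValueError):
            classify_egj_opening(0.0, 15.0)
        with pytest.raises(ValueError):
            classify_egj_opening(2.0, -1.0)


class TestDecisionTables:
    @pytest.mark.parametrize(
        "cr,egjo,expected",
        [
            (CRPatternV2.ABSENT, EGJOpening.REDUCED,
             MotilityV2.NON_SPASTIC_OBSTRUCTION),
            (CRPatternV2.DISORDERED, EGJOpening.REDUCED,
             MotilityV2.SPASTIC_OBSTRUCTION),
            (CRPatternV2.NORMAL, EGJOpening.NORMAL, MotilityV2.NORMAL),
            (CRPatternV2.NORMAL, EGJOpening.REDUCED,
             MotilityV2.OBSTRUCTION_NORMAL_CR),
            (CRPatternV2.DIMINISHED, EGJOpening.NORMAL,
             MotilityV2.HYPOCONTRACTILITY),
        ],
    )
    def test_v2_lookups(self, cr, egjo, expected):
        assert classify_motility(cr, egjo, V2_TABLE) is expected

    def test_shipped_tables_are_total_and_valid(self):
        report = validate_decision_table(V2_TABLE)
        assert len(V2_TABLE.cells) == 15 and report.ok
        report1 = validate_decision_table(V1_TABLE)
        assert len(V1_TABLE.cells) == 12 and report1.ok

    def test_missing_cell_is_reported(self):
        broken = DecisionTable(version="v2.0", cells=dict(V2_TABLE.cells))
        del broken.cells[(CRPatternV2.SPASTIC, EGJOpening.REDUCED)]
        report = validate_decision_table(broken)
        assert len(report.violations) == 1
        assert "missing" in report.violations[0]

    def test_duplicate_cell_violates_single_valuedness(self):
        text = V2_TABLE.to_text()
        first_line = text.splitlines()[0]
        duplicated = text + first_line.rsplit("\t", 1)[0] + "\tuser-override\n"
        table = DecisionTable.from_text(duplicated)
        report = validate_decision_table(table)
        assert any("single-valuedness" in v for v in report.violations)

    def test_serialisation_round_trip(self, tmp_path):
        for table in (V2_TABLE, V1_TABLE):
            path = tmp_path / f"{table.version}.tsv"
            table.write(path)
            back = DecisionTable.read(path)
            assert back.version == table.version
            assert back.cells == table.cells

    def test_unmapped_combination_raises_table_incomplete(self):
        broken = DecisionTable(version="v2.0", cells=dict(V2_TABLE.cells))
        del broken.cells[(CRPatternV2.NORMAL, EGJOpening.NORMAL)]
        with pytest.raises(KeyError, match="incomplete"):
            classify_motility(CRPatternV2.NORMAL, EGJOpening.NORMAL, broken)


def test_end_to_end_every_cr_egjo_pair_maps_through_the_table():
    """Noise-free simulations of all 15 phenotype pairs land on the table."""
    from panometry.features import extract_metrics
    from panometry.topo import TopographySpec, simulate_topography

    cr_map = {
        "normal": CRPatternV2.NORMAL, "diminished": CRPatternV2.DIMINISHED,
        "disordered": CRPatternV2.DISORDERED, "absent": CRPatternV2.ABSENT,
        "spastic": CRPatternV2.SPASTIC,
    }
    egjo_map = {
        "normal": EGJOpening.NORMAL, "inconclusive": EGJOpening.INCONCLUSIVE,
        "reduced": EGJOpening.REDUCED,
    }
    for cr_name, egjo_name in itertools.product(cr_map, egjo_map):
        spec = TopographySpec.from_phenotypes(cr_name, egjo_name, seed=0)
        study, _ = simulate_topography(spec)
        m = extract_metrics(study)
        cr = classify_cr_v2(m)
        egjo = classify_egj_opening(m.egj_di_60, m.max_egj_diameter)
        assert (cr, egjo) == (cr_map[cr_name], egjo_map[egjo_name])
        assert classify_motility(cr, egjo, V2_TABLE) is \
            V2_TABLE.cells[(cr, egjo)][0]
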