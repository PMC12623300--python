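"""Diagnostic concordance between FLIP panometry classes and HRM diagnoses.

Implements the study-style analysis: partition of an adjudicated cohort into
the conclusive primary-analysis subset and the inconclusive remainder,
FLIP x HRM cross-tabulation, within-class proportions, positive/negative
predictive values for disorders of EGJ outflow (achalasia of any subtype or
conclusive EGJOO), v1.0 vs v2.0 reclassification tables, and standard group
comparison tests. Percentages are rounded half away from zero to integers,
matching the convention of the published tables; raw fractions are always
retained alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .adjudicate import (
    AdjudicatedDiagnosis,
    TBEStudy,
    adjudicate_diagnosis,
    is_outflow_disorder,
)
from .classify import MotilityV1, MotilityV2
from .cohort import (
    CATEGORY_TO_LABEL,
    FLIP_CLASS_ORDER,
    HRM_CATEGORY_ORDER,
    SyntheticPatient,
)


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero (92.7->93, 98.5->99)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class CohortRecord:
    """One patient in the concordance analysis."""

    patient_id: str
    flip_v2: MotilityV2
    adjudicated: AdjudicatedDiagnosis
    hrm_category: str                    # one of HRM_CATEGORY_ORDER
    flip_v1: MotilityV1 | None = None
    site: str | None = None


@dataclass
class ContingencyTable:
    """Labelled cross-tabulation with margins."""

    counts: pd.DataFrame                 # integer counts, labelled axes

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be >= 0")

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def column_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def cell(self, row, column) -> int:
        return int(self.counts.loc[row, column])


@dataclass(frozen=True)
class Proportion:
    numerator: int
    denominator: int

    @property
    def defined(self) -> bool:
        return self.denominator > 0

    @property
    def fraction(self) -> float | None:
        return self.numerator / self.denominator if self.defined else None

    @property
    def percent(self) -> int | None:
        """Integer percent, rounded half away from zero; None if undefined."""
        return round_half_away(100.0 * self.fraction) if self.defined else None


@dataclass(frozen=True)
class PredictiveValues:
    """PPV/NPV of FLIP class sets for a positive condition."""

    condition: str
    ppv: Proportion | None
    npv: Proportion | None


class UnadjudicatedError(ValueError):
    """Cohort records lack adjudication where the analysis requires it."""


def adjudicate_patients(
    patients: list[SyntheticPatient],
    flip_v1_of=None,
) -> list[CohortRecord]:
    """Adjudicate synthetic patients into concordance-ready records.

    ``flip_v1_of``, if given, maps a SyntheticPatient to its v1.0 class.
    """
    records = []
    for p in patients:
        records.append(CohortRecord(
            patient_id=p.patient_id,
            flip_v2=p.flip_class,
            adjudicated=adjudicate_diagnosis(p.ccv4_label, p.tbe),
            hrm_category=p.hrm_category,
            flip_v1=flip_v1_of(p) if flip_v1_of is not None else None,
        ))
    return records


def expand_counts_to_records(counts: pd.DataFrame) -> list[CohortRecord]:
    """Expand a (HRM category x FLIP class) count table into unit records.

    Each inconclusive-EGJOO patient is represented as an EGJOO label with a
    missing TBE, so adjudication reproduces the table's conclusive/
    inconclusive split exactly.
    """
    records = []
    i = 0
    for hrm_category in counts.index:
        label = CATEGORY_TO_LABEL[hrm_category]
        for flip_code in counts.columns:
            cell = int(counts.loc[hrm_category, flip_code])
            for _ in range(cell):
                if hrm_category == "egjoo":
                    tbe = TBEStudy(present=True, column_height_1min=8.0,
                                   column_height_5min=7.0)
                else:
                    tbe = TBEStudy.missing()
                records.append(CohortRecord(
                    patient_id=f"F{i:04d}",
                    flip_v2=MotilityV2(flip_code),
                    adjudicated=adjudicate_diagnosis(label, tbe),
                    hrm_category=hrm_category,
                ))
                i += 1
    return records


def primary_filter(
    records: list[CohortRecord],
) -> tuple[list[CohortRecord], list[CohortRecord]]:
    """Partition into (conclusive primary-analysis subset, excluded subset)."""
    for r in records:
        if not isinstance(r.adjudicated, AdjudicatedDiagnosis):
            raise UnadjudicatedError(
                f"record {r.patient_id} is not adjudicated"
            )
    conclusive = [r for r in records if r.adjudicated.conclusive]
    excluded = [r for r in records if not r.adjudicated.conclusive]
    assert len(conclusive) + len(excluded) == len(records)
    return conclusive, excluded


_VARIABLES = {
    "flip_v2": (lambda r: r.flip_v2.value,
                [c.value for c in FLIP_CLASS_ORDER]
                + [MotilityV2.OBSTRUCTION_NORMAL_CR.value]),
    "flip_v1": (lambda r: r.flip_v1.value if r.flip_v1 else None,
                [c.value for c in MotilityV1]),
    "hrm": (lambda r: r.hrm_category, list(HRM_CATEGORY_ORDER)),
}


def build_crosstab(
    records: list[CohortRecord], row_var: str, col_var: str
) -> ContingencyTable:
    """Cross-tabulate two categorical variables in canonical label order."""
    for var in (row_var, col_var):
        if var not in _VARIABLES:
            raise KeyError(f"unknown variable {var!r}; "
                           f"choose from {sorted(_VARIABLES)}")
    row_get, row_order = _VARIABLES[row_var]
    col_get, col_order = _VARIABLES[col_var]
    rows = [row_get(r) for r in records]
    cols = [col_get(r) for r in records]
    if any(v is None for v in rows + cols):
        raise ValueError(f"records missing values for {row_var}/{col_var}")
    counts = pd.crosstab(pd.Series(rows, name=row_var),
                         pd.Series(cols, name=col_var))
    counts = counts.reindex(index=row_order, columns=col_order,
                            fill_value=0).fillna(0).astype(int)
    return ContingencyTable(counts=counts)


def proportion_within(
    table: ContingencyTable, rows: list[str], column: str
) -> Proportion:
    """Share of a column's total falling in the given rows."""
    denominator = int(table.counts[column].sum())
    numerator = int(table.counts.loc[list(rows), column].sum())
    return Proportion(numerator=numerator, denominator=denominator)


def predictive_values(
    records: list[CohortRecord],
    positive_classes: set[MotilityV2] | None = None,
    negative_classes: set[MotilityV2] | None = None,
    condition: str = "disorder of EGJ outflow",
) -> PredictiveValues:
    """PPV/NPV of FLIP class sets for disorders of EGJ outflow.

    PPV = P(condition | FLIP class in positive set);
    NPV = P(no condition | FLIP class in negative set).
    Requires a conclusive cohort (run ``primary_filter`` first).
    """
    for r in records:
        if not r.adjudicated.conclusive:
            raise UnadjudicatedError(
                "predictive values require a conclusive cohort"
            )
    ppv = npv = None
    if positive_classes:
        pos = [r for r in records if r.flip_v2 in positive_classes]
        ppv = Proportion(
            numerator=sum(is_outflow_disorder(r.adjudicated) for r in pos),
            denominator=len(pos),
        )
    if negative_classes:
        neg = [r for r in records if r.flip_v2 in negative_classes]
        npv = Proportion(
            numerator=sum(not is_outflow_disorder(r.adjudicated) for r in neg),
            denominator=len(neg),
        )
    return PredictiveValues(condition=condition, ppv=ppv, npv=npv)


def version_reclassification(
    records: list[CohortRecord],
) -> tuple[ContingencyTable, dict]:
    """v1.0 x v2.0 flow table with a per-cell HRM-category breakdown."""
    if any(r.flip_v1 is None for r in records):
        raise ValueError("version_reclassification requires v1.0 labels on "
                         "every record")
    table = build_crosstab(records, "flip_v1", "flip_v2")
    breakdown: dict = {}
    for r in records:
        key = (r.flip_v1.value, r.flip_v2.value)
        cell = breakdown.setdefault(key, {})
        cell[r.hrm_category] = cell.get(r.hrm_category, 0) + 1
    return table, breakdown


@dataclass(frozen=True)
class GroupTestResult:
    test: str
    statistic: float | None
    pvalue: float | None

    @property
    def defined(self) -> bool:
        return self.statistic is not None


def chi_square_test(counts: pd.DataFrame | np.ndarray) -> GroupTestResult:
    """Uncorrected chi-square test of independence on a contingency table."""
    arr = np.asarray(counts, dtype=float)
    if arr.sum() == 0 or min(arr.shape) < 2:
        return GroupTestResult(test="chi_square", statistic=None, pvalue=None)
    res = stats.chi2_contingency(arr, correction=False)
    return GroupTestResult(test="chi_square", statistic=float(res.statistic),
                           pvalue=float(res.pvalue))


def group_comparison_tests(
    groups: list[np.ndarray], parametric: bool = True
) -> GroupTestResult:
    """Compare continuous values between groups.

    Two groups: t test (parametric) or Mann-Whitney U; three or more: one-way
    ANOVA or Kruskal-Wallis. Degenerate input yields an undefined result.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        return GroupTestResult(test="undefined", statistic=None, pvalue=None)
    if len(groups) == 2:
        if parametric:
            res = stats.ttest_ind(*groups)
            name = "t_test"
        else:
            res = stats.mannwhitneyu(*groups, alternative="two-sided")
            name = "mann_whitney_u"
    else:
        if parametric:
            res = stats.f_oneway(*groups)
            name = "anova"
        else:
            res = stats.kruskal(*groups)
            name = "kruskal_wallis"
    return GroupTestResult(test=name, statistic=float(res.statistic),
                           pvalue=float(res.pvalue))


# ---------------------------------------------------------------------------
# headline report: every printed concordance quantity, from a count table
# ---------------------------------------------------------------------------

OUTFLOW_DISORDER_ROWS = ("achalasia_i", "achalasia_ii", "achalasia_iii",
                         "egjoo")


def headline_report(counts: pd.DataFrame) -> dict:
    """Recompute the study's headline concordance figures from a count table.

    Input is a (HRM category x FLIP v2.0 class) table like the packaged
    fixture. All percentages are integer, rounded half away from zero.
    """
    records = expand_counts_to_records(counts)
    conclusive, excluded = primary_filter(records)
    ct = build_crosstab(conclusive, "hrm", "flip_v2")

    def pct(rows, column):
        p = proportion_within(ct, rows, column)
        return {"numerator": p.numerator, "denominator": p.denominator,
                "percent": p.percent}

    pv = predictive_values(
        conclusive,
        positive_classes={MotilityV2.NON_SPASTIC_OBSTRUCTION},
        negative_classes={MotilityV2.NORMAL},
    )
    normal_col = MotilityV2.NORMAL.value
    nso_col = MotilityV2.NON_SPASTIC_OBSTRUCTION.value
    hypo_col = MotilityV2.HYPOCONTRACTILITY.value
    spasm_col = MotilityV2.POSSIBLE_SPASM.value
    pobs_col = MotilityV2.POSSIBLE_OBSTRUCTION.value

    # share of type III achalasia classified spastic obstruction (row-wise)
    ach3_row = ct.counts.loc["achalasia_iii"]
    ach3 = Proportion(
        numerator=int(ach3_row[MotilityV2.SPASTIC_OBSTRUCTION.value]),
        denominator=int(ach3_row.sum()),
    )

    return {
        "total_n": int(counts.to_numpy().sum()),
        "conclusive_n": len(conclusive),
        "excluded_inconclusive_n": len(excluded),
        "normal_flip": {
            "n": int(ct.counts[normal_col].sum()),
            "pct_normal_hrm": pct(["normal"], normal_col),
            "pct_normal_or_iem_hrm": pct(["normal", "iem"], normal_col),
            "npv_outflow": {"numerator": pv.npv.numerator,
                            "denominator": pv.npv.denominator,
                            "percent": pv.npv.percent},
        },
        "non_spastic_obstruction": {
            "n": int(ct.counts[nso_col].sum()),
            "ppv_outflow": {"numerator": pv.ppv.numerator,
                            "denominator": pv.ppv.denominator,
                            "percent": pv.ppv.percent},
            "pct_type_1_2_achalasia": pct(["achalasia_i", "achalasia_ii"],
                                          nso_col),
        },
        "hypocontractility": {
            "n": int(ct.counts[hypo_col].sum()),
            "pct_absent_or_iem": pct(["absent_contractility", "iem"],
                                     hypo_col),
        },
        "possible_spasm": {
            "n": int(ct.counts[spasm_col].sum()),
            "pct_spastic_hrm": pct(["hypercontractile", "des"], spasm_col),
            "pct_normal_hrm": pct(["normal"], spasm_col),
        },
        "possible_obstruction": {
            "n": int(ct.counts[pobs_col].sum()),
            "pct_type_1_2_achalasia": pct(["achalasia_i", "achalasia_ii"],
                                          pobs_col),
        },
        "type_3_achalasia": {
            "n": ach3.denominator,
            "pct_spastic_obstruction": {"numerator": ach3.numerator,
                                        "denominator": ach3.denominator,
                                        "percent": ach3.percent},
        },
    }
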