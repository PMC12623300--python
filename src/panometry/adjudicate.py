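"""HRM (CCv4.0) diagnosis adjudication against IRP and timed barium esophagram.

High-resolution manometry diagnoses enter as Chicago Classification v4.0
labels. Achalasia (any subtype) is a conclusive disorder of EGJ outflow on
its own. EGJ outflow obstruction (EGJOO) is inconclusive at the HRM level and
is resolved by the timed barium esophagram (TBE):

* abnormal TBE (barium column > 5 cm at 5 min, or > 5 cm at 1 min together
  with impaction of a 12.5-mm barium tablet) -> conclusive EGJOO, a disorder
  of EGJ outflow;
* normal TBE -> normal EGJ outflow;
* missing or inconclusive TBE (column > 5 cm at 1 min but <= 5 cm at 5 min
  with the tablet not administered or passed; or column <= 5 cm at 1 min with
  tablet impaction) -> inconclusive, excluded from a primary analysis.

A standalone IRP utility implements the positional cut-offs (median IRP
abnormal if > 15 mmHg supine, > 12 mmHg upright); labels themselves are not
re-derived from raw HRM metrics here.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass


class CCv4Label(enum.Enum):
    NORMAL = "normal"
    IEM = "iem"
    ABSENT_CONTRACTILITY = "absent_contractility"
    DES = "des"
    HYPERCONTRACTILE = "hypercontractile"
    EGJOO = "egjoo"
    ACHALASIA_I = "achalasia_i"
    ACHALASIA_II = "achalasia_ii"
    ACHALASIA_III = "achalasia_iii"
    #: an HRM study inconclusive for reasons other than EGJOO; always
    #: adjudicates to inconclusive (needed for cohort bookkeeping)
    INCONCLUSIVE_OTHER = "inconclusive_other"


#: labels that are inconclusive at the HRM level, pending TBE
HRM_INCONCLUSIVE_LABELS = frozenset({CCv4Label.EGJOO})

ACHALASIA_LABELS = frozenset({
    CCv4Label.ACHALASIA_I, CCv4Label.ACHALASIA_II, CCv4Label.ACHALASIA_III,
})


class Tablet(enum.Enum):
    NOT_ADMINISTERED = "not_administered"
    PASSED = "passed"
    IMPACTED = "impacted"


@dataclass(frozen=True)
class TBEStudy:
    """Timed barium esophagram: column heights (cm) and tablet outcome.

    The 2-min image is carried for completeness but no rule consumes it.
    ``present=False`` models a missing study.
    """

    present: bool = True
    column_height_1min: float = 0.0
    column_height_5min: float = 0.0
    column_height_2min: float | None = None
    tablet: Tablet = Tablet.NOT_ADMINISTERED

    def __post_init__(self):
        if self.column_height_1min < 0 or self.column_height_5min < 0:
            raise ValueError("barium column heights must be >= 0")

    @property
    def height_inversion(self) -> bool:
        """Flag a 5-min column taller than the 1-min one (unexpected)."""
        return self.column_height_5min > self.column_height_1min

    @classmethod
    def missing(cls) -> "TBEStudy":
        return cls(present=False)


class TBEResult(enum.Enum):
    ABNORMAL = "abnormal"
    NORMAL = "normal"
    INCONCLUSIVE = "inconclusive"
    MISSING = "missing"


class OutflowStatus(enum.Enum):
    CONCLUSIVE_OUTFLOW_DISORDER = "conclusive_outflow_disorder"
    NORMAL_OUTFLOW = "normal_outflow"
    INCONCLUSIVE = "inconclusive"


@dataclass(frozen=True)
class AdjudicatedDiagnosis:
    """A CCv4.0 label resolved into an EGJ-outflow status."""

    label: CCv4Label
    outflow_status: OutflowStatus
    conclusive: bool
    #: conclusive EGJOO is EGJOO confirmed by an abnormal TBE
    conclusive_egjoo: bool = False
    rationale: tuple[str, ...] = ()

    def __post_init__(self):
        if self.label in ACHALASIA_LABELS and (
            self.outflow_status is not OutflowStatus.CONCLUSIVE_OUTFLOW_DISORDER
        ):
            raise ValueError("achalasia must be a conclusive outflow disorder")
        if not self.conclusive and (
            self.outflow_status is not OutflowStatus.INCONCLUSIVE
        ):
            raise ValueError("non-conclusive diagnoses have inconclusive outflow")


def check_irp_abnormal(median_irp: float, position: str) -> bool:
    """Is a median integrated relaxation pressure abnormal for the position?

    Supine swallows: abnormal if > 15 mmHg; upright: abnormal if > 12 mmHg.
    """
    if not math.isfinite(median_irp):
        raise ValueError("median IRP must be finite")
    if position == "supine":
        return median_irp > 15.0
    if position == "upright":
        return median_irp > 12.0
    raise ValueError(f"unknown swallow position {position!r}")


def classify_tbe(
    t: TBEStudy,
    height_threshold_cm: float = 5.0,
    inconclusive_clause: str = "not-administered-or-passed",
) -> TBEResult:
    """Classify a timed barium esophagram.

    ``inconclusive_clause`` selects the parse of the inconclusive rule's
    tablet condition for a tall 1-min/cleared 5-min column:
    ``"not-administered-or-passed"`` (default) or ``"not-administered-only"``.
    """
    if t is None or not t.present:
        return TBEResult.MISSING
    h1, h5 = t.column_height_1min, t.column_height_5min
    thr = height_threshold_cm
    if h5 > thr or (h1 > thr and t.tablet is Tablet.IMPACTED):
        return TBEResult.ABNORMAL
    if inconclusive_clause == "not-administered-or-passed":
        cleared_tablet_states = (Tablet.NOT_ADMINISTERED, Tablet.PASSED)
    elif inconclusive_clause == "not-administered-only":
        cleared_tablet_states = (Tablet.NOT_ADMINISTERED,)
    else:
        raise ValueError(f"unknown inconclusive_clause {inconclusive_clause!r}")
    if h1 > thr and h5 <= thr and t.tablet in cleared_tablet_states:
        return TBEResult.INCONCLUSIVE
    if h1 <= thr and t.tablet is Tablet.IMPACTED:
        return TBEResult.INCONCLUSIVE
    return TBEResult.NORMAL


def adjudicate_diagnosis(
    label: CCv4Label,
    tbe: TBEStudy | None = None,
    inconclusive_clause: str = "not-administered-or-passed",
) -> AdjudicatedDiagnosis:
    """Resolve a CCv4.0 label and TBE into an outflow status."""
    if label in ACHALASIA_LABELS:
        return AdjudicatedDiagnosis(
            label=label,
            outflow_status=OutflowStatus.CONCLUSIVE_OUTFLOW_DISORDER,
            conclusive=True,
            rationale=("achalasia is conclusive regardless of TBE",),
        )
    if label is CCv4Label.INCONCLUSIVE_OTHER:
        return AdjudicatedDiagnosis(
            label=label,
            outflow_status=OutflowStatus.INCONCLUSIVE,
            conclusive=False,
            rationale=("HRM inconclusive (non-EGJOO)",),
        )
    if label in HRM_INCONCLUSIVE_LABELS:
        result = classify_tbe(
            tbe if tbe is not None else TBEStudy.missing(),
            inconclusive_clause=inconclusive_clause,
        )
        if result is TBEResult.ABNORMAL:
            return AdjudicatedDiagnosis(
                label=label,
                outflow_status=OutflowStatus.CONCLUSIVE_OUTFLOW_DISORDER,
                conclusive=True,
                conclusive_egjoo=True,
                rationale=("inconclusive HRM label", "abnormal TBE -> "
                           "conclusive disorder of EGJ outflow"),
            )
        if result is TBEResult.NORMAL:
            return AdjudicatedDiagnosis(
                label=label,
                outflow_status=OutflowStatus.NORMAL_OUTFLOW,
                conclusive=True,
                rationale=("inconclusive HRM label",
                           "normal TBE -> normal EGJ outflow"),
            )
        return AdjudicatedDiagnosis(
            label=label,
            outflow_status=OutflowStatus.INCONCLUSIVE,
            conclusive=False,
            rationale=("inconclusive HRM label",
                       f"{result.value} TBE -> inconclusive EGJ outflow"),
        )
    return AdjudicatedDiagnosis(
        label=label,
        outflow_status=OutflowStatus.NORMAL_OUTFLOW,
        conclusive=True,
        rationale=("conclusive non-obstructive HRM label",),
    )


def is_outflow_disorder(d: AdjudicatedDiagnosis) -> bool:
    """Is this a disorder of EGJ outflow (achalasia or conclusive EGJOO)?"""
    if not d.conclusive:
        raise ValueError("outflow-disorder status undefined for inconclusive "
                         "diagnoses")
    return d.outflow_status is OutflowStatus.CONCLUSIVE_OUTFLOW_DISORDER
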