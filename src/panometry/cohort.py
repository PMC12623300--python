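"""Synthetic patient cohorts calibrated to the study's printed cross-tabulation.

The packaged fixture stores the published cohort table verbatim: counts of
patients cross-tabulated by CCv4.0 HRM diagnosis (rows, including the two
inconclusive categories) and FLIP panometry v2.0 motility classification
(columns), totalling 805 patients. ``calibrate_joint_from_counts`` turns any
such table of counts into a joint categorical distribution;
``sample_cohort`` draws i.i.d. synthetic patients from it and attaches FLIP
metrics consistent with the drawn FLIP class (so that re-classification under
default thresholds recovers the class) and a TBE consistent with the drawn
HRM conclusiveness category.

Known internal inconsistency of the source table: its conclusive column sums
give 75 spastic-obstruction and 200 possible-obstruction patients, while the
source prose says 76 and 199. The fixture stores the table verbatim.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .adjudicate import CCv4Label, TBEStudy, Tablet
from .classify import (
    CRPatternV2,
    ClassifierThresholds,
    EGJOpening,
    MotilityV2,
    V2_TABLE,
)
from .features import FlipMetrics

#: canonical FLIP v2.0 class order (columns of the fixture)
FLIP_CLASS_ORDER = (
    MotilityV2.NORMAL,
    MotilityV2.HYPOCONTRACTILITY,
    MotilityV2.NON_SPASTIC_OBSTRUCTION,
    MotilityV2.SPASTIC_OBSTRUCTION,
    MotilityV2.POSSIBLE_SPASM,
    MotilityV2.POSSIBLE_OBSTRUCTION,
)

#: canonical HRM category order (rows of the fixture); the two inconclusive
#: categories follow the conclusive CCv4.0 labels
HRM_CATEGORY_ORDER = (
    "normal", "iem", "absent_contractility", "des", "hypercontractile",
    "egjoo", "achalasia_i", "achalasia_ii", "achalasia_iii",
    "inconclusive_egjoo", "inconclusive_other",
)

HRM_CONCLUSIVE_CATEGORIES = HRM_CATEGORY_ORDER[:9]
HRM_INCONCLUSIVE_CATEGORIES = HRM_CATEGORY_ORDER[9:]

#: verbatim fixture labels <-> canonical codes
FLIP_LABELS = {
    "Normal": MotilityV2.NORMAL,
    "Hypo-contractility": MotilityV2.HYPOCONTRACTILITY,
    "Non-spastic obstruction": MotilityV2.NON_SPASTIC_OBSTRUCTION,
    "Spastic obstruction": MotilityV2.SPASTIC_OBSTRUCTION,
    "Possible spasm": MotilityV2.POSSIBLE_SPASM,
    "Possible obstruction": MotilityV2.POSSIBLE_OBSTRUCTION,
}
HRM_LABELS = {
    "Normal": "normal",
    "IEM": "iem",
    "Absent": "absent_contractility",
    "DES": "des",
    "Hypercontractile": "hypercontractile",
    "EGJOO": "egjoo",
    "Type I achalasia": "achalasia_i",
    "Type II achalasia": "achalasia_ii",
    "Type III achalasia": "achalasia_iii",
    "Inconclusive EGJOO": "inconclusive_egjoo",
    "Inconclusive": "inconclusive_other",
}

#: HRM category -> CCv4.0 label handed to the adjudicator
CATEGORY_TO_LABEL = {
    "normal": CCv4Label.NORMAL,
    "iem": CCv4Label.IEM,
    "absent_contractility": CCv4Label.ABSENT_CONTRACTILITY,
    "des": CCv4Label.DES,
    "hypercontractile": CCv4Label.HYPERCONTRACTILE,
    "egjoo": CCv4Label.EGJOO,
    "achalasia_i": CCv4Label.ACHALASIA_I,
    "achalasia_ii": CCv4Label.ACHALASIA_II,
    "achalasia_iii": CCv4Label.ACHALASIA_III,
    "inconclusive_egjoo": CCv4Label.EGJOO,
    "inconclusive_other": CCv4Label.INCONCLUSIVE_OTHER,
}


def load_table2_counts() -> pd.DataFrame:
    """Packaged cohort cross-tabulation as a (HRM x FLIP-class) count table.

    Rows and columns are returned in canonical code order; values are ints.
    """
    ref = importlib.resources.files("panometry") / "data" / "table2_counts.csv"
    with importlib.resources.as_file(ref) as path:
        raw = pd.read_csv(path, comment="#", index_col=0)
    raw.index = [HRM_LABELS[label] for label in raw.index]
    raw.columns = [FLIP_LABELS[label].value for label in raw.columns]
    counts = raw.reindex(
        index=list(HRM_CATEGORY_ORDER),
        columns=[c.value for c in FLIP_CLASS_ORDER],
    )
    return counts.astype(int)


@dataclass(frozen=True)
class JointDistributionSpec:
    """Joint probability table over (HRM category) x (FLIP v2.0 class)."""

    probs: pd.DataFrame          # rows: HRM categories; columns: class codes
    seed: int = 0

    def __post_init__(self):
        values = self.probs.to_numpy(dtype=float)
        if np.any(values < 0):
            raise ValueError("probabilities must be >= 0")
        if abs(values.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1")


def calibrate_joint_from_counts(
    counts: pd.DataFrame, seed: int = 0
) -> JointDistributionSpec:
    """Normalise a table of non-negative counts into a joint distribution."""
    values = counts.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("counts must be non-negative")
    total = values.sum()
    if total <= 0:
        raise ValueError("counts must contain at least one positive cell")
    return JointDistributionSpec(probs=counts / total, seed=seed)


@dataclass(frozen=True)
class SyntheticPatient:
    """One synthetic patient with class-consistent metrics and TBE."""

    patient_id: str
    flip_class: MotilityV2        # ground truth
    cr: CRPatternV2
    egjo: EGJOpening
    metrics: FlipMetrics
    hrm_category: str             # one of HRM_CATEGORY_ORDER
    ccv4_label: CCv4Label
    tbe: TBEStudy
    age: float | None = None
    sex: str | None = None


def _sample_egj_metrics(egjo: EGJOpening, rng: np.random.Generator):
    """(egj_di_60, max_egj_diameter) drawn inside the class's region."""
    if egjo is EGJOpening.NORMAL:
        return rng.uniform(2.5, 6.0), rng.uniform(16.0, 22.0)
    if egjo is EGJOpening.REDUCED:
        return rng.uniform(0.5, 1.8), rng.uniform(6.0, 11.5)
    # neither normal (DI < 2) nor reduced (max diameter >= 12)
    return rng.uniform(0.5, 1.9), rng.uniform(12.5, 15.5)


def _sample_cr_metrics(cr: CRPatternV2, rng: np.random.Generator):
    """(n_qual, any_contractility, occluding, les, pressure_60)."""
    if cr is CRPatternV2.NORMAL:
        return int(rng.integers(2, 5)), True, False, False, rng.uniform(15, 60)
    if cr is CRPatternV2.DIMINISHED:
        return int(rng.integers(0, 2)), True, False, False, rng.uniform(15, 40)
    if cr is CRPatternV2.DISORDERED:
        return int(rng.integers(0, 2)), True, False, False, rng.uniform(41, 70)
    if cr is CRPatternV2.ABSENT:
        return 0, False, False, False, rng.uniform(15, 60)
    occluding = bool(rng.integers(0, 2))
    return (int(rng.integers(0, 2)), True, occluding, not occluding,
            rng.uniform(15, 70))


def attach_metrics(
    flip_class: MotilityV2,
    rng: np.random.Generator,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> tuple[FlipMetrics, CRPatternV2, EGJOpening]:
    """Sample FlipMetrics that re-classify to ``flip_class`` by construction.

    A (CR, EGJ-opening) pair mapping to the class is drawn uniformly from the
    v2.0 decision table's preimage, then metrics are drawn from uniform
    ranges inside that pair's region of metric space.
    """
    preimage = sorted(
        (key for key, (mot, _) in V2_TABLE.cells.items() if mot is flip_class),
        key=lambda key: (key[0].value, key[1].value),
    )
    if not preimage:
        raise ValueError(f"no (CR, EGJO) pair maps to {flip_class.value}")
    cr, egjo = preimage[rng.integers(0, len(preimage))]
    di, dmax = _sample_egj_metrics(egjo, rng)
    n_qual, any_c, occluding, les, pressure = _sample_cr_metrics(cr, rng)
    metrics = FlipMetrics(
        egj_di_60=di, max_egj_diameter=dmax, pressure_60=pressure,
        n_qualifying_antegrade=n_qual, any_contractility=any_c,
        sustained_occluding=occluding, sustained_les=les,
        rac_pattern=n_qual >= 3,
    )
    return metrics, cr, egjo


def _sample_tbe(hrm_category: str, rng: np.random.Generator) -> TBEStudy:
    """A TBE consistent with the drawn HRM conclusiveness category."""
    if hrm_category == "egjoo":
        # conclusive EGJOO requires an abnormal TBE
        h5 = rng.uniform(6.0, 12.0)
        return TBEStudy(
            present=True,
            column_height_1min=h5 + rng.uniform(0.0, 5.0),
            column_height_5min=h5,
            tablet=Tablet(rng.choice([t.value for t in Tablet])),
        )
    # inconclusive EGJOO mirrors the dominant pattern in the source cohort:
    # an inconclusive HRM with no TBE performed; conclusive non-obstructive
    # labels need no TBE at all
    return TBEStudy.missing()


def sample_cohort(
    spec: JointDistributionSpec,
    n: int,
    seed: int | None = None,
    demographics: bool = True,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> list[SyntheticPatient]:
    """Draw ``n`` i.i.d. synthetic patients from the joint distribution."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    probs = spec.probs.to_numpy(dtype=float).reshape(-1)
    hrm_cats = list(spec.probs.index)
    flip_codes = list(spec.probs.columns)
    cells = [(h, f) for h in hrm_cats for f in flip_codes]
    draws = rng.choice(len(cells), size=n, p=probs)

    patients = []
    for i, cell in enumerate(draws):
        hrm_category, flip_code = cells[cell]
        flip_class = MotilityV2(flip_code)
        metrics, cr, egjo = attach_metrics(flip_class, rng, thresholds)
        tbe = _sample_tbe(hrm_category, rng)
        age = sex = None
        if demographics:
            age = float(np.clip(rng.normal(55.0, 17.0), 18.0, 91.0))
            sex = "female" if rng.random() < 0.62 else "male"
        patients.append(SyntheticPatient(
            patient_id=f"P{i:06d}",
            flip_class=flip_class, cr=cr, egjo=egjo, metrics=metrics,
            hrm_category=hrm_category,
            ccv4_label=CATEGORY_TO_LABEL[hrm_category],
            tbe=tbe, age=age, sex=sex,
        ))
    return patients
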