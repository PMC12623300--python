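"""Rule-based FLIP panometry motility classification (v1.0 and v2.0).

Two rule layers. First, the contractile-response (CR) pattern and the EGJ
opening class are each derived from FLIP metrics:

* CR v2.0 precedence: SPASTIC (sustained occluding or sustained LES
  contraction) -> NORMAL (more than one distinct antegrade contraction of at
  least 6 cm with a pressure rise > 10 mmHg) -> DIMINISHED/DISORDERED
  (contractility present but not normal/spastic; split at a 60-mL FLIP
  pressure of 40 mmHg, <= 40 diminished, > 40 disordered) -> ABSENT.
* CR v1.0 is the same scheme without the 40-mmHg split: diminished and
  disordered merge into a single impaired/disordered (IDCR) category, and
  spastic is called spastic-reactive.
* EGJ opening: NORMAL if EGJ-DI >= 2.0 mm^2/mmHg and maximum EGJ diameter
  >= 16 mm; REDUCED if EGJ-DI < 2.0 and maximum diameter < 12 mm; otherwise
  INCONCLUSIVE (called "borderline" in v1.0). The numeric cut-offs are
  consensus defaults, configurable.

Second, a total decision table maps (CR pattern, EGJ opening) to a motility
class. Tables are explicit, serialisable, and carry a provenance note per
cell so reconstructed cells are distinguishable from anchored ones.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

from .features import FlipMetrics


class CRPatternV2(enum.Enum):
    NORMAL = "normal"
    DIMINISHED = "diminished"
    DISORDERED = "disordered"
    ABSENT = "absent"
    SPASTIC = "spastic"


class CRPatternV1(enum.Enum):
    NORMAL = "normal"
    IMPAIRED_DISORDERED = "impaired_disordered"
    ABSENT = "absent"
    SPASTIC_REACTIVE = "spastic_reactive"


class EGJOpening(enum.Enum):
    NORMAL = "normal"
    INCONCLUSIVE = "inconclusive"   # "borderline" in v1.0 nomenclature
    REDUCED = "reduced"


class MotilityV2(enum.Enum):
    NORMAL = "normal"
    HYPOCONTRACTILITY = "hypocontractility"
    NON_SPASTIC_OBSTRUCTION = "non_spastic_obstruction"
    SPASTIC_OBSTRUCTION = "spastic_obstruction"
    POSSIBLE_SPASM = "possible_spasm"
    POSSIBLE_OBSTRUCTION = "possible_obstruction"
    OBSTRUCTION_NORMAL_CR = "obstruction_normal_cr"


class MotilityV1(enum.Enum):
    NORMAL = "normal"
    WEAK = "weak"
    OBSTRUCTION_WEAK_CR = "obstruction_weak_cr"
    OBSTRUCTION_NORMAL_CR = "obstruction_normal_cr"
    SPASTIC_REACTIVE = "spastic_reactive"
    BORDERLINE_OTHER = "borderline_other"


PROVENANCES = ("paper-anchored", "consensus-default", "user-override")


@dataclass(frozen=True)
class ClassifierThresholds:
    """Numeric cut-offs for CR and EGJ-opening classification."""

    #: 60-mL FLIP pressure split between diminished and disordered (mmHg)
    pressure_split: float = 40.0
    #: minimum count of qualifying antegrade contractions for normal CR (> 1)
    normal_min_antegrade: int = 2
    #: EGJ-DI (mm^2/mmHg) at/above which opening can be normal
    di_normal_min: float = 2.0
    #: maximum EGJ diameter (mm) at/above which opening can be normal
    dmax_normal_min: float = 16.0
    #: EGJ-DI below which opening can be reduced
    di_reduced_max: float = 2.0
    #: maximum EGJ diameter below which opening can be reduced
    dmax_reduced_max: float = 12.0


@dataclass
class DecisionTable:
    """Total mapping (CR pattern, EGJ opening) -> motility class.

    ``cells`` maps ``(cr, egjo)`` to ``(motility_class, provenance)``.
    """

    version: str                          # "v2.0" or "v1.0"
    cells: dict = field(default_factory=dict)

    @property
    def cr_type(self):
        return CRPatternV2 if self.version == "v2.0" else CRPatternV1

    @property
    def motility_type(self):
        return MotilityV2 if self.version == "v2.0" else MotilityV1

    def lookup(self, cr, egjo: EGJOpening):
        try:
            return self.cells[(cr, egjo)][0]
        except KeyError:
            raise KeyError(
                f"decision table {self.version} has no cell for "
                f"({cr.value}, {egjo.value}); table incomplete"
            ) from None

    def set_cell(self, cr, egjo, motility, provenance="user-override"):
        self.cells[(cr, egjo)] = (motility, provenance)

    # -- serialisation: one cell per line, human-auditable ------------------

    def to_text(self) -> str:
        lines = []
        for (cr, egjo), (mot, prov) in sorted(
            self.cells.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value)
        ):
            lines.append(
                f"{self.version}\t{cr.value}\t{egjo.value}\t{mot.value}\t{prov}"
            )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "DecisionTable":
        table = None
        duplicates = []
        for raw in text.splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            version, cr_s, egjo_s, mot_s, prov = line.split("\t")
            if table is None:
                table = cls(version=version)
            elif table.version != version:
                raise ValueError("mixed scheme versions in one table file")
            key = (table.cr_type(cr_s), EGJOpening(egjo_s))
            if key in table.cells:
                duplicates.append(key)
            table.cells[key] = (table.motility_type(mot_s), prov)
        if table is None:
            raise ValueError("empty decision-table text")
        table._duplicate_keys = duplicates  # retained for validation
        return table

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text())

    @classmethod
    def read(cls, path: str | Path) -> "DecisionTable":
        return cls.from_text(Path(path).read_text())


@dataclass
class TableValidationReport:
    violations: list

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_decision_table(table: DecisionTable) -> TableValidationReport:
    """Check totality, single-valuedness, and provenance annotation."""
    violations = []
    for cr in table.cr_type:
        for egjo in EGJOpening:
            if (cr, egjo) not in table.cells:
                violations.append(
                    f"missing cell ({cr.value}, {egjo.value})"
                )
    for (cr, egjo), (mot, prov) in table.cells.items():
        if not isinstance(mot, table.motility_type):
            violations.append(
                f"cell ({cr.value}, {egjo.value}) maps outside the "
                f"{table.version} class set"
            )
        if prov not in PROVENANCES:
            violations.append(
                f"cell ({cr.value}, {egjo.value}) has unlabelled provenance"
            )
    for key in getattr(table, "_duplicate_keys", []):
        violations.append(
            f"duplicate cell ({key[0].value}, {key[1].value}) "
            "violates single-valuedness"
        )
    return TableValidationReport(violations=violations)


def _build_v2_table() -> DecisionTable:
    t = DecisionTable(version="v2.0")
    C, E, M = CRPatternV2, EGJOpening, MotilityV2
    anchored = "paper-anchored"
    default = "consensus-default"
    t.set_cell(C.NORMAL, E.NORMAL, M.NORMAL, anchored)
    t.set_cell(C.DIMINISHED, E.NORMAL, M.HYPOCONTRACTILITY, anchored)
    t.set_cell(C.ABSENT, E.NORMAL, M.HYPOCONTRACTILITY, anchored)
    t.set_cell(C.DISORDERED, E.NORMAL, M.POSSIBLE_SPASM, anchored)
    t.set_cell(C.SPASTIC, E.NORMAL, M.POSSIBLE_SPASM, anchored)
    t.set_cell(C.NORMAL, E.INCONCLUSIVE, M.POSSIBLE_OBSTRUCTION, default)
    t.set_cell(C.DIMINISHED, E.INCONCLUSIVE, M.POSSIBLE_OBSTRUCTION, default)
    t.set_cell(C.ABSENT, E.INCONCLUSIVE, M.POSSIBLE_OBSTRUCTION, default)
    t.set_cell(C.DISORDERED, E.INCONCLUSIVE, M.POSSIBLE_SPASM, default)
    t.set_cell(C.SPASTIC, E.INCONCLUSIVE, M.POSSIBLE_SPASM, default)
    t.set_cell(C.NORMAL, E.REDUCED, M.OBSTRUCTION_NORMAL_CR, anchored)
    t.set_cell(C.DIMINISHED, E.REDUCED, M.NON_SPASTIC_OBSTRUCTION, anchored)
    t.set_cell(C.ABSENT, E.REDUCED, M.NON_SPASTIC_OBSTRUCTION, anchored)
    t.set_cell(C.DISORDERED, E.REDUCED, M.SPASTIC_OBSTRUCTION, anchored)
    t.set_cell(C.SPASTIC, E.REDUCED, M.SPASTIC_OBSTRUCTION, anchored)
    return t


def _build_v1_table() -> DecisionTable:
    # Reconstructed v1.0 scheme; every cell is a documented consensus default.
    t = DecisionTable(version="v1.0")
    C, E, M = CRPatternV1, EGJOpening, MotilityV1
    default = "consensus-default"
    t.set_cell(C.NORMAL, E.NORMAL, M.NORMAL, default)
    t.set_cell(C.IMPAIRED_DISORDERED, E.NORMAL, M.WEAK, default)
    t.set_cell(C.ABSENT, E.NORMAL, M.WEAK, default)
    t.set_cell(C.SPASTIC_REACTIVE, E.NORMAL, M.SPASTIC_REACTIVE, default)
    t.set_cell(C.NORMAL, E.INCONCLUSIVE, M.BORDERLINE_OTHER, default)
    t.set_cell(C.IMPAIRED_DISORDERED, E.INCONCLUSIVE, M.BORDERLINE_OTHER, default)
    t.set_cell(C.ABSENT, E.INCONCLUSIVE, M.BORDERLINE_OTHER, default)
    t.set_cell(C.SPASTIC_REACTIVE, E.INCONCLUSIVE, M.SPASTIC_REACTIVE, default)
    t.set_cell(C.NORMAL, E.REDUCED, M.OBSTRUCTION_NORMAL_CR, default)
    t.set_cell(C.IMPAIRED_DISORDERED, E.REDUCED, M.OBSTRUCTION_WEAK_CR, default)
    t.set_cell(C.ABSENT, E.REDUCED, M.OBSTRUCTION_WEAK_CR, default)
    t.set_cell(C.SPASTIC_REACTIVE, E.REDUCED, M.SPASTIC_REACTIVE, default)
    return t


V2_TABLE = _build_v2_table()
V1_TABLE = _build_v1_table()


def classify_cr_v2(
    m: FlipMetrics, thresholds: ClassifierThresholds = ClassifierThresholds()
) -> CRPatternV2:
    """v2.0 contractile-response pattern with spastic-first precedence."""
    if m.sustained_occluding or m.sustained_les:
        return CRPatternV2.SPASTIC
    if m.n_qualifying_antegrade >= thresholds.normal_min_antegrade:
        return CRPatternV2.NORMAL
    if m.any_contractility:
        if m.pressure_60 <= thresholds.pressure_split:
            return CRPatternV2.DIMINISHED
        return CRPatternV2.DISORDERED
    return CRPatternV2.ABSENT


def classify_cr_v1(
    m: FlipMetrics, thresholds: ClassifierThresholds = ClassifierThresholds()
) -> CRPatternV1:
    """v1.0 contractile-response pattern (no 40-mmHg pressure split)."""
    return merge_cr_v2_to_v1(classify_cr_v2(m, thresholds))


def merge_cr_v2_to_v1(cr: CRPatternV2) -> CRPatternV1:
    """Nomenclature map v2.0 -> v1.0 (diminished+disordered merge to IDCR)."""
    return {
        CRPatternV2.NORMAL: CRPatternV1.NORMAL,
        CRPatternV2.DIMINISHED: CRPatternV1.IMPAIRED_DISORDERED,
        CRPatternV2.DISORDERED: CRPatternV1.IMPAIRED_DISORDERED,
        CRPatternV2.ABSENT: CRPatternV1.ABSENT,
        CRPatternV2.SPASTIC: CRPatternV1.SPASTIC_REACTIVE,
    }[cr]


def classify_egj_opening(
    egj_di_60: float,
    max_egj_diameter: float,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> EGJOpening:
    """EGJ opening class from EGJ-DI at 60 mL and the 60-70 mL max diameter."""
    if egj_di_60 <= 0 or max_egj_diameter <= 0:
        raise ValueError("EGJ metrics must be > 0")
    if (egj_di_60 >= thresholds.di_normal_min
            and max_egj_diameter >= thresholds.dmax_normal_min):
        return EGJOpening.NORMAL
    if (egj_di_60 < thresholds.di_reduced_max
            and max_egj_diameter < thresholds.dmax_reduced_max):
        return EGJOpening.REDUCED
    return EGJOpening.INCONCLUSIVE


def classify_motility(cr, egjo: EGJOpening, table: DecisionTable = V2_TABLE):
    """Pure decision-table lookup of the motility class."""
    return table.lookup(cr, egjo)


def classify_study_metrics(
    m: FlipMetrics,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
    table: DecisionTable = V2_TABLE,
):
    """Convenience: metrics -> (CR pattern, EGJ opening, motility class)."""
    cr = (classify_cr_v2(m, thresholds) if table.version == "v2.0"
          else classify_cr_v1(m, thresholds))
    egjo = classify_egj_opening(m.egj_di_60, m.max_egj_diameter, thresholds)
    return cr, egjo, classify_motility(cr, egjo, table)
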