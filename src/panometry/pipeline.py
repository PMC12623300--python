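"""Configuration, cohort file IO, and end-to-end pipeline orchestration.

Cohort tables are plain delimited text (comma-separated, UTF-8, header
required); reports and configurations are JSON. Each pipeline stage logs one
structured line with its input/output counts, and the full configuration is
embedded in every report for auditability.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, Field

from .adjudicate import CCv4Label, TBEStudy, Tablet, adjudicate_diagnosis
from .classify import (
    ClassifierThresholds,
    DecisionTable,
    MotilityV2,
    V1_TABLE,
    classify_motility,
    merge_cr_v2_to_v1,
)
from .cohort import calibrate_joint_from_counts, load_table2_counts, sample_cohort
from .concordance import (
    adjudicate_patients,
    build_crosstab,
    headline_report,
    predictive_values,
    primary_filter,
    version_reclassification,
)
from .features import FeatureParams

log = logging.getLogger("panometry")


class ThresholdConfig(BaseModel):
    """All classifier and detector thresholds, schema-validated."""

    pressure_split: float = Field(40.0, gt=0)
    normal_min_antegrade: int = Field(2, ge=1)
    di_normal_min: float = Field(2.0, gt=0)
    dmax_normal_min: float = Field(16.0, gt=0)
    di_reduced_max: float = Field(2.0, gt=0)
    dmax_reduced_max: float = Field(12.0, gt=0)
    rel_drop: float = Field(0.5, gt=0, lt=1)
    abs_floor_mm: float = Field(9.0, gt=0)
    occluding_diameter_mm: float = Field(2.0, gt=0)
    sustained_s: float = Field(10.0, gt=0)
    qualifying_extent_cm: float = Field(6.0, gt=0)
    qualifying_pressure_rise: float = Field(10.0, gt=0)
    egj_window_s: float = Field(10.0, gt=0)

    def classifier(self) -> ClassifierThresholds:
        return ClassifierThresholds(
            pressure_split=self.pressure_split,
            normal_min_antegrade=self.normal_min_antegrade,
            di_normal_min=self.di_normal_min,
            dmax_normal_min=self.dmax_normal_min,
            di_reduced_max=self.di_reduced_max,
            dmax_reduced_max=self.dmax_reduced_max,
        )

    def features(self) -> FeatureParams:
        return FeatureParams(
            rel_drop=self.rel_drop,
            abs_floor_mm=self.abs_floor_mm,
            occluding_diameter_mm=self.occluding_diameter_mm,
            sustained_s=self.sustained_s,
            qualifying_extent_cm=self.qualifying_extent_cm,
            qualifying_pressure_rise=self.qualifying_pressure_rise,
            egj_window_s=self.egj_window_s,
        )


class PipelineConfig(BaseModel):
    """Top-level pipeline configuration; round-trips losslessly via JSON."""

    seed: int = 0
    n_synthetic: int = 0            # 0 = fixture-only run
    thresholds: ThresholdConfig = Field(default_factory=ThresholdConfig)
    tbe_inconclusive_clause: str = "not-administered-or-passed"
    decision_table_v2_path: str | None = None
    decision_table_v1_path: str | None = None

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.model_validate_json(Path(path).read_text())

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2))


COHORT_COLUMNS = (
    "patient_id", "ccv4_label", "irp_supine", "irp_upright",
    "tbe_present", "tbe_h1", "tbe_h5", "tbe_tablet",
)


class CohortFormatError(ValueError):
    """Malformed cohort file; message names the offending rows."""


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a per-patient cohort table, validating categories row by row.

    Required columns: ``patient_id`` and ``ccv4_label``; the IRP, TBE and
    FLIP-class columns are optional. Unknown category values are rejected
    with their row numbers rather than silently dropped.
    """
    frame = pd.read_csv(path, dtype={"patient_id": str})
    missing = {"patient_id", "ccv4_label"} - set(frame.columns)
    if missing:
        raise CohortFormatError(
            f"cohort file lacks required columns: {sorted(missing)}"
        )
    problems = []
    valid_labels = {l.value for l in CCv4Label}
    valid_tablets = {t.value for t in Tablet}
    valid_flip = {m.value for m in MotilityV2}
    for i, row in frame.iterrows():
        rowno = i + 2  # header is line 1
        if row["ccv4_label"] not in valid_labels:
            problems.append(
                f"row {rowno}: unknown ccv4_label {row['ccv4_label']!r}"
            )
        if "tbe_tablet" in frame.columns and pd.notna(row.get("tbe_tablet")) \
                and row["tbe_tablet"] not in valid_tablets:
            problems.append(
                f"row {rowno}: unknown tbe_tablet {row['tbe_tablet']!r}"
            )
        if "flip_v2_class" in frame.columns \
                and pd.notna(row.get("flip_v2_class")) \
                and row["flip_v2_class"] not in valid_flip:
            problems.append(
                f"row {rowno}: unknown flip_v2_class {row['flip_v2_class']!r}"
            )
    if problems:
        raise CohortFormatError("; ".join(problems))
    return frame


def write_cohort(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False)


def adjudicate_cohort(
    frame: pd.DataFrame,
    inconclusive_clause: str = "not-administered-or-passed",
) -> pd.DataFrame:
    """Append outflow_status, conclusive and rationale columns to a cohort."""
    out = frame.copy()
    statuses, conclusives, rationales = [], [], []
    for _, row in frame.iterrows():
        if "tbe_present" in frame.columns and bool(row.get("tbe_present")):
            tbe = TBEStudy(
                present=True,
                column_height_1min=float(row.get("tbe_h1", 0.0)),
                column_height_5min=float(row.get("tbe_h5", 0.0)),
                tablet=Tablet(row["tbe_tablet"])
                if pd.notna(row.get("tbe_tablet"))
                else Tablet.NOT_ADMINISTERED,
            )
        else:
            tbe = TBEStudy.missing()
        d = adjudicate_diagnosis(CCv4Label(row["ccv4_label"]), tbe,
                                 inconclusive_clause=inconclusive_clause)
        statuses.append(d.outflow_status.value)
        conclusives.append(d.conclusive)
        rationales.append(" | ".join(d.rationale))
    out["outflow_status"] = statuses
    out["conclusive"] = conclusives
    out["rationale"] = rationales
    return out


def patients_to_frame(patients) -> pd.DataFrame:
    """Serialise synthetic patients into the standard cohort table."""
    rows = []
    for p in patients:
        rows.append({
            "patient_id": p.patient_id,
            "flip_v2_class": p.flip_class.value,
            "hrm_category": p.hrm_category,
            "ccv4_label": p.ccv4_label.value,
            "tbe_present": p.tbe.present,
            "tbe_h1": p.tbe.column_height_1min,
            "tbe_h5": p.tbe.column_height_5min,
            "tbe_tablet": p.tbe.tablet.value,
            "egj_di_60": p.metrics.egj_di_60,
            "max_egj_diameter": p.metrics.max_egj_diameter,
            "pressure_60": p.metrics.pressure_60,
            "n_qualifying_antegrade": p.metrics.n_qualifying_antegrade,
            "any_contractility": p.metrics.any_contractility,
            "sustained_occluding": p.metrics.sustained_occluding,
            "sustained_les": p.metrics.sustained_les,
            "age": p.age,
            "sex": p.sex,
        })
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Fixture analysis plus optional synthetic-cohort round trip.

    Returns a JSON-serialisable report bundle; deterministic given the seed.
    """
    report: dict = {"config": config.model_dump()}

    counts = load_table2_counts()
    log.info("stage=fixture in=%d cells out=%d patients",
             counts.size, int(counts.to_numpy().sum()))
    report["fixture"] = headline_report(counts)

    if config.n_synthetic > 0:
        spec = calibrate_joint_from_counts(counts, seed=config.seed)
        patients = sample_cohort(spec, config.n_synthetic, seed=config.seed,
                                 thresholds=config.thresholds.classifier())
        log.info("stage=sample in=%d requested out=%d patients",
                 config.n_synthetic, len(patients))
        v1_table = (V1_TABLE if config.decision_table_v1_path is None else
                    DecisionTable.read(config.decision_table_v1_path))

        def v1_of(p):
            cr1 = merge_cr_v2_to_v1(p.cr)
            return classify_motility(cr1, p.egjo, v1_table)

        records = adjudicate_patients(patients, flip_v1_of=v1_of)
        conclusive, excluded = primary_filter(records)
        log.info("stage=primary_filter in=%d out=%d excluded=%d",
                 len(records), len(conclusive), len(excluded))
        ct = build_crosstab(conclusive, "hrm", "flip_v2")
        pv = predictive_values(
            conclusive,
            positive_classes={MotilityV2.NON_SPASTIC_OBSTRUCTION},
            negative_classes={MotilityV2.NORMAL},
        )
        flow, _ = version_reclassification(records)
        report["synthetic"] = {
            "n": len(records),
            "conclusive_n": len(conclusive),
            "excluded_n": len(excluded),
            "crosstab": ct.counts.to_dict(),
            "ppv_outflow_pct": pv.ppv.percent if pv.ppv.defined else None,
            "npv_outflow_pct": pv.npv.percent if pv.npv.defined else None,
            "v1_v2_flow": flow.counts.to_dict(),
        }
    return report


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True))
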