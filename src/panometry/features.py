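"""Feature extraction from FLIP topography.

Derives the quantities the motility classification rules consume: the EGJ
distensibility index at the 60-mL fill volume (EGJ-DI, mm^2/mmHg), the
maximum EGJ diameter over the 60-70 mL steps, the bag pressure concurrent
with the 60-mL EGJ-DI window, and the contraction events detected in the
diameter topography during the 50-70 mL analysis period.

Contraction events are maximal connected spatiotemporal regions where the
diameter falls below a per-channel threshold (a relative drop from baseline
with an absolute floor, whichever is stricter). Direction is the sign of the
fitted ridge slope (channel vs time); axial extent is the channel span in cm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .topo import CHANNEL_SPACING_CM, FILL_STEPS_ML, FlipStudy


class ProtocolIncompleteError(ValueError):
    """Study lacks the fill steps the protocol requires (e.g. 60/70 mL)."""


def compute_csa(diameter):
    """Cross-sectional area (mm^2) of a circular lumen of given diameter (mm)."""
    diameter = np.asarray(diameter, dtype=float)
    if np.any(diameter <= 0):
        raise ValueError("diameter must be > 0")
    area = math.pi * (diameter / 2.0) ** 2
    return float(area) if area.ndim == 0 else area


@dataclass(frozen=True)
class ContractionEvent:
    """One detected luminal narrowing event."""

    onset_time: float
    offset_time: float
    channel_start: int
    channel_end: int          # inclusive
    axial_extent: float       # cm
    direction: str            # antegrade / retrograde / mixed
    occluding: bool
    sustained: bool
    at_egj: bool
    pressure_rise: float      # mmHg, peak minus pre-event baseline
    min_diameter: float       # mm

    def __post_init__(self):
        if self.offset_time < self.onset_time:
            raise ValueError("offset must be >= onset")
        if not 0 < self.axial_extent <= 16.0:
            raise ValueError("axial_extent must lie in (0, 16] cm")
        if not math.isfinite(self.pressure_rise):
            raise ValueError("pressure_rise must be finite")

    @property
    def duration(self) -> float:
        return self.offset_time - self.onset_time


@dataclass(frozen=True)
class FlipMetrics:
    """Scalar metrics and event flags feeding the classification rules."""

    egj_di_60: float            # mm^2/mmHg
    max_egj_diameter: float     # mm, max over 60-70 mL
    pressure_60: float          # mmHg, concurrent with the 60-mL EGJ-DI
    n_qualifying_antegrade: int
    any_contractility: bool
    sustained_occluding: bool
    sustained_les: bool
    rac_pattern: bool = False   # descriptive only; never alters classification

    def __post_init__(self):
        if self.egj_di_60 <= 0 or self.max_egj_diameter <= 0:
            raise ValueError("EGJ metrics must be > 0")
        if self.n_qualifying_antegrade < 0:
            raise ValueError("counts must be >= 0")


@dataclass(frozen=True)
class FeatureParams:
    """Detector and EGJ-window configuration (all thresholds live here)."""

    #: relative contraction threshold: fraction of the per-channel baseline
    rel_drop: float = 0.5
    #: absolute contraction floor (mm); the stricter (lower) threshold wins
    abs_floor_mm: float = 9.0
    #: minimum event-region diameter (mm) for the 'occluding' flag
    occluding_diameter_mm: float = 2.0
    #: minimum event duration (s) for the 'sustained' flag
    sustained_s: float = 10.0
    #: qualifying antegrade contraction: minimum axial extent (cm)
    qualifying_extent_cm: float = 6.0
    #: qualifying antegrade contraction: minimum pressure rise (mmHg)
    qualifying_pressure_rise: float = 10.0
    #: events closer than BOTH gaps are merged into one ('distinct' rule)
    distinct_time_gap_s: float = 2.0
    distinct_channel_gap: int = 2
    #: event analysis restricted to fill volumes >= this (mL)
    min_fill_ml: float = 50.0
    #: pre-event window (s) for the pressure-rise baseline
    pre_event_baseline_s: float = 5.0
    #: |ridge slope| below this (cm/s) is direction 'mixed'
    direction_speed_min: float = 0.25
    #: 60-mL EGJ-DI analysis window: final seconds of the 60-mL step
    egj_window_s: float = 10.0
    #: minimum antegrade count for the descriptive RAC flag
    rac_min_antegrade: int = 3


def compute_egj_metrics(
    study: FlipStudy, params: FeatureParams = FeatureParams()
) -> tuple[float, float, float]:
    """EGJ metrics: (egj_di_60, max_egj_diameter, pressure_60).

    EGJ-DI is median(narrowest EGJ CSA) / median(bag pressure) over the final
    ``egj_window_s`` seconds of the 60-mL step; the maximum EGJ diameter is
    the largest narrowest-EGJ-channel diameter over the 60- and 70-mL steps.
    """
    m60 = study.step_mask(60.0)
    m70 = study.step_mask(70.0)
    if not (m60.any() and m70.any()):
        raise ProtocolIncompleteError(
            "study lacks the 60- and/or 70-mL fill steps (technically limited)"
        )
    lo, hi = study.egj_channel_range
    narrowest = study.diameters[:, lo:hi + 1].min(axis=1)

    idx60 = np.nonzero(m60)[0]
    n_win = min(int(round(params.egj_window_s * study.sample_hz)), idx60.size)
    win = idx60[-n_win:]
    med_csa = float(np.median(compute_csa(narrowest[win])))
    pressure_60 = float(np.median(study.bag_pressure[win]))
    egj_di_60 = med_csa / pressure_60
    max_egj_diameter = float(narrowest[m60 | m70].max())
    return egj_di_60, max_egj_diameter, pressure_60


def _connected_regions(mask: np.ndarray) -> list[np.ndarray]:
    """8-connected components of a boolean (time x channel) mask.

    Returns one integer index array of flat pixel positions per component.
    """
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return []
    flat = labels.reshape(-1)
    order = np.argsort(flat, kind="stable")
    sorted_labels = flat[order]
    bounds = np.searchsorted(sorted_labels, np.arange(1, n + 2))
    return [order[bounds[i]:bounds[i + 1]] for i in range(n)]


def _merge_indistinct(
    boxes: list[tuple[float, float, int, int]],
    time_gap: float,
    channel_gap: int,
) -> list[list[int]]:
    """Union components whose bounding boxes are separated by less than the
    time gap AND less than the channel gap (i.e. not 'distinct')."""
    n = len(boxes)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            t0i, t1i, c0i, c1i = boxes[i]
            t0j, t1j, c0j, c1j = boxes[j]
            dt = max(t0j - t1i, t0i - t1j, 0.0)
            dc = max(c0j - c1i - 1, c0i - c1j - 1, 0)
            if dt < time_gap and dc < channel_gap:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return list(groups.values())


def detect_contraction_events(
    study: FlipStudy, params: FeatureParams = FeatureParams()
) -> list[ContractionEvent]:
    """Detect contraction events in the 50-70 mL analysis period.

    An empty list is a valid result (e.g. absent contractile response).
    """
    baseline = np.empty_like(study.diameters)
    for vol in FILL_STEPS_ML:
        rows = study.step_mask(vol)
        if rows.any():
            baseline[rows] = np.median(study.diameters[rows], axis=0)
    threshold = np.minimum(params.rel_drop * baseline, params.abs_floor_mm)
    mask = study.diameters < threshold
    mask[study.fill_volume < params.min_fill_ml, :] = False

    regions = _connected_regions(mask)
    if not regions:
        return []
    boxes = []
    for idx in regions:
        t_idx, ch_idx = np.unravel_index(idx, mask.shape)
        boxes.append((float(study.time[t_idx.min()]),
                      float(study.time[t_idx.max()]),
                      int(ch_idx.min()), int(ch_idx.max())))
    groups = _merge_indistinct(
        boxes, params.distinct_time_gap_s, params.distinct_channel_gap
    )

    lo, hi = study.egj_channel_range
    events = []
    for group in groups:
        idx = np.concatenate([regions[g] for g in group])
        t_idx, ch_idx = np.unravel_index(idx, mask.shape)
        onset = float(study.time[t_idx.min()])
        offset = float(study.time[t_idx.max()])
        c0, c1 = int(ch_idx.min()), int(ch_idx.max())

        # ridge slope: per-time centroid channel regressed on time
        times = study.time[t_idx]
        uniq_t, inv = np.unique(times, return_inverse=True)
        centroid = np.zeros(uniq_t.size)
        np.add.at(centroid, inv, ch_idx.astype(float))
        counts = np.bincount(inv)
        centroid /= counts
        if uniq_t.size >= 3 and np.ptp(uniq_t) > 0:
            slope = stats.linregress(uniq_t, centroid).slope  # channels/s
        else:
            slope = 0.0
        speed = slope * CHANNEL_SPACING_CM
        if speed >= params.direction_speed_min:
            direction = "antegrade"
        elif speed <= -params.direction_speed_min:
            direction = "retrograde"
        else:
            direction = "mixed"

        pre = (study.time >= onset - params.pre_event_baseline_s) & \
              (study.time < onset)
        pre_p = float(np.median(study.bag_pressure[pre])) if pre.any() \
            else float(study.bag_pressure[0])
        during = (study.time >= onset) & (study.time <= offset)
        rise = float(study.bag_pressure[during].max() - pre_p)

        min_d = float(study.diameters.reshape(-1)[idx].min())
        events.append(ContractionEvent(
            onset_time=onset, offset_time=offset,
            channel_start=c0, channel_end=c1,
            axial_extent=(c1 - c0 + 1) * CHANNEL_SPACING_CM,
            direction=direction,
            occluding=min_d <= params.occluding_diameter_mm,
            sustained=(offset - onset) >= params.sustained_s,
            at_egj=not (c1 < lo or c0 > hi),
            pressure_rise=rise,
            min_diameter=min_d,
        ))
    events.sort(key=lambda e: e.onset_time)
    return events


def extract_metrics(
    study: FlipStudy, params: FeatureParams = FeatureParams()
) -> FlipMetrics:
    """Aggregate EGJ metrics and contraction events into FlipMetrics."""
    egj_di_60, max_egj_diameter, pressure_60 = compute_egj_metrics(study, params)
    events = detect_contraction_events(study, params)
    n_qual = sum(
        1 for e in events
        if e.direction == "antegrade"
        and e.axial_extent >= params.qualifying_extent_cm
        and e.pressure_rise > params.qualifying_pressure_rise
    )
    return FlipMetrics(
        egj_di_60=egj_di_60,
        max_egj_diameter=max_egj_diameter,
        pressure_60=pressure_60,
        n_qualifying_antegrade=n_qual,
        any_contractility=len(events) > 0,
        sustained_occluding=any(
            e.sustained and e.occluding and not e.at_egj for e in events
        ),
        sustained_les=any(e.sustained and e.at_egj for e in events),
        rac_pattern=n_qual >= params.rac_min_antegrade,
    )
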