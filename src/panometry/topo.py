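"""Synthetic FLIP panometry topography.

A functional lumen imaging probe (FLIP) study records luminal diameters on a
16-channel catheter (1-cm sensor spacing) together with bag pressure while the
bag is filled in stepwise 10-mL increments from 40 to 70 mL, each volume held
for 30-60 s. This module generates studies with known ground truth: one of
five contractile-response (CR) phenotypes in the esophageal body and one of
three esophagogastric-junction (EGJ) opening phenotypes, so that downstream
feature extraction and classification can be validated by construction.

Contractions are modelled as Gaussian-in-space luminal narrowings travelling
along the channel axis, superimposed on a per-fill-step baseline diameter
profile, with a synchronous bag-pressure rise. The EGJ channels carry a
diameter trace chosen so that the 60-mL distensibility index (EGJ-DI) and the
60-70 mL maximum EGJ diameter equal the requested values.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

N_CHANNELS = 16
CHANNEL_SPACING_CM = 1.0
FILL_STEPS_ML = (40.0, 50.0, 60.0, 70.0)

CR_PHENOTYPES = ("normal", "diminished", "disordered", "absent", "spastic")
EGJ_PHENOTYPES = ("normal", "inconclusive", "reduced")

#: multiplicative depth of an injected narrowing (fraction of baseline removed)
_BAND_DEPTH = 0.95
#: spatial half-width (channels) of a travelling contraction band
_BAND_SIGMA = 0.44
#: spatial half-width (channels) of a stationary spastic band
_SPASTIC_SIGMA = 1.2


class ContradictorySpecError(ValueError):
    """Raised when a topography spec requests mutually impossible features."""


@dataclass(frozen=True)
class TopographySpec:
    """Ground-truth parameters for one simulated FLIP study.

    Parameters
    ----------
    cr_phenotype
        Contractile-response phenotype in the esophageal body; one of
        ``normal, diminished, disordered, absent, spastic``.
    egj_phenotype
        EGJ-opening phenotype; one of ``normal, inconclusive, reduced``.
    n_contractions
        Number of propagating contraction bands injected (0 for absent and
        for the default spastic study, which injects a sustained band
        instead).
    contraction_axial_extent
        Axial length (cm) each propagating band traverses.
    contraction_speed
        Signed axial velocity (cm/s); positive is antegrade
        (proximal -> distal).
    occlusion_duration
        Duration (s) of the sustained spastic band.
    pressure_60ml
        Bag pressure (mmHg) during the 60-mL fill step.
    egj_di_60
        Target EGJ distensibility index at 60 mL (mm^2/mmHg).
    max_egj_diameter
        Target maximum EGJ diameter over the 60-70 mL steps (mm).
    noise_sd
        SD (mm) of additive Gaussian diameter noise (0 = noise-free).
    seed
        Seed for the study's private random stream.
    """

    cr_phenotype: str
    egj_phenotype: str
    n_contractions: int = 0
    contraction_axial_extent: float = 8.0
    contraction_speed: float = 4.0
    occlusion_duration: float = 12.0
    pressure_60ml: float = 30.0
    egj_di_60: float = 4.0
    max_egj_diameter: float = 18.0
    contraction_pressure_rise: float = 15.0
    spastic_mode: str = "occluding"  # "occluding" (body) or "les" (at EGJ)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.cr_phenotype not in CR_PHENOTYPES:
            raise ContradictorySpecError(
                f"unknown cr_phenotype {self.cr_phenotype!r}"
            )
        if self.egj_phenotype not in EGJ_PHENOTYPES:
            raise ContradictorySpecError(
                f"unknown egj_phenotype {self.egj_phenotype!r}"
            )
        if self.n_contractions < 0:
            raise ContradictorySpecError("n_contractions must be >= 0")
        if not 0.0 < self.contraction_axial_extent <= 16.0:
            raise ContradictorySpecError(
                "contraction_axial_extent must lie in (0, 16] cm"
            )
        if self.noise_sd < 0:
            raise ContradictorySpecError("noise_sd must be >= 0")
        if self.pressure_60ml <= 0:
            raise ContradictorySpecError("pressure_60ml must be > 0")
        if self.egj_di_60 <= 0:
            raise ContradictorySpecError("egj_di_60 must be > 0")
        if self.max_egj_diameter <= 0:
            raise ContradictorySpecError("max_egj_diameter must be > 0")
        if self.spastic_mode not in ("occluding", "les"):
            raise ContradictorySpecError(
                f"unknown spastic_mode {self.spastic_mode!r}"
            )
        # cross-field contradictions
        if self.cr_phenotype == "absent" and self.n_contractions > 0:
            raise ContradictorySpecError(
                "absent contractile response contradicts n_contractions > 0"
            )
        if self.cr_phenotype == "normal":
            if self.n_contractions < 2:
                raise ContradictorySpecError(
                    "normal CR requires > 1 antegrade contraction"
                )
            if self.contraction_axial_extent < 6.0:
                raise ContradictorySpecError(
                    "normal CR requires contractions of >= 6 cm axial extent"
                )
            if self.contraction_speed <= 0:
                raise ContradictorySpecError(
                    "normal CR requires antegrade (positive-speed) bands"
                )
        if self.cr_phenotype in ("diminished", "disordered"):
            if self.n_contractions < 1:
                raise ContradictorySpecError(
                    f"{self.cr_phenotype} CR requires contractility present"
                )
            if (
                self.n_contractions >= 2
                and self.contraction_axial_extent >= 6.0
                and self.contraction_speed > 0
            ):
                raise ContradictorySpecError(
                    f"{self.cr_phenotype} CR contradicts >1 qualifying "
                    "antegrade contraction (would meet normal-CR criteria)"
                )
            if self.cr_phenotype == "diminished" and self.pressure_60ml > 40.0:
                raise ContradictorySpecError(
                    "diminished CR requires 60-mL pressure <= 40 mmHg"
                )
            if self.cr_phenotype == "disordered" and self.pressure_60ml <= 40.0:
                raise ContradictorySpecError(
                    "disordered CR requires 60-mL pressure > 40 mmHg"
                )
        # the 60-mL EGJ diameter implied by the DI must not exceed the maximum
        d60 = implied_egj_diameter_60(self.egj_di_60, self.pressure_60ml)
        if d60 > self.max_egj_diameter + 1e-9:
            raise ContradictorySpecError(
                f"egj_di_60={self.egj_di_60} at {self.pressure_60ml} mmHg "
                f"implies a 60-mL EGJ diameter of {d60:.1f} mm, exceeding "
                f"max_egj_diameter={self.max_egj_diameter} mm"
            )

    @classmethod
    def from_phenotypes(
        cls,
        cr_phenotype: str,
        egj_phenotype: str,
        seed: int = 0,
        noise_sd: float = 0.0,
        **overrides,
    ) -> "TopographySpec":
        """Build a spec with phenotype-consistent default parameters."""
        cr_defaults = {
            "normal": dict(n_contractions=3, contraction_axial_extent=8.0,
                           pressure_60ml=30.0),
            "diminished": dict(n_contractions=2, contraction_axial_extent=4.0,
                               pressure_60ml=30.0),
            "disordered": dict(n_contractions=2, contraction_axial_extent=4.0,
                               pressure_60ml=55.0),
            "absent": dict(n_contractions=0, pressure_60ml=30.0),
            "spastic": dict(n_contractions=0, pressure_60ml=45.0),
        }
        egj_defaults = {
            "normal": dict(egj_di_60=4.0, max_egj_diameter=18.0),
            "inconclusive": dict(egj_di_60=1.5, max_egj_diameter=14.0),
            "reduced": dict(egj_di_60=1.0, max_egj_diameter=9.0),
        }
        if cr_phenotype not in cr_defaults:
            raise ContradictorySpecError(f"unknown cr_phenotype {cr_phenotype!r}")
        if egj_phenotype not in egj_defaults:
            raise ContradictorySpecError(f"unknown egj_phenotype {egj_phenotype!r}")
        kwargs = dict(cr_phenotype=cr_phenotype, egj_phenotype=egj_phenotype,
                      seed=seed, noise_sd=noise_sd)
        kwargs.update(cr_defaults[cr_phenotype])
        kwargs.update(egj_defaults[egj_phenotype])
        kwargs.update(overrides)
        return cls(**kwargs)


def implied_egj_diameter_60(egj_di_60: float, pressure_60: float) -> float:
    """Narrowest EGJ diameter (mm) at 60 mL implied by a DI and pressure."""
    csa = egj_di_60 * pressure_60
    return 2.0 * math.sqrt(csa / math.pi)


@dataclass
class FlipStudy:
    """One FLIP exam: uniformly sampled time x 16-channel diameter grid.

    ``diameters`` has shape (n_samples, 16); channel 0 is most proximal,
    channel 15 most distal. ``egj_channel_range`` is the inclusive index
    interval of the channels straddling the EGJ.
    """

    time: np.ndarray            # s
    fill_volume: np.ndarray     # mL, step function over FILL_STEPS_ML
    bag_pressure: np.ndarray    # mmHg
    diameters: np.ndarray       # mm, (n_samples, N_CHANNELS)
    egj_channel_range: tuple[int, int] = (12, 14)

    @property
    def n_samples(self) -> int:
        return self.time.shape[0]

    @property
    def sample_hz(self) -> float:
        return 1.0 / float(self.time[1] - self.time[0])

    def validate(self) -> None:
        n = self.n_samples
        if self.diameters.shape != (n, N_CHANNELS):
            raise ValueError(
                f"diameters shape {self.diameters.shape} != ({n}, {N_CHANNELS})"
            )
        if self.fill_volume.shape != (n,) or self.bag_pressure.shape != (n,):
            raise ValueError("pressure/volume traces must match time length")
        if not np.all(self.diameters > 0):
            raise ValueError("all diameters must be > 0")
        if np.any(np.diff(self.fill_volume) < 0):
            raise ValueError("fill_volume must be non-decreasing")
        lo, hi = self.egj_channel_range
        if not (0 <= lo <= hi < N_CHANNELS):
            raise ValueError("egj_channel_range out of bounds")
        dt = np.diff(self.time)
        if not np.allclose(dt, dt[0]):
            raise ValueError("time must be uniformly sampled")
        for vol in np.unique(self.fill_volume):
            dwell = dt[0] * np.count_nonzero(self.fill_volume == vol)
            if not 30.0 <= dwell <= 60.0:
                raise ValueError(
                    f"dwell at {vol} mL is {dwell:.1f} s, outside 30-60 s"
                )

    def step_mask(self, volume_ml: float) -> np.ndarray:
        return self.fill_volume == volume_ml

    # -- plain-text serialisation -------------------------------------------

    def write(self, directory: str | Path) -> None:
        """Write as long-format CSV (time, channel, diameter) + JSON sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        n = self.n_samples
        frame = pd.DataFrame({
            "time": np.repeat(self.time, N_CHANNELS),
            "channel": np.tile(np.arange(N_CHANNELS), n),
            "diameter": self.diameters.reshape(-1),
        })
        frame.to_csv(directory / "topography.csv", index=False)
        sidecar = {
            "fill_volume": self.fill_volume.tolist(),
            "bag_pressure": self.bag_pressure.tolist(),
            "egj_channel_range": list(self.egj_channel_range),
        }
        (directory / "study.json").write_text(json.dumps(sidecar))

    @classmethod
    def read(cls, directory: str | Path) -> "FlipStudy":
        directory = Path(directory)
        frame = pd.read_csv(directory / "topography.csv")
        sidecar = json.loads((directory / "study.json").read_text())
        time = frame["time"].to_numpy()[::N_CHANNELS]
        diameters = frame["diameter"].to_numpy().reshape(-1, N_CHANNELS)
        return cls(
            time=time,
            fill_volume=np.asarray(sidecar["fill_volume"], dtype=float),
            bag_pressure=np.asarray(sidecar["bag_pressure"], dtype=float),
            diameters=diameters,
            egj_channel_range=tuple(sidecar["egj_channel_range"]),
        )


@dataclass(frozen=True)
class GroundTruthEvent:
    """One injected contraction band, as the simulator placed it."""

    direction: str              # antegrade / retrograde / stationary
    channel_start: int
    channel_end: int            # inclusive
    t_start: float
    t_end: float
    occluding: bool = False
    sustained: bool = False
    at_egj: bool = False

    @property
    def axial_extent_cm(self) -> float:
        return (self.channel_end - self.channel_start + 1) * CHANNEL_SPACING_CM


def _body_baseline(step_index: int) -> float:
    """Esophageal-body baseline diameter (mm) for fill step 0..3."""
    return 16.0 + 2.0 * step_index


def _inject_travelling_band(
    diameters: np.ndarray,
    time: np.ndarray,
    t0: float,
    ch_start: int,
    ch_end: int,
    speed: float,
    depth: float = _BAND_DEPTH,
    sigma: float = _BAND_SIGMA,
) -> tuple[float, float]:
    """Multiply in a travelling Gaussian narrowing; return (t0, t1)."""
    duration = abs(ch_end - ch_start) / abs(speed)
    t1 = t0 + duration
    idx = np.nonzero((time >= t0) & (time <= t1))[0]
    start = ch_start if speed > 0 else ch_end
    centers = start + speed * (time[idx] - t0)
    chans = np.arange(N_CHANNELS)
    dip = depth * np.exp(-((chans[None, :] - centers[:, None]) ** 2)
                         / (2.0 * sigma**2))
    diameters[idx] *= (1.0 - dip)
    return t0, t1


def _inject_stationary_band(
    diameters: np.ndarray,
    time: np.ndarray,
    t0: float,
    t1: float,
    center: float,
    depth: float = _BAND_DEPTH,
    sigma: float = _SPASTIC_SIGMA,
) -> None:
    idx = np.nonzero((time >= t0) & (time <= t1))[0]
    chans = np.arange(N_CHANNELS)
    dip = depth * np.exp(-((chans - center) ** 2) / (2.0 * sigma**2))
    diameters[idx] *= (1.0 - dip[None, :])


def _inject_pressure_bump(
    pressure: np.ndarray, time: np.ndarray, t0: float, t1: float, rise: float
) -> None:
    idx = np.nonzero((time >= t0) & (time <= t1))[0]
    if idx.size == 0:
        return
    phase = (time[idx] - t0) / max(t1 - t0, 1e-9)
    pressure[idx] += rise * np.sin(np.pi * phase)


def simulate_topography(
    spec: TopographySpec,
    sample_hz: float = 10.0,
    dwell_s: float = 40.0,
    egj_channel_range: tuple[int, int] = (12, 14),
) -> tuple[FlipStudy, list[GroundTruthEvent]]:
    """Simulate one FLIP study embedding the requested phenotypes.

    Returns the study and the list of injected contraction bands. Identical
    specs (including seed) yield bit-identical studies.
    """
    spec.validate()
    if not 30.0 <= dwell_s <= 60.0:
        raise ValueError("dwell_s must lie within the protocol's 30-60 s")
    n_per = int(round(dwell_s * sample_hz))
    n_total = n_per * len(FILL_STEPS_ML)
    time = np.arange(n_total) / sample_hz
    fill = np.repeat(np.asarray(FILL_STEPS_ML), n_per)

    # bag pressure: per-step plateau anchored to the 60-mL value
    step_offsets = (-10.0, -5.0, 0.0, 5.0)
    pressure = np.repeat(
        np.maximum([spec.pressure_60ml + o for o in step_offsets], 5.0), n_per
    ).astype(float)

    # baseline diameter grid
    diameters = np.empty((n_total, N_CHANNELS))
    egj_lo, egj_hi = egj_channel_range
    egj_mid = (egj_lo + egj_hi) // 2
    d60 = implied_egj_diameter_60(spec.egj_di_60, spec.pressure_60ml)
    egj_by_step = (0.85 * d60, 0.9 * d60, d60, spec.max_egj_diameter)
    for s in range(len(FILL_STEPS_ML)):
        rows = slice(s * n_per, (s + 1) * n_per)
        diameters[rows, :] = _body_baseline(s)
        diameters[rows, egj_lo:egj_hi + 1] = egj_by_step[s] + 2.0
        diameters[rows, egj_mid] = egj_by_step[s]
        diameters[rows, N_CHANNELS - 1] = 25.0  # sensor beyond the EGJ

    events: list[GroundTruthEvent] = []

    # propagating contraction bands (analysis period: 50-70 mL steps)
    extent_ch = int(round(spec.contraction_axial_extent / CHANNEL_SPACING_CM))
    body_max = egj_lo - 1
    ch_start = 2
    ch_end = ch_start + extent_ch - 1
    if spec.n_contractions > 0 and ch_end > body_max:
        raise ContradictorySpecError(
            f"extent {spec.contraction_axial_extent} cm does not fit in the "
            f"esophageal body (channels {ch_start}..{body_max})"
        )
    for k in range(spec.n_contractions):
        step = 1 + (k % 3)  # cycle 50, 60, 70 mL
        offset = 6.0 + 10.0 * (k // 3)
        t0 = step * dwell_s + offset
        t0, t1 = _inject_travelling_band(
            diameters, time, t0, ch_start, ch_end, spec.contraction_speed
        )
        _inject_pressure_bump(pressure, time, t0, t1,
                              spec.contraction_pressure_rise)
        events.append(GroundTruthEvent(
            direction="antegrade" if spec.contraction_speed > 0 else "retrograde",
            channel_start=ch_start, channel_end=ch_end,
            t_start=t0, t_end=t1,
        ))

    # spastic feature: a sustained band, occluding in the body or at the EGJ
    if spec.cr_phenotype == "spastic":
        t0 = 2 * dwell_s + 5.0  # during the 60-mL step, clear of its last 10 s
        t1 = t0 + spec.occlusion_duration
        center = 5.0 if spec.spastic_mode == "occluding" else float(egj_mid)
        _inject_stationary_band(diameters, time, t0, t1, center)
        _inject_pressure_bump(pressure, time, t0, t1,
                              spec.contraction_pressure_rise)
        events.append(GroundTruthEvent(
            direction="stationary",
            channel_start=int(math.floor(center - 1)),
            channel_end=int(math.ceil(center + 1)),
            t_start=t0, t_end=t1,
            occluding=spec.spastic_mode == "occluding",
            sustained=spec.occlusion_duration >= 10.0,
            at_egj=spec.spastic_mode == "les",
        ))

    np.clip(diameters, 0.5, None, out=diameters)
    study = FlipStudy(
        time=time, fill_volume=fill.astype(float), bag_pressure=pressure,
        diameters=diameters, egj_channel_range=egj_channel_range,
    )
    if spec.noise_sd > 0:
        study = add_noise(study, spec.noise_sd, seed=spec.seed)
    study.validate()
    return study, events


def add_noise(study: FlipStudy, noise_sd: float, seed: int) -> FlipStudy:
    """Add zero-mean Gaussian diameter noise, clipped so diameters stay > 0.

    Pressure and volume traces are untouched. ``noise_sd == 0`` returns the
    input unchanged; the same seed always produces the same output.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd == 0:
        return study
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
    noisy = study.diameters + rng.normal(0.0, noise_sd, study.diameters.shape)
    np.clip(noisy, 0.5, None, out=noisy)
    return replace(study, diameters=noisy)
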