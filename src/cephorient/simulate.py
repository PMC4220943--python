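"""Synthetic digitization cohorts with the statistical structure of a
repeated-landmarking study.

The generator emulates a study design of 20 patients, each digitized in
three independent trials on the same CBCT image by one observer.  It
composes three layers:

1. a fixed 19-landmark **skull template** expressed directly in the
   anatomical frame convention (MLWS at the origin, Na anterior on the
   midsagittal plane, Ba posteroinferior), whose 15 analysis landmarks sit
   at published per-landmark perpendicular distances from the x axis;
2. **between-patient anatomy**: a global size factor, per-landmark
   isotropic jitter, and a random rigid placement of the patient in the
   scanner (small rotation + translation);
3. **digitization noise**: independent per-landmark, per-axis Gaussian
   placement error in scanner axes, calibrated so that the expected
   absolute per-axis difference between two placements matches published
   repeat-digitization measurements (half-normal identity:
   sigma = mean_abs_diff * sqrt(pi) / 2).

All randomness flows from a single seed, so cohorts are reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np

from .errors import ValidationError
from .landmarks import (
    LANDMARK_NAMES,
    REFERENCE_LANDMARKS,
    LandmarkSet,
)

# ---------------------------------------------------------------------------
# template geometry

#: Calibration targets: perpendicular distance (mm) of each analysis
#: landmark from the anatomical x axis, from repeat-digitization reference
#: measurements on 20 adult patients.
AXIS_DISTANCE_TARGETS_MM: Dict[str, float] = {
    "Ans": 55.35, "A": 61.14, "Pns": 47.82, "Pg": 120.21, "Me": 126.63,
    "Gn": 124.70, "B": 105.81, "OrR": 47.01, "OrL": 45.90, "PoR": 50.14,
    "PoL": 54.43, "CoR": 57.98, "CoL": 58.80, "GoR": 95.37, "GoL": 95.14,
}

#: Stylized placement of each analysis landmark: (elevation angle in the
#: y-z plane, degrees below the +y axis; transverse x offset, mm).  Only
#: the axis distance above is calibrated; these angles and offsets are
#: fixed plausible adult-skull values (midsagittal landmarks at x = 0,
#: bilateral pairs mirrored in x).
_TEMPLATE_PLACEMENT: Dict[str, Tuple[float, float]] = {
    "Ans": (25.0, 0.0),
    "A":   (32.0, 0.0),
    "Pns": (72.0, 0.0),
    "Pg":  (63.0, 0.0),
    "Me":  (69.0, 0.0),
    "Gn":  (66.0, 0.0),
    "B":   (59.0, 0.0),
    "OrR": (33.0, +28.0), "OrL": (33.0, -28.0),
    "PoR": (113.0, +52.0), "PoL": (113.0, -52.0),
    "CoR": (100.0, +48.0), "CoL": (100.0, -48.0),
    "GoR": (112.0, +43.0), "GoL": (112.0, -43.0),
}

#: Reference landmarks in the anatomical frame.  The Na-S line runs
#: parallel to the y axis 2.58 mm above the origin; Ba hangs 37 mm from
#: the x axis, posteroinferior.  Built so that the frame constructed from
#: these four points is exactly the canonical frame (identity axes,
#: origin at MLWS).
_REFERENCE_TEMPLATE: Dict[str, Tuple[float, float, float]] = {
    "MLWS": (0.0, 0.0, 0.0),
    "S":    (0.0, -3.0, 2.58),
    "Na":   (0.0, 67.0, 2.58),
    "Ba":   (0.0, -25.0, -27.3),
}


def default_template() -> Dict[str, np.ndarray]:
    """The fixed 19-landmark skull template, anatomical-frame mm.

    Each analysis landmark lies at exactly its calibrated distance from
    the x axis; bilateral pairs are mirror images in the x coordinate.
    """
    template = {
        name: np.array(xyz, dtype=float)
        for name, xyz in _REFERENCE_TEMPLATE.items()
    }
    for name, (elev_deg, x_off) in _TEMPLATE_PLACEMENT.items():
        d = AXIS_DISTANCE_TARGETS_MM[name]
        th = math.radians(elev_deg)
        template[name] = np.array([x_off, d * math.cos(th), -d * math.sin(th)])
    return template


# ---------------------------------------------------------------------------
# digitization-noise calibration

#: Mean absolute per-axis coordinate difference (mm) between two
#: placements of each landmark, from the reference repeat-digitization
#: study; the generator's noise calibration input.
AXIS_LOCATING_ERROR_MM: Dict[str, Tuple[float, float, float]] = {
    "MLWS": (0.19, 0.16, 0.14),
    "Na":   (0.32, 0.20, 0.31),
    "S":    (0.39, 0.31, 0.38),
    "Ba":   (0.30, 0.33, 0.20),
    "Ans":  (0.27, 0.26, 0.24),
    "A":    (0.24, 0.20, 0.79),
    "Pns":  (0.24, 0.25, 0.31),
    "Pg":   (0.50, 0.17, 0.58),
    "Me":   (0.53, 0.17, 0.27),
    "Gn":   (0.55, 0.24, 0.44),
    "B":    (0.33, 0.14, 0.68),
    "OrR":  (0.89, 0.38, 0.23),
    "OrL":  (0.68, 0.34, 0.30),
    "PoR":  (0.61, 0.46, 0.32),
    "PoL":  (0.56, 0.50, 0.38),
    "CoR":  (0.38, 0.25, 0.14),
    "CoL":  (0.29, 0.31, 0.12),
    "GoR":  (0.46, 0.56, 0.70),
    "GoL":  (0.45, 0.45, 0.63),
}


def calibrate_axis_noise(mean_abs_diff: float) -> float:
    """Placement-noise SD sigma (mm) such that two independent
    Normal(0, sigma^2) placements have the given expected absolute
    difference on that axis.

    The difference is Normal(0, 2 sigma^2), whose absolute value is
    half-normal with mean 2 sigma / sqrt(pi); inverting gives
    sigma = mean_abs_diff * sqrt(pi) / 2.
    """
    if mean_abs_diff < 0:
        raise ValidationError("mean absolute difference must be >= 0")
    return mean_abs_diff * math.sqrt(math.pi) / 2.0


def default_locating_noise() -> Dict[str, np.ndarray]:
    """Per-landmark per-axis placement-noise SDs (mm) calibrated to the
    reference locating-error table."""
    return {
        name: np.array([calibrate_axis_noise(m) for m in means])
        for name, means in AXIS_LOCATING_ERROR_MM.items()
    }


# ---------------------------------------------------------------------------
# cohort generation


@dataclass
class CohortConfig:
    """Study-design and noise parameters of a synthetic cohort.

    Defaults reproduce the reference study conditions: 20 patients, three
    digitization trials each, noise calibrated per landmark and axis.
    Between-patient anatomy (3% size SD, 2 mm landmark jitter) and scanner
    placement (5 degree / 10 mm SDs) are fixed plausible values.
    """

    n_patients: int = 20
    n_trials: int = 3
    seed: int = 0
    template: Optional[Dict[str, np.ndarray]] = None
    patient_scale_sd: float = 0.03        # fractional size variation
    patient_jitter_sd_mm: float = 2.0     # per-landmark anatomical jitter
    rotation_sd_deg: float = 5.0          # scanner placement, per axis
    translation_sd_mm: float = 10.0       # scanner placement, per axis
    locating_noise: Optional[Dict[str, np.ndarray]] = None  # per-axis SDs
    noise_scale: float = 1.0              # global multiplier on placement noise

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        if self.n_trials < 1:
            raise ValidationError("n_trials must be >= 1")
        for name, val in (
            ("patient_scale_sd", self.patient_scale_sd),
            ("patient_jitter_sd_mm", self.patient_jitter_sd_mm),
            ("rotation_sd_deg", self.rotation_sd_deg),
            ("translation_sd_mm", self.translation_sd_mm),
            ("noise_scale", self.noise_scale),
        ):
            if val < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.template is None:
            self.template = default_template()
        missing = [n for n in LANDMARK_NAMES if n not in self.template]
        if missing:
            raise ValidationError(f"template lacks landmark(s) {missing}")
        if self.locating_noise is None:
            self.locating_noise = default_locating_noise()

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        known = {k: d[k] for k in d if k in cls.__dataclass_fields__}
        unknown = set(d) - set(known)
        if unknown:
            raise ValidationError(f"unknown cohort config key(s) {sorted(unknown)}")
        return cls(**known)


@dataclass
class SyntheticCohort:
    """Generated cohort: per-patient true geometry plus noisy trials."""

    config: CohortConfig
    truths: Dict[str, LandmarkSet]
    trials: List[LandmarkSet]

    def trials_of(self, patient_id: str) -> List[LandmarkSet]:
        return [t for t in self.trials if t.patient_id == patient_id]


def _small_rotation(angles_rad: np.ndarray) -> np.ndarray:
    """Rotation matrix from intrinsic x, y, z rotations (applied in that
    order): R = Rz @ Ry @ Rx."""
    ax, ay, az = angles_rad
    cx, sx = math.cos(ax), math.sin(ax)
    cy, sy = math.cos(ay), math.sin(ay)
    cz, sz = math.cos(az), math.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a cohort deterministically from ``config.seed``.

    Each patient's true geometry is the template scaled by a global size
    factor, jittered per landmark, then rigidly placed in the scanner;
    each trial adds independent per-landmark per-axis placement noise in
    scanner axes (where a digitizer's error arises).
    """
    rng = np.random.default_rng(config.seed)
    template = config.template
    noise = config.locating_noise

    truths: Dict[str, LandmarkSet] = {}
    trials: List[LandmarkSet] = []
    width = max(2, len(str(config.n_patients)))
    for i in range(config.n_patients):
        pid = f"P{i + 1:0{width}d}"
        scale = 1.0 + rng.normal(0.0, config.patient_scale_sd)
        jitter = {
            name: rng.normal(0.0, config.patient_jitter_sd_mm, size=3)
            for name in LANDMARK_NAMES
        }
        rot = _small_rotation(np.radians(
            rng.normal(0.0, config.rotation_sd_deg, size=3)))
        trans = rng.normal(0.0, config.translation_sd_mm, size=3)
        truth_points = {
            name: rot @ (scale * template[name] + jitter[name]) + trans
            for name in LANDMARK_NAMES
        }
        truths[pid] = LandmarkSet(pid, "truth", truth_points)
        for k in range(config.n_trials):
            trial_points = {
                name: truth_points[name]
                + config.noise_scale * noise[name] * rng.normal(size=3)
                for name in LANDMARK_NAMES
            }
            trials.append(LandmarkSet(pid, f"T{k + 1}", trial_points))
    return SyntheticCohort(config=config, truths=truths, trials=trials)
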