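"""Per-landmark reproducibility and superimposition-error statistics.

All statistics are defined on a :class:`TrialPair` — two digitization
trials of the same patient on the same image:

* **locating error** (Db): Euclidean distance between the two placements of
  a landmark in scanner coordinates, plus the per-axis absolute
  differences;
* **reorientation error** (Y): distance between the two placements after
  each trial has been reoriented by the frame built from its *own*
  reference landmarks — the error the superimposition procedure itself
  introduces on top of Db;
* **DX**: perpendicular distance of the pair-averaged landmark from the
  reoriented x axis (frame built from pair-averaged reference landmarks);
* **A3r**: sum of the three angles, at the averaged landmark, subtended by
  the two placements of each reference point Na, S and Ba (degrees) — how
  far the reference configuration shifted as seen from that landmark.

ICC(3,1) reproducibility per coordinate and the per-landmark summary
tables (mean, SD, quartiles) complete the module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import (
    DegenerateAngleError,
    InsufficientDataError,
    MissingLandmarkError,
)
from .geometry import (
    DEGENERACY_TOL_MM,
    build_reference_frame,
    distance_from_x_axis,
    reorient,
)
from .landmarks import (
    REFERENCE_LANDMARKS,
    LandmarkSet,
    group_by_patient,
)

#: Columns of the error-record CSV interchange format.
RECORD_CSV_COLUMNS = [
    "patient_id", "pair", "landmark",
    "Db_mm", "dxerr_mm", "dyerr_mm", "dzerr_mm",
    "Y_mm", "DX_mm", "A3r_deg", "DY_mm", "DZ_mm", "D0_mm",
]


@dataclass(frozen=True)
class TrialPair:
    """Two digitization trials of the same patient on the same image."""

    patient_id: str
    trial_a: LandmarkSet
    trial_b: LandmarkSet
    pair_label: str

    def __post_init__(self) -> None:
        if self.trial_a.patient_id != self.trial_b.patient_id:
            raise ValueError(
                f"pair {self.pair_label}: trials belong to different patients"
            )

    @classmethod
    def from_trials(cls, a: LandmarkSet, b: LandmarkSet) -> "TrialPair":
        return cls(a.patient_id, a, b, f"{a.trial_id}-{b.trial_id}")


@dataclass
class ErrorRecord:
    """One regression observation: all error statistics for one
    (patient, trial pair, landmark)."""

    patient_id: str
    pair: str
    landmark: str
    db_mm: float
    dxerr_mm: float
    dyerr_mm: float
    dzerr_mm: float
    y_mm: float
    dx_axis_mm: float      # DX: distance of the averaged landmark from the x axis
    a3r_deg: float         # NaN for the four reference landmarks
    avg_reoriented: Optional[np.ndarray] = None  # averaged landmark in the averaged frame

    @property
    def dy_axis_mm(self) -> float:
        """Distance of the averaged reoriented landmark from the y axis."""
        c = self.avg_reoriented
        return float(np.hypot(c[0], c[2])) if c is not None else float("nan")

    @property
    def dz_axis_mm(self) -> float:
        """Distance of the averaged reoriented landmark from the z axis."""
        c = self.avg_reoriented
        return float(np.hypot(c[0], c[1])) if c is not None else float("nan")

    @property
    def d0_mm(self) -> float:
        """Distance of the averaged reoriented landmark from the origin."""
        c = self.avg_reoriented
        return float(np.linalg.norm(c)) if c is not None else float("nan")


# ---------------------------------------------------------------------------
# pairwise operations


def locating_error(pair: TrialPair, landmark: str) -> Tuple[float, float, float, float]:
    """Per-axis absolute coordinate differences and the Euclidean distance
    Db between the two placements, in scanner coordinates."""
    a = pair.trial_a[landmark]
    b = pair.trial_b[landmark]
    d = np.abs(a - b)
    return float(d[0]), float(d[1]), float(d[2]), float(np.linalg.norm(a - b))


def reorientation_error(pair: TrialPair, landmark: str) -> float:
    """Distance Y between the two reoriented placements of ``landmark``,
    each trial reoriented by the frame built from its own reference
    landmarks."""
    frame_a = build_reference_frame(pair.trial_a)
    frame_b = build_reference_frame(pair.trial_b)
    ra = frame_a.rotation @ (pair.trial_a[landmark] - frame_a.origin)
    rb = frame_b.rotation @ (pair.trial_b[landmark] - frame_b.origin)
    return float(np.linalg.norm(ra - rb))


def _angle_at(apex: np.ndarray, p: np.ndarray, q: np.ndarray) -> float:
    """Angle (radians) at ``apex`` between directions to p and q, via the
    clamped arccosine of the normalized dot product."""
    u = p - apex
    v = q - apex
    nu = float(np.linalg.norm(u))
    nv = float(np.linalg.norm(v))
    if nu < DEGENERACY_TOL_MM or nv < DEGENERACY_TOL_MM:
        raise DegenerateAngleError(
            "reference placement coincides with the averaged landmark"
        )
    c = float(u @ v) / (nu * nv)
    return math.acos(min(1.0, max(-1.0, c)))


def a3r(pair: TrialPair, landmark: str) -> float:
    """Sum of the angle errors of Na, S and Ba viewed from the averaged
    landmark, in degrees.

    The averaged landmark is the midpoint of the two placements in scanner
    coordinates; for each reference point the angle is subtended at that
    midpoint by the point's two placements.
    """
    a_bar = 0.5 * (pair.trial_a[landmark] + pair.trial_b[landmark])
    total = 0.0
    for ref in ("Na", "S", "Ba"):
        total += _angle_at(a_bar, pair.trial_a[ref], pair.trial_b[ref])
    return math.degrees(total)


def _averaged_reference_frame(pair: TrialPair):
    """Frame built from the midpoints of the four reference landmarks."""
    pair.trial_a.require_reference_landmarks()
    pair.trial_b.require_reference_landmarks()
    avg_points = {
        n: 0.5 * (pair.trial_a[n] + pair.trial_b[n]) for n in REFERENCE_LANDMARKS
    }
    avg_trial = LandmarkSet(pair.patient_id, pair.pair_label, avg_points)
    return build_reference_frame(avg_trial)


def averaged_reoriented_landmark(pair: TrialPair, landmark: str) -> np.ndarray:
    """Pair-averaged landmark expressed in the pair-averaged frame."""
    frame = _averaged_reference_frame(pair)
    a_bar = 0.5 * (pair.trial_a[landmark] + pair.trial_b[landmark])
    return frame.rotation @ (a_bar - frame.origin)


def dx_metric(pair: TrialPair, landmark: str) -> float:
    """DX: perpendicular distance (mm) of the pair-averaged landmark from
    the reoriented x axis of the pair-averaged frame."""
    return distance_from_x_axis(averaged_reoriented_landmark(pair, landmark))


# ---------------------------------------------------------------------------
# cohort drivers


def iter_pairs(trials: Iterable[LandmarkSet]) -> List[TrialPair]:
    """All within-patient trial pairs, ordered by trial id (T1-T2, T1-T3,
    T2-T3 for a three-trial design)."""
    pairs = []
    for pid, ts in sorted(group_by_patient(trials).items()):
        for i in range(len(ts)):
            for j in range(i + 1, len(ts)):
                pairs.append(TrialPair.from_trials(ts[i], ts[j]))
    return pairs


def pair_records(pair: TrialPair, landmarks: Optional[Sequence[str]] = None) -> List[ErrorRecord]:
    """Compute every error statistic for one pair.

    A3r is reported only for non-reference landmarks (viewed from a
    reference point's own average the subtended angles are ill-defined);
    reference landmarks carry NaN.
    """
    if landmarks is None:
        landmarks = [n for n in pair.trial_a.landmark_names if n in pair.trial_b]
    frame_avg = _averaged_reference_frame(pair)
    rot, origin = frame_avg.rotation, frame_avg.origin
    records = []
    for name in landmarks:
        dx_e, dy_e, dz_e, db = locating_error(pair, name)
        y = reorientation_error(pair, name)
        a_bar = 0.5 * (pair.trial_a[name] + pair.trial_b[name])
        avg_reor = rot @ (a_bar - origin)
        angle = a3r(pair, name) if name not in REFERENCE_LANDMARKS else float("nan")
        records.append(ErrorRecord(
            patient_id=pair.patient_id,
            pair=pair.pair_label,
            landmark=name,
            db_mm=db, dxerr_mm=dx_e, dyerr_mm=dy_e, dzerr_mm=dz_e,
            y_mm=y,
            dx_axis_mm=distance_from_x_axis(avg_reor),
            a3r_deg=angle,
            avg_reoriented=avg_reor,
        ))
    return records


def compute_error_records(trials: Iterable[LandmarkSet]) -> List[ErrorRecord]:
    """Error records for every within-patient pair and landmark."""
    records: List[ErrorRecord] = []
    for pair in iter_pairs(trials):
        records.extend(pair_records(pair))
    return records


def records_to_frame(records: Iterable[ErrorRecord]) -> pd.DataFrame:
    rows = [
        (r.patient_id, r.pair, r.landmark, r.db_mm, r.dxerr_mm, r.dyerr_mm,
         r.dzerr_mm, r.y_mm, r.dx_axis_mm, r.a3r_deg,
         r.dy_axis_mm, r.dz_axis_mm, r.d0_mm)
        for r in records
    ]
    return pd.DataFrame(rows, columns=RECORD_CSV_COLUMNS)


# ---------------------------------------------------------------------------
# reproducibility (ICC) and summary tables


def icc_per_coordinate(trials: Iterable[LandmarkSet]) -> pd.DataFrame:
    """ICC(3,1) — two-way mixed effects, single rater, consistency — per
    (landmark, axis), with patients as targets and trials as raters.

    Returns a data frame with columns ``landmark``, ``axis``, ``icc``.
    """
    import pingouin as pg

    trials = list(trials)
    by_patient = group_by_patient(trials)
    n_trials = {len(ts) for ts in by_patient.values()}
    if len(by_patient) < 2 or max(n_trials, default=0) < 2:
        raise InsufficientDataError(
            "ICC needs at least 2 patients and 2 trials per patient"
        )

    long_rows = []
    for t in trials:
        for name, p in t.points.items():
            for ax, val in zip("xyz", p):
                long_rows.append((t.patient_id, t.trial_id, name, ax, val))
    long = pd.DataFrame(
        long_rows, columns=["patient_id", "trial_id", "landmark", "axis", "value"]
    )

    out = []
    for (name, ax), grp in long.groupby(["landmark", "axis"], sort=True):
        res = pg.intraclass_corr(
            data=grp, targets="patient_id", raters="trial_id",
            ratings="value", nan_policy="omit",
        )
        # two-way mixed, single rater, consistency: labelled ICC3 or
        # ICC(C,1) depending on the pingouin version
        mask = res["Type"].isin(["ICC3", "ICC(C,1)"])
        icc3 = float(res.loc[mask, "ICC"].iloc[0])
        out.append((name, ax, icc3))
    table = pd.DataFrame(out, columns=["landmark", "axis", "icc"])
    # keep the anatomical landmark order of the vocabulary
    order = {n: i for i, n in enumerate(
        dict.fromkeys([t for tr in trials for t in tr.landmark_names]))}
    return table.sort_values(
        by=["landmark", "axis"],
        key=lambda s: s.map(order) if s.name == "landmark" else s,
        kind="stable",
    ).reset_index(drop=True)


def _summary_stats(values: np.ndarray) -> Tuple[float, float, float, float]:
    """mean, sample SD (n-1; NaN for a single value), and inclusive
    linearly interpolated Q1/Q3."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        return (float("nan"),) * 4
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if values.size > 1 else float("nan")
    q1, q3 = np.percentile(values, [25, 75])  # inclusive linear interpolation
    return mean, sd, float(q1), float(q3)


def summarize_records(records: Iterable[ErrorRecord]) -> pd.DataFrame:
    """Per-landmark summary of the error statistics.

    Columns mirror the reorientation-error table layout: reorientation
    error Y and locating error Db with mean/SD/Q1/Q3, DX and A3r with
    mean/SD.
    """
    df = records_to_frame(records)
    if df.empty:
        raise InsufficientDataError("no error records to summarize")
    rows = []
    seen = list(dict.fromkeys(df["landmark"]))
    for name in seen:
        sub = df[df["landmark"] == name]
        y = _summary_stats(sub["Y_mm"].to_numpy())
        db = _summary_stats(sub["Db_mm"].to_numpy())
        dx = _summary_stats(sub["DX_mm"].to_numpy())
        a = _summary_stats(sub["A3r_deg"].to_numpy())
        rows.append((name, *y, *db, dx[0], dx[1], a[0], a[1]))
    return pd.DataFrame(rows, columns=[
        "landmark",
        "Y_mean", "Y_sd", "Y_q1", "Y_q3",
        "Db_mean", "Db_sd", "Db_q1", "Db_q3",
        "DX_mean", "DX_sd", "A3r_mean", "A3r_sd",
    ])


def summarize_axis_errors(records: Iterable[ErrorRecord]) -> pd.DataFrame:
    """Per-landmark mean(SD) of the per-axis locating errors (the
    coordinate locating-error table)."""
    df = records_to_frame(records)
    if df.empty:
        raise InsufficientDataError("no error records to summarize")
    rows = []
    for name in dict.fromkeys(df["landmark"]):
        sub = df[df["landmark"] == name]
        row = [name]
        for col in ("dxerr_mm", "dyerr_mm", "dzerr_mm"):
            m, sd, _, _ = _summary_stats(sub[col].to_numpy())
            row.extend([m, sd])
        rows.append(tuple(row))
    return pd.DataFrame(rows, columns=[
        "landmark", "x_mean", "x_sd", "y_mean", "y_sd", "z_mean", "z_sd",
    ])
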