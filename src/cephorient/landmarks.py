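"""Landmark vocabulary, the :class:`LandmarkSet` container and CSV I/O.

A *digitization trial* is one complete manual placement of the 19
cephalometric landmarks on a patient's CBCT volume.  Coordinates are in
millimetres in the scanner coordinate system.  Four landmarks — MLWS (the
midpoint between the most posterior points of the lesser wings of the
sphenoid), nasion (Na), sella (S) and basion (Ba) — serve as the reference
set from which the anatomical frame is built; the remaining 15 are the
commonly used orthodontic landmarks whose reorientation error is analysed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Sequence

import numpy as np
import pandas as pd

from .errors import MissingLandmarkError, ValidationError

#: Landmarks that define the reference frame (origin + axes).
REFERENCE_LANDMARKS: tuple = ("MLWS", "Na", "S", "Ba")

#: The 15 orthodontic landmarks analysed for reorientation error.
ANALYSIS_LANDMARKS: tuple = (
    "Ans", "A", "Pns", "Pg", "Me", "Gn", "B",
    "OrR", "OrL", "PoR", "PoL", "CoR", "CoL", "GoR", "GoL",
)

#: Full 19-landmark vocabulary.
LANDMARK_NAMES: tuple = REFERENCE_LANDMARKS + ANALYSIS_LANDMARKS

#: Columns of the landmark-table CSV interchange format.
CSV_COLUMNS = ["patient_id", "trial_id", "landmark", "x_mm", "y_mm", "z_mm"]


@dataclass
class LandmarkSet:
    """One digitization trial: named 3D points for one patient.

    Parameters
    ----------
    patient_id, trial_id
        Identifiers; trials of the same patient digitize the same image.
    points
        Mapping landmark name -> (3,) float array, millimetres, scanner
        coordinates.  All coordinates must be finite.
    """

    patient_id: str
    trial_id: str
    points: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: Dict[str, np.ndarray] = {}
        for name, p in self.points.items():
            arr = np.asarray(p, dtype=float)
            if arr.shape != (3,):
                raise ValidationError(
                    f"landmark {name!r} of {self.patient_id}/{self.trial_id}: "
                    f"expected a 3-vector, got shape {arr.shape}"
                )
            if not np.all(np.isfinite(arr)):
                raise ValidationError(
                    f"landmark {name!r} of {self.patient_id}/{self.trial_id}: "
                    "non-finite coordinates"
                )
            clean[name] = arr
        self.points = clean

    def __contains__(self, name: str) -> bool:
        return name in self.points

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.points[name]
        except KeyError:
            raise MissingLandmarkError(
                f"landmark {name!r} absent from trial "
                f"{self.patient_id}/{self.trial_id}"
            ) from None

    @property
    def landmark_names(self) -> List[str]:
        return list(self.points)

    def has_reference_landmarks(self) -> bool:
        """True when all four frame-defining landmarks are present."""
        return all(name in self.points for name in REFERENCE_LANDMARKS)

    def require_reference_landmarks(self) -> None:
        missing = [n for n in REFERENCE_LANDMARKS if n not in self.points]
        if missing:
            raise MissingLandmarkError(
                f"trial {self.patient_id}/{self.trial_id} lacks reference "
                f"landmark(s) {missing}"
            )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "LandmarkSet":
        """Return a copy with every point mapped to R @ p + t."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        return LandmarkSet(
            self.patient_id,
            self.trial_id,
            {n: rotation @ p + translation for n, p in self.points.items()},
        )


def trials_to_frame(trials: Iterable[LandmarkSet]) -> pd.DataFrame:
    """Flatten trials into the landmark-table layout (one row per point)."""
    rows = []
    for t in trials:
        for name, p in t.points.items():
            rows.append((t.patient_id, t.trial_id, name, p[0], p[1], p[2]))
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def frame_to_trials(table: pd.DataFrame) -> List[LandmarkSet]:
    """Group a landmark table back into :class:`LandmarkSet` objects.

    Trials are returned sorted by (patient_id, trial_id) for deterministic
    downstream pairing.
    """
    missing = [c for c in CSV_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"landmark table lacks column(s) {missing}")
    trials = []
    for (pid, tid), grp in table.groupby(["patient_id", "trial_id"], sort=True):
        dup = grp["landmark"].duplicated()
        if dup.any():
            raise ValidationError(
                f"duplicate landmark rows for {pid}/{tid}: "
                f"{sorted(grp.loc[dup, 'landmark'])}"
            )
        points = {
            r.landmark: np.array([r.x_mm, r.y_mm, r.z_mm])
            for r in grp.itertuples()
        }
        trials.append(LandmarkSet(str(pid), str(tid), points))
    return trials


def read_landmark_csv(path: str | Path) -> List[LandmarkSet]:
    """Read a landmark table CSV (UTF-8, '.' decimal separator)."""
    table = pd.read_csv(path, dtype={"patient_id": str, "trial_id": str})
    return frame_to_trials(table)


def write_landmark_csv(trials: Sequence[LandmarkSet], path: str | Path) -> None:
    trials_to_frame(trials).to_csv(path, index=False)


def group_by_patient(trials: Iterable[LandmarkSet]) -> Dict[str, List[LandmarkSet]]:
    """Patient id -> trials sorted by trial id."""
    out: Dict[str, List[LandmarkSet]] = {}
    for t in trials:
        out.setdefault(t.patient_id, []).append(t)
    for pid in out:
        out[pid].sort(key=lambda t: t.trial_id)
    return out
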