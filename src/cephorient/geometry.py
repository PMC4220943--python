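"""Construction of the 4-point anatomical reference frame and rigid
reorientation of landmark sets into it.

The frame is defined from four cranial-base landmarks:

* the **y axis** (anteroposterior, positive anterior) is parallel to the
  line through nasion (Na) and sella (S), oriented from S toward Na;
* the **z axis** (vertical, positive superior) is parallel to the
  perpendicular dropped from basion (Ba) onto the Na-S line, oriented from
  Ba toward that line;
* the **x axis** (transverse) completes the right-handed system,
  x = y × z;
* the **origin** is MLWS, the midpoint between the most posterior points of
  the bilateral lesser wings of the sphenoid.

Reorientation expresses every landmark in this frame; because the map is a
rigid motion, all inter-landmark distances are preserved and the origin
landmark maps exactly to the zero vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateFrameError
from .landmarks import LandmarkSet

#: Below this length (mm) a direction is considered undefined.  Far below
#: digitization noise (~0.3 mm) yet far above double-precision rounding.
DEGENERACY_TOL_MM = 1e-6


@dataclass(frozen=True)
class ReferenceFrame:
    """Origin plus right-handed orthonormal axes, in scanner coordinates."""

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    @property
    def rotation(self) -> np.ndarray:
        """3x3 matrix whose rows are the axes; maps scanner-frame offsets
        to reoriented coordinates."""
        return np.vstack([self.x_axis, self.y_axis, self.z_axis])

    def validate(self, tol: float = 1e-9) -> None:
        """Check unit norms, pairwise orthogonality and right-handedness."""
        for name, ax in (("x", self.x_axis), ("y", self.y_axis), ("z", self.z_axis)):
            if abs(np.linalg.norm(ax) - 1.0) > tol:
                raise DegenerateFrameError(f"{name} axis is not unit length")
        for a, b in ((self.x_axis, self.y_axis),
                     (self.y_axis, self.z_axis),
                     (self.x_axis, self.z_axis)):
            if abs(float(a @ b)) > tol:
                raise DegenerateFrameError("axes are not orthogonal")
        if np.max(np.abs(np.cross(self.y_axis, self.z_axis) - self.x_axis)) > tol:
            raise DegenerateFrameError("axes are not right-handed")


def build_reference_frame(trial: LandmarkSet) -> ReferenceFrame:
    """Build the anatomical frame from a trial's MLWS, Na, S and Ba.

    Raises
    ------
    MissingLandmarkError
        If any of the four reference landmarks is absent.
    DegenerateFrameError
        If Na coincides with S, or Ba lies on the Na-S line (within
        :data:`DEGENERACY_TOL_MM`).
    """
    trial.require_reference_landmarks()
    mlws, na, s, ba = (trial[n] for n in ("MLWS", "Na", "S", "Ba"))

    ns = na - s
    ns_len = float(np.linalg.norm(ns))
    if ns_len < DEGENERACY_TOL_MM:
        raise DegenerateFrameError(
            f"Na and S coincide in trial {trial.patient_id}/{trial.trial_id}"
        )
    y_axis = ns / ns_len

    # Perpendicular foot of Ba on the Na-S line; z points from Ba up to it.
    foot = s + float((ba - s) @ y_axis) * y_axis
    up = foot - ba
    up_len = float(np.linalg.norm(up))
    if up_len < DEGENERACY_TOL_MM:
        raise DegenerateFrameError(
            f"Ba lies on the Na-S line in trial {trial.patient_id}/{trial.trial_id}"
        )
    z_axis = up / up_len
    x_axis = np.cross(y_axis, z_axis)
    return ReferenceFrame(origin=mlws, x_axis=x_axis, y_axis=y_axis, z_axis=z_axis)


def reorient(trial: LandmarkSet, frame: ReferenceFrame) -> LandmarkSet:
    """Express every landmark of ``trial`` in ``frame`` coordinates.

    Each point P maps to ((P-o)·x, (P-o)·y, (P-o)·z).  Landmarks absent
    from the input are absent from the output.  The returned object reuses
    the :class:`LandmarkSet` container; its coordinates are in the
    reoriented anatomical frame, not scanner coordinates.
    """
    rot = frame.rotation
    coords = {name: rot @ (p - frame.origin) for name, p in trial.points.items()}
    return LandmarkSet(trial.patient_id, trial.trial_id, coords)


def reorient_in_own_frame(trial: LandmarkSet) -> LandmarkSet:
    """Reorient a trial with the frame built from its own reference
    landmarks (the operation applied to each digitization trial)."""
    return reorient(trial, build_reference_frame(trial))


def distance_from_x_axis(coords: np.ndarray) -> float:
    """Perpendicular distance (mm) of a reoriented point from the x axis:
    sqrt(y^2 + z^2)."""
    coords = np.asarray(coords, dtype=float)
    return float(np.hypot(coords[1], coords[2]))
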