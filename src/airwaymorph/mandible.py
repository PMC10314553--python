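"""Mandibular kinematics between two timepoints.

B-point displacement is read off directly in the oriented frame (+Y anterior,
+Z superior).  "Pitch" rotations of the ramus (Co→Go) and anterior body
(Co→B) lines are signed angles between their projections onto the
midsagittal YZ plane: positive = counterclockwise seen from the patient's
right (anterior end rotating superiorly), negative = clockwise — the pattern
a bite-opening mandibular advancement device produces.
"""
from __future__ import annotations

import numpy as np

from .errors import DegenerateGeometryError
from .model import LandmarkSet, MandibleChange, MANDIBLE_LANDMARKS

_DEGENERATE_TOL = 1e-9


def b_point_displacement(lm_t0: LandmarkSet, lm_t1: LandmarkSet) -> tuple[float, float]:
    """Anteroposterior and superoinferior B-point displacement (mm).

    Returns ``(delta_ap, delta_si)`` with + anterior / + superior; both sets
    must be expressed in the oriented common frame.
    """
    lm_t0.require(("B",), "B-point displacement")
    lm_t1.require(("B",), "B-point displacement")
    d = lm_t1["B"] - lm_t0["B"]
    return float(d[1]), float(d[2])


def _sagittal_angle(p: np.ndarray, q: np.ndarray) -> float:
    """Orientation angle (radians) of the directed line p→q projected on YZ."""
    v = q - p
    vy, vz = v[1], v[2]
    if vy * vy + vz * vz < _DEGENERATE_TOL ** 2:
        raise DegenerateGeometryError(
            "line is parallel to the left-right axis; its sagittal projection is degenerate")
    return float(np.arctan2(vz, vy))


def line_pitch_rotation(p_t0, q_t0, p_t1, q_t1) -> float:
    """Signed pitch rotation (degrees) of the directed line p→q from T0 to T1.

    The angle difference of the sagittal-plane projections, wrapped to
    (−180, 180].  Pure yaw or roll of a line leaves its projection angle
    unchanged only in special configurations; for the mandibular lines used
    here the projection is the standard pitch reading.
    """
    p_t0, q_t0, p_t1, q_t1 = (np.asarray(x, dtype=float) for x in (p_t0, q_t0, p_t1, q_t1))
    theta0 = _sagittal_angle(p_t0, q_t0)
    theta1 = _sagittal_angle(p_t1, q_t1)
    d = np.degrees(theta1 - theta0)
    d = (d + 180.0) % 360.0 - 180.0
    if d == -180.0:
        d = 180.0
    return float(d)


def measure_mandible(lm_t0: LandmarkSet, lm_t1: LandmarkSet,
                     patient_id: str | None = None) -> MandibleChange:
    """Full mandibular change: B-point displacement and per-side pitches.

    Ramus pitch from Co→Go, anterior pitch from Co→B, each side separately;
    left/right means are exposed on the returned :class:`MandibleChange`.
    """
    for lm, tag in ((lm_t0, "T0"), (lm_t1, "T1")):
        lm.require(MANDIBLE_LANDMARKS, f"mandible kinematics ({tag})")
    delta_ap, delta_si = b_point_displacement(lm_t0, lm_t1)
    return MandibleChange(
        patient_id=patient_id if patient_id is not None else lm_t0.patient_id,
        delta_ap=delta_ap,
        delta_si=delta_si,
        ramus_pitch_R=line_pitch_rotation(lm_t0["CoR"], lm_t0["GoR"],
                                          lm_t1["CoR"], lm_t1["GoR"]),
        ramus_pitch_L=line_pitch_rotation(lm_t0["CoL"], lm_t0["GoL"],
                                          lm_t1["CoL"], lm_t1["GoL"]),
        anterior_pitch_R=line_pitch_rotation(lm_t0["CoR"], lm_t0["B"],
                                             lm_t1["CoR"], lm_t1["B"]),
        anterior_pitch_L=line_pitch_rotation(lm_t0["CoL"], lm_t0["B"],
                                             lm_t1["CoL"], lm_t1["B"]),
    )
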