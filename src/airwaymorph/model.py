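"""Core geometric data model.

All geometry lives in a single internal world convention: RAS millimetres
(+X patient-right, +Y anterior, +Z superior).  File readers convert on load,
so every downstream sign rule (anterior displacement positive, superior
positive, pitch about +X) is stated once, here.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

from .errors import DegenerateGeometryError, MissingLandmarkError, ValidationError

#: Landmarks required to delimit the oropharynx regions.
AIRWAY_LANDMARKS = ("Ba", "PNS", "C2I", "C4S")
#: Landmarks required for mandibular kinematics.
MANDIBLE_LANDMARKS = ("CoR", "CoL", "GoR", "GoL", "B")
#: Landmarks required to build the oriented head frame.
ORIENTATION_LANDMARKS = ("PoR", "PoL", "OrR", "OrL")

ORTHONORMALITY_TOL = 1e-8


def _as_vec3(x) -> np.ndarray:
    v = np.asarray(x, dtype=float).reshape(3)
    if not np.all(np.isfinite(v)):
        raise ValidationError(f"non-finite 3-vector: {x!r}")
    return v


@dataclass(frozen=True)
class RigidTransform:
    """A 6-DOF rotation + translation, ``y = R x + t``, in mm.

    The rotation must be a proper rotation (orthonormal, det +1); reflections
    and scalings are rejected on construction.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = _as_vec3(self.translation)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
            raise ValidationError("rotation matrix is not orthonormal")
        det = float(np.linalg.det(R))
        if abs(det - 1.0) > 1e-6:
            raise ValidationError(f"rotation determinant {det:.6f} != +1 (reflection or scaling)")
        # re-project onto SO(3) so long compositions stay orthonormal
        u, _, vt = np.linalg.svd(R)
        R = u @ vt
        if np.linalg.det(R) < 0:  # pragma: no cover - excluded by det check above
            raise ValidationError("rotation projects onto a reflection")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        assert np.allclose(R @ R.T, np.eye(3), atol=ORTHONORMALITY_TOL)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, m) -> "RigidTransform":
        m = np.asarray(m, dtype=float).reshape(4, 4)
        if not np.allclose(m[3], (0, 0, 0, 1), atol=1e-9):
            raise ValidationError("not an affine rigid matrix (last row must be 0 0 0 1)")
        return cls(m[:3, :3], m[:3, 3])

    @classmethod
    def about_axis(cls, axis, angle_deg: float, center=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Rotation by ``angle_deg`` about ``axis`` through ``center``."""
        from scipy.spatial.transform import Rotation

        axis = _as_vec3(axis)
        n = np.linalg.norm(axis)
        if n == 0:
            raise ValidationError("zero rotation axis")
        R = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis / n).as_matrix()
        c = _as_vec3(center)
        return cls(R, c - R @ c)

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def apply(self, points) -> np.ndarray:
        """Map an (N,3) array or a single 3-vector of world points."""
        p = np.asarray(points, dtype=float)
        single = p.ndim == 1
        out = p.reshape(-1, 3) @ self.rotation.T + self.translation
        return out[0] if single else out

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equal to applying ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def translation_magnitude(self) -> float:
        return float(np.linalg.norm(self.translation))

    def rotation_angle_deg(self) -> float:
        """Total rotation angle (degrees) of the rotation component."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


@dataclass
class LandmarkSet:
    """Named 3D anatomical points in millimetre world coordinates.

    ``frame_tag`` records which frame the coordinates live in (e.g.
    ``"scanner-RAS"`` after loading, ``"head"`` after orientation); geometric
    operations that assume the oriented head frame check it only loosely —
    the tag is provenance, not enforcement.
    """

    points: dict[str, np.ndarray]
    frame_tag: str = "scanner-RAS"
    patient_id: str = ""
    timepoint: str = "T0"

    def __post_init__(self):
        clean: dict[str, np.ndarray] = {}
        for name, p in self.points.items():
            if name in clean:
                raise ValidationError(f"duplicate landmark name {name!r}")
            clean[str(name)] = _as_vec3(p)
        self.points = clean
        if self.timepoint not in ("T0", "T1"):
            raise ValidationError(f"timepoint must be T0 or T1, got {self.timepoint!r}")

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.points[name]
        except KeyError:
            raise MissingLandmarkError([name]) from None

    def __contains__(self, name: str) -> bool:
        return name in self.points

    def names(self) -> list[str]:
        return list(self.points)

    def require(self, names: Iterable[str], task: str = "") -> None:
        missing = [n for n in names if n not in self.points]
        if missing:
            raise MissingLandmarkError(missing, task)

    def subset(self, names: Iterable[str]) -> "LandmarkSet":
        self.require(names)
        return replace(self, points={n: self.points[n].copy() for n in names})

    def transformed(self, t: RigidTransform, frame_tag: str | None = None) -> "LandmarkSet":
        pts = {n: t.apply(p) for n, p in self.points.items()}
        return replace(self, points=pts, frame_tag=frame_tag or self.frame_tag)

    def coordinates(self, names: Iterable[str] | None = None) -> np.ndarray:
        names = list(names) if names is not None else self.names()
        self.require(names)
        return np.array([self.points[n] for n in names])


@dataclass
class VoxelMask:
    """Binary 3D segmentation on a regular grid with a voxel→world affine.

    ``affine`` maps integer voxel indices (i, j, k) to RAS millimetre
    coordinates of the voxel *centre*, following the NIfTI convention.
    """

    grid: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        g = np.asarray(self.grid)
        if g.ndim != 3 or g.size == 0:
            raise ValidationError("mask grid must be a non-empty 3D array")
        self.grid = (g > 0.5).astype(np.uint8)
        A = np.asarray(self.affine, dtype=float).reshape(4, 4)
        if abs(np.linalg.det(A[:3, :3])) < 1e-12:
            raise ValidationError("mask affine is singular")
        if np.any(self.spacing_of(A) <= 0):
            raise ValidationError("voxel spacing must be strictly positive")
        self.affine = A

    @staticmethod
    def spacing_of(affine: np.ndarray) -> np.ndarray:
        return np.linalg.norm(np.asarray(affine)[:3, :3], axis=0)

    @property
    def spacing(self) -> np.ndarray:
        """Voxel edge lengths (mm) along each grid axis."""
        return self.spacing_of(self.affine)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm³."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def foreground_centers(self) -> np.ndarray:
        """World coordinates (N,3) of the centres of all foreground voxels."""
        idx = np.argwhere(self.grid > 0)
        if idx.size == 0:
            return np.empty((0, 3))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def volume(self) -> float:
        """Total foreground volume (mm³)."""
        return float(self.grid.sum()) * self.voxel_volume

    def count(self) -> int:
        return int(self.grid.sum())


@dataclass(frozen=True)
class Plane:
    """An oriented plane ``{x : n·x = offset}`` with unit normal ``n``.

    The positive half-space (``n·x > offset``) is the plane's "superior"
    side for the delimiting planes used in airway measurement.
    """

    normal: np.ndarray
    offset: float

    def __post_init__(self):
        n = _as_vec3(self.normal)
        nn = np.linalg.norm(n)
        if nn < 1e-12:
            raise DegenerateGeometryError("plane normal has zero length")
        object.__setattr__(self, "normal", n / nn)
        object.__setattr__(self, "offset", float(self.offset) / nn)

    @classmethod
    def from_point_normal(cls, point, normal) -> "Plane":
        n = _as_vec3(normal)
        nn = np.linalg.norm(n)
        if nn < 1e-12:
            raise DegenerateGeometryError("plane normal has zero length")
        n = n / nn
        return cls(n, float(n @ _as_vec3(point)))

    def signed_distance(self, points) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        single = p.ndim == 1
        d = p.reshape(-1, 3) @ self.normal - self.offset
        return float(d[0]) if single else d


@dataclass
class AirwayMeasurement:
    """Volumes (mm³) and surface areas (mm²) of the three oropharynx regions.

    ``total`` spans the Ba–PNS plane down to the C4S plane; ``superior`` stops
    at the C2I plane and ``inferior`` continues from it, so the two
    sub-regions partition the total exactly.
    """

    patient_id: str = ""
    timepoint: str = "T0"
    total_volume: float = np.nan
    superior_volume: float = np.nan
    inferior_volume: float = np.nan
    total_area: float = np.nan
    superior_area: float = np.nan
    inferior_area: float = np.nan

    def as_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "timepoint": self.timepoint,
            "total_volume": self.total_volume,
            "superior_volume": self.superior_volume,
            "inferior_volume": self.inferior_volume,
            "total_area": self.total_area,
            "superior_area": self.superior_area,
            "inferior_area": self.inferior_area,
        }


#: Human-readable statement of the pitch sign convention, embedded in outputs.
PITCH_SIGN_CONVENTION = (
    "pitch in degrees about the +X (left-right) axis; positive = counterclockwise "
    "viewed from the patient's right (anterior landmarks rotate superiorly), "
    "negative = clockwise"
)


@dataclass
class MandibleChange:
    """T0→T1 mandibular displacement and signed pitch rotations.

    ``delta_ap`` is the anteroposterior B-point displacement (+ anterior) and
    ``delta_si`` the superoinferior one (+ superior), both in mm.  Pitch
    angles follow :data:`PITCH_SIGN_CONVENTION`: a clockwise rotation (as in
    mandibular-advancement-device bite opening) is negative.
    """

    patient_id: str = ""
    delta_ap: float = np.nan
    delta_si: float = np.nan
    ramus_pitch_R: float = np.nan
    ramus_pitch_L: float = np.nan
    anterior_pitch_R: float = np.nan
    anterior_pitch_L: float = np.nan

    @property
    def ramus_pitch_mean(self) -> float:
        return (self.ramus_pitch_R + self.ramus_pitch_L) / 2.0

    @property
    def anterior_pitch_mean(self) -> float:
        return (self.anterior_pitch_R + self.anterior_pitch_L) / 2.0

    def as_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "delta_ap": self.delta_ap,
            "delta_si": self.delta_si,
            "ramus_pitch_R": self.ramus_pitch_R,
            "ramus_pitch_L": self.ramus_pitch_L,
            "ramus_pitch_mean": self.ramus_pitch_mean,
            "anterior_pitch_R": self.anterior_pitch_R,
            "anterior_pitch_L": self.anterior_pitch_L,
            "anterior_pitch_mean": self.anterior_pitch_mean,
            "sign_convention": PITCH_SIGN_CONVENTION,
        }
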