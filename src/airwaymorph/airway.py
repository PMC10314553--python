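"""Plane-delimited oropharynx volumetrics.

Three parallel planes — through Ba–PNS, through C2I and through C4S — cut
the airway mask into a superior and an inferior oropharynx whose union is
the total region.  Volumes are counted over voxel centres in half-open
slabs, which makes the superior/inferior split an exact partition of the
total; surface areas come from one triangulated iso-surface of the whole
mask whose triangles are assigned to slabs by centroid (no artificial planar
caps are added).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .errors import DegenerateGeometryError, ValidationError
from .model import AirwayMeasurement, LandmarkSet, Plane, VoxelMask

log = logging.getLogger(__name__)

_PARALLEL_TOL = 1e-9


@dataclass(frozen=True)
class DelimitingPlanes:
    """The three parallel delimiting planes, superior to inferior.

    All share one unit normal whose Z component is positive, so signed
    offsets order the planes: ``base`` (through Ba and PNS) above ``c2i``
    above ``c4s``.
    """

    base: Plane
    c2i: Plane
    c4s: Plane

    def __post_init__(self):
        for other in (self.c2i, self.c4s):
            if np.linalg.norm(np.cross(self.base.normal, other.normal)) > 1e-9:
                raise ValidationError("delimiting planes must share one normal")
        if not (self.base.offset > self.c2i.offset > self.c4s.offset):
            raise DegenerateGeometryError(
                "delimiting planes out of order: need offset(base) > offset(C2I) > offset(C4S), "
                f"got {self.base.offset:.3f}, {self.c2i.offset:.3f}, {self.c4s.offset:.3f}")


def build_delimiting_planes(landmarks: LandmarkSet) -> DelimitingPlanes:
    """Construct the Ba–PNS, C2I and C4S planes from oriented-frame landmarks.

    Two points and the word "parallel" do not determine a plane, so the
    Ba–PNS plane is completed by requiring it to be perpendicular to the
    midsagittal plane: its normal lies in the sagittal YZ plane, orthogonal
    to the YZ projection of the Ba→PNS direction, with positive Z component.
    The C2I and C4S planes share that normal.
    """
    landmarks.require(("Ba", "PNS", "C2I", "C4S"), "airway delimitation")
    ba, pns = landmarks["Ba"], landmarks["PNS"]
    v = pns - ba
    if np.linalg.norm(v) < 1e-9:
        raise DegenerateGeometryError("Ba and PNS coincide")
    vy, vz = v[1], v[2]
    if abs(vy) < 1e-12 and abs(vz) < 1e-12:
        raise DegenerateGeometryError("Ba->PNS is parallel to the left-right axis; "
                                      "its sagittal projection is a point")
    normal = np.array([0.0, -vz, vy])
    if abs(normal[2]) < 1e-12:
        raise DegenerateGeometryError("Ba->PNS is vertical; base plane has no superior side")
    if normal[2] < 0:
        normal = -normal
    base = Plane.from_point_normal(ba, normal)
    c2i = Plane.from_point_normal(landmarks["C2I"], normal)
    c4s = Plane.from_point_normal(landmarks["C4S"], normal)
    return DelimitingPlanes(base=base, c2i=c2i, c4s=c4s)


def _check_slab(upper: Plane, lower: Plane) -> None:
    if np.linalg.norm(np.cross(upper.normal, lower.normal)) > 1e-9:
        raise ValidationError("slab planes are not parallel")
    if not upper.offset > lower.offset:
        raise ValidationError("upper plane must be strictly superior to lower plane")


def region_voxel_count(mask: VoxelMask, upper: Plane, lower: Plane) -> int:
    """Number of foreground voxels whose centre lies in the half-open slab
    [lower, upper).  The half-open convention makes stacked slabs partition
    the foreground exactly, voxel by voxel."""
    _check_slab(upper, lower)
    centers = mask.foreground_centers()
    if centers.size == 0:
        return 0
    s = centers @ upper.normal
    return int(((s >= lower.offset) & (s < upper.offset)).sum())


def region_volume(mask: VoxelMask, upper: Plane, lower: Plane) -> float:
    """Foreground volume (mm³) in the half-open slab [lower, upper).

    Voxel-centre counting times the voxel volume: exactly additive across
    stacked slabs and exactly reproducible; no partial-volume weighting.
    """
    return region_voxel_count(mask, upper, lower) * mask.voxel_volume


def mask_surface(mask: VoxelMask, smooth_voxels: float = 1.0):
    """Triangulated 0.5 iso-surface of the mask in world coordinates.

    The binary grid is Gaussian-smoothed by ``smooth_voxels`` (in voxel
    units) before marching cubes; this suppresses the staircase bias that
    would otherwise inflate areas of smooth anatomy by several percent.
    Returns ``(vertices (N,3) world mm, faces (M,3))``.
    """
    grid = mask.grid.astype(float)
    if smooth_voxels > 0:
        grid = ndimage.gaussian_filter(grid, smooth_voxels)
    # pad so surfaces of structures touching the grid edge stay closed
    grid = np.pad(grid, 1, mode="constant")
    verts, faces, _, _ = measure.marching_cubes(grid, level=0.5)
    verts = verts - 1.0  # undo padding
    A = mask.affine
    world = verts @ A[:3, :3].T + A[:3, 3]
    return world, faces


def _triangle_areas_and_centroids(verts: np.ndarray, faces: np.ndarray):
    tri = verts[faces]
    a = tri[:, 1] - tri[:, 0]
    b = tri[:, 2] - tri[:, 0]
    areas = 0.5 * np.linalg.norm(np.cross(a, b), axis=1)
    centroids = tri.mean(axis=1)
    return areas, centroids


def region_surface_area(mask: VoxelMask, upper: Plane, lower: Plane,
                        surface=None) -> float:
    """Surface area (mm²) of the mask's iso-surface inside [lower, upper).

    Triangles are assigned to the slab by centroid, so stacked slabs
    partition the full surface.  The planar cut faces are *not* added: the
    area measures anatomy, not the artificial delimitation.  Pass a
    precomputed ``surface=(verts, faces)`` to amortize marching cubes across
    regions.
    """
    _check_slab(upper, lower)
    verts, faces = surface if surface is not None else mask_surface(mask)
    if len(faces) == 0:
        return 0.0
    areas, centroids = _triangle_areas_and_centroids(verts, faces)
    s = centroids @ upper.normal
    inside = (s >= lower.offset) & (s < upper.offset)
    return float(areas[inside].sum())


def measure_airway(mask: VoxelMask, landmarks: LandmarkSet,
                   patient_id: str | None = None,
                   timepoint: str | None = None) -> AirwayMeasurement:
    """Measure total/superior/inferior oropharynx volume and surface area.

    ``mask`` and ``landmarks`` must already be in the same oriented,
    registered frame.  Total spans [C4S, base); superior [C2I, base);
    inferior [C4S, C2I) — so superior + inferior equals total exactly for
    volumes and for centroid-assigned areas.
    """
    planes = build_delimiting_planes(landmarks)
    vol_sup = region_volume(mask, planes.base, planes.c2i)
    vol_inf = region_volume(mask, planes.c2i, planes.c4s)
    surface = mask_surface(mask)
    area_sup = region_surface_area(mask, planes.base, planes.c2i, surface=surface)
    area_inf = region_surface_area(mask, planes.c2i, planes.c4s, surface=surface)
    if vol_sup + vol_inf == 0.0:
        log.warning("airway mask has no voxels between the Ba-PNS and C4S planes "
                    "(patient %s %s)", patient_id, timepoint)
    return AirwayMeasurement(
        patient_id=patient_id if patient_id is not None else landmarks.patient_id,
        timepoint=timepoint if timepoint is not None else landmarks.timepoint,
        total_volume=vol_sup + vol_inf,
        superior_volume=vol_sup,
        inferior_volume=vol_inf,
        total_area=area_sup + area_inf,
        superior_area=area_sup,
        inferior_area=area_inf,
    )
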