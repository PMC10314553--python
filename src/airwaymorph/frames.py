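"""Head-frame construction and rigid T1→T0 registration.

The oriented head frame puts the Frankfurt horizontal plane perpendicular to
+Z, the midsagittal plane at X = 0 and the transporionic axis along +X, with
the origin at the mid-transporionic point.  Two registration paths are
offered: a deterministic least-squares fit over named cranial-base landmarks
(the pipeline default) and an intensity/overlap-based rigid voxel
registration for mask or grayscale volumes.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .errors import DegenerateGeometryError, ValidationError
from .model import LandmarkSet, RigidTransform, VoxelMask

log = logging.getLogger(__name__)

_COLLINEAR_TOL = 1e-8


@dataclass(frozen=True)
class HeadFrame:
    """Oriented head coordinate system derived from Po/Or landmarks.

    ``transform`` maps scanner-world coordinates into the oriented frame;
    ``origin`` is the mid-transporionic point in scanner-world coordinates.
    """

    transform: RigidTransform
    origin: np.ndarray


def build_head_frame(landmarks: LandmarkSet) -> HeadFrame:
    """Build the oriented head frame from porion and orbitale landmarks.

    The transporionic axis defines X, the best-fit Frankfurt plane through
    the two porions and the mean orbitale defines Z (superior-positive), and
    Y completes the right-handed triad.  Left/right orbitale are averaged so
    the three points determine the Frankfurt plane uniquely; if only one
    orbitale is present it is used alone.
    """
    landmarks.require(("PoR", "PoL"), "head orientation")
    if "OrR" not in landmarks and "OrL" not in landmarks:
        raise ValidationError("head orientation needs at least one orbitale (OrR or OrL)")
    por, pol = landmarks["PoR"], landmarks["PoL"]
    ors = [landmarks[n] for n in ("OrR", "OrL") if n in landmarks]
    orb = np.mean(ors, axis=0)

    x_dir = pol - por
    nx = np.linalg.norm(x_dir)
    if nx < _COLLINEAR_TOL:
        raise DegenerateGeometryError("porions coincide; transporionic axis undefined")
    x_axis = x_dir / nx

    # Frankfurt plane through PoR, PoL, mean orbitale
    v = orb - por
    z_axis = np.cross(x_axis, v)
    nz = np.linalg.norm(z_axis)
    if nz < _COLLINEAR_TOL * max(1.0, np.linalg.norm(v)):
        raise DegenerateGeometryError("porions and orbitale are collinear; Frankfurt plane undefined")
    z_axis = z_axis / nz
    # orient superiorly: the orbitale sits anterior to the porions, so the
    # superior normal is the one making a right-handed (x, y, z) with y toward it
    if np.dot(np.cross(z_axis, x_axis), v) < 0:
        z_axis = -z_axis
    y_axis = np.cross(z_axis, x_axis)
    y_axis /= np.linalg.norm(y_axis)
    z_axis = np.cross(x_axis, y_axis)

    R = np.vstack([x_axis, y_axis, z_axis])  # rows = frame axes in world coords
    origin = 0.5 * (por + pol)
    transform = RigidTransform(R, -R @ origin)
    return HeadFrame(transform=transform, origin=origin)


def register_landmarks_rigid(source: LandmarkSet, target: LandmarkSet,
                             names: Iterable[str] | None = None) -> RigidTransform:
    """Least-squares rigid fit mapping ``source`` points onto ``target``.

    Solves the orthogonal Procrustes problem (no scaling) over the named
    landmarks shared by the two sets.  A best fit that would require a
    reflection is rejected — it cannot arise from a physical motion.
    """
    if names is None:
        names = [n for n in source.names() if n in target]
    names = list(names)
    if len(names) < 3:
        raise ValidationError(f"rigid fit needs >= 3 shared landmarks, got {len(names)}")
    P = source.coordinates(names)
    Q = target.coordinates(names)
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    # collinearity check: rank of the centered source configuration
    if np.linalg.matrix_rank(P0, tol=1e-8 * max(1.0, np.abs(P0).max())) < 2:
        raise DegenerateGeometryError("landmarks are collinear; rotation is not determined")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    R = Vt.T @ U.T
    if np.linalg.det(R) < 0:
        raise DegenerateGeometryError("best rigid fit requires a reflection")
    t = qc - R @ pc
    fit = RigidTransform(R, t)
    rms = float(np.sqrt(np.mean(np.sum((fit.apply(P) - Q) ** 2, axis=1))))
    log.debug("rigid landmark fit over %d points, RMS %.4f mm", len(names), rms)
    return fit


def registration_rms(t: RigidTransform, source: LandmarkSet, target: LandmarkSet,
                     names: Iterable[str] | None = None) -> float:
    """RMS residual (mm) of a rigid fit over the named shared landmarks."""
    if names is None:
        names = [n for n in source.names() if n in target]
    names = list(names)
    P, Q = source.coordinates(names), target.coordinates(names)
    return float(np.sqrt(np.mean(np.sum((t.apply(P) - Q) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# voxel-based registration

#: LPS↔RAS flip used to talk to ITK, which works in LPS world coordinates.
_RAS2LPS = np.diag([-1.0, -1.0, 1.0])


def _mask_to_sitk(mask: VoxelMask, smooth_mm: float = 0.0) -> sitk.Image:
    grid = mask.grid.astype(np.float32)
    if smooth_mm > 0:
        grid = ndimage.gaussian_filter(grid, smooth_mm / mask.spacing)
    # SimpleITK array indexing is (z, y, x) relative to image (x, y, z)
    img = sitk.GetImageFromArray(np.ascontiguousarray(grid.transpose(2, 1, 0)))
    A = _RAS2LPS @ mask.affine[:3, :3]
    spacing = np.linalg.norm(A, axis=0)
    direction = A / spacing
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetDirection(tuple(direction.flatten()))
    origin = _RAS2LPS @ mask.affine[:3, 3]
    img.SetOrigin(tuple(float(o) for o in origin))
    return img


def _euler_to_ras_transform(tf: sitk.Transform) -> RigidTransform:
    """Convert an ITK rigid transform (LPS, fixed→moving) to RAS moving→fixed."""
    tf = sitk.Euler3DTransform(tf)
    R_lps = np.asarray(tf.GetMatrix()).reshape(3, 3)
    c = np.asarray(tf.GetCenter())
    t = np.asarray(tf.GetTranslation())
    # point map in LPS: y = R (x - c) + c + t  (fixed-space point -> moving-space point)
    t_lps = c + t - R_lps @ c
    fixed_to_moving_lps = RigidTransform(R_lps, t_lps)
    m = fixed_to_moving_lps.inverse()
    R_ras = _RAS2LPS @ m.rotation @ _RAS2LPS
    t_ras = _RAS2LPS @ m.translation
    return RigidTransform(R_ras, t_ras)


@dataclass
class VoxelRegistrationResult:
    transform: RigidTransform
    final_metric: float
    converged: bool


def register_voxel_rigid(fixed: VoxelMask, moving: VoxelMask,
                         region_mask: VoxelMask | None = None,
                         init: RigidTransform | None = None,
                         smooth_mm: float = 1.5,
                         shrink_factors: Sequence[int] = (4, 2, 1),
                         smoothing_sigmas: Sequence[float] = (2.0, 1.0, 0.0),
                         n_iterations: int = 200,
                         seed: int = 0,
                         full_result: bool = False) -> RigidTransform | VoxelRegistrationResult:
    """Rigid voxel registration of ``moving`` onto ``fixed``.

    Binary inputs are Gaussian-smoothed (``smooth_mm``) into soft edge maps
    and aligned by maximizing normalized correlation with a multi-resolution
    regular-step gradient descent; sampling is dense, so the result is
    deterministic for fixed settings.  When ``region_mask`` is given (e.g. a
    cranial-base box), the metric is evaluated only inside it.  Returns the
    RAS transform mapping moving-frame coordinates into the fixed frame; with
    ``full_result=True`` a :class:`VoxelRegistrationResult` carrying the final
    metric value and a convergence flag.
    """
    if region_mask is not None and region_mask.count() == 0:
        raise ValidationError("region_mask is empty")

    f_img = _mask_to_sitk(fixed, smooth_mm)
    m_img = _mask_to_sitk(moving, smooth_mm)

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsCorrelation()
    if region_mask is not None:
        reg.SetMetricFixedMask(_mask_to_sitk(region_mask) > 0.5)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetMetricSamplingStrategy(reg.NONE)  # dense sampling: deterministic
    reg.SetShrinkFactorsPerLevel(list(shrink_factors))
    reg.SetSmoothingSigmasPerLevel(list(smoothing_sigmas))
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOn()
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-5, numberOfIterations=n_iterations,
        relaxationFactor=0.6, gradientMagnitudeTolerance=1e-8)
    reg.SetOptimizerScalesFromPhysicalShift()

    initial = sitk.CenteredTransformInitializer(
        f_img, m_img, sitk.Euler3DTransform(),
        sitk.CenteredTransformInitializerFilter.GEOMETRY)
    if init is not None:
        # caller supplies moving→fixed in RAS; ITK wants fixed→moving in LPS
        inv = init.inverse()
        e = sitk.Euler3DTransform(initial)
        e.SetCenter((0.0, 0.0, 0.0))
        e.SetMatrix(tuple((_RAS2LPS @ inv.rotation @ _RAS2LPS).flatten()))
        e.SetTranslation(tuple(_RAS2LPS @ inv.translation))
        initial = e
    reg.SetInitialTransform(sitk.Euler3DTransform(initial), inPlace=True)

    final = reg.Execute(f_img, m_img)
    metric = float(reg.GetMetricValue())
    stop = reg.GetOptimizerStopConditionDescription()
    converged = "Maximum number of iterations" not in stop
    if not converged:
        log.warning("voxel registration hit the iteration budget (%d); "
                    "returning best-so-far (metric %.5f)", n_iterations, metric)
    result = VoxelRegistrationResult(_euler_to_ras_transform(final), metric, converged)
    return result if full_result else result.transform


def transform_discrepancy(a: RigidTransform, b: RigidTransform,
                          points: np.ndarray) -> tuple[float, float]:
    """How differently two rigid transforms move a point cloud.

    Returns ``(mean displacement mm, rotation angle difference deg)`` —
    the natural error measure for registration recovery, since a raw
    translation-vector comparison conflates rotation-center choice with
    actual misregistration.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    disp = float(np.mean(np.linalg.norm(a.apply(pts) - b.apply(pts), axis=1)))
    return disp, a.compose(b.inverse()).rotation_angle_deg()


# ---------------------------------------------------------------------------
# applying transforms


def apply_transform(x: LandmarkSet | VoxelMask, t: RigidTransform):
    """Map a landmark set (exactly) or a voxel mask (nearest-neighbour resample).

    Masks are resampled back onto their own grid: the output voxel at index
    ``i`` takes the value of the input at world point ``t⁻¹(A i)``, which
    preserves binarity and grid geometry.
    """
    if isinstance(x, LandmarkSet):
        return x.transformed(t)
    if isinstance(x, VoxelMask):
        A = x.affine
        # index -> index map of the *inverse* point transform, as required by map_coordinates
        inv = t.inverse()
        M = np.linalg.inv(A) @ inv.as_matrix() @ A
        out = ndimage.affine_transform(x.grid, M[:3, :3], offset=M[:3, 3],
                                       order=0, mode="constant", cval=0,
                                       output=np.uint8)
        return VoxelMask(grid=out, affine=A.copy())
    raise ValidationError(f"cannot transform object of type {type(x).__name__}")
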