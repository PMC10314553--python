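"""Synthetic phantoms with analytic ground truth.

No imaging data ship with the package, so validation runs end-to-end on
synthetic stand-ins for the study inputs: tube-shaped airway masks whose
plane-bounded volumes and lateral areas are closed-form, mandibular landmark
pairs related by a programmed rigid motion, repeated landmarkings with
Gaussian jitter, and two-group cohorts drawn from multivariate normals with
programmable means, SDs and correlations.  Default cohort parameters are set
to the published group summaries of the MAD/MMA study population the package
targets, so a default simulation reproduces that study's conditions in
distribution.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .model import (AirwayMeasurement, LandmarkSet, MandibleChange,
                    RigidTransform, VoxelMask)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# airway tube phantom

@dataclass
class AirwayPhantomSpec:
    """Tube-shaped airway phantom with landmark levels on the Z axis.

    The tube axis runs along +Z through (0, 0).  ``radius`` is either a
    single value or a list of ``(z_lo, z_hi, r)`` segments (piecewise
    constant, mm); segment breaks must coincide with landmark levels or lie
    outside the measured range for the analytic truth to be exact.
    ``tilt_deg`` tilts the three delimiting planes about +X (the Ba–PNS line
    is placed on the tilted base plane).  ``grid_offset`` shifts the voxel
    grid by a fraction of one voxel, for probing discretization error.
    """

    radius: float | Sequence[tuple[float, float, float]] = 10.0
    z_base: float = 40.0
    z_c2i: float = 15.0
    z_c4s: float = -10.0
    tilt_deg: float = 0.0
    spacing: float = 0.4
    margin: float = 4.0
    grid_offset: tuple[float, float, float] = (0.11, 0.29, 0.05)
    patient_id: str = "phantom"
    timepoint: str = "T0"

    def __post_init__(self):
        if not (self.z_base > self.z_c2i > self.z_c4s):
            raise ValidationError("landmark levels must satisfy z_base > z_c2i > z_c4s")
        if self.spacing <= 0:
            raise ValidationError("spacing must be positive")
        for _, _, r in self.segments():
            if r <= 0:
                raise ValidationError("tube radius must be positive")

    def segments(self) -> list[tuple[float, float, float]]:
        if np.isscalar(self.radius):
            lo = self.z_c4s - self.margin - self._tilt_reach()
            hi = self.z_base + self.margin + self._tilt_reach()
            return [(lo, hi, float(self.radius))]
        return [(float(a), float(b), float(r)) for a, b, r in self.radius]

    def _tilt_reach(self) -> float:
        rmax = self.radius if np.isscalar(self.radius) else max(r for _, _, r in self.radius)
        return abs(np.tan(np.deg2rad(self.tilt_deg))) * (float(rmax) + self.margin)

    def radius_at(self, z: np.ndarray) -> np.ndarray:
        r = np.zeros_like(z)
        for lo, hi, rad in self.segments():
            r[(z >= lo) & (z < hi)] = rad
        return r


def _segment_overlap(lo: float, hi: float, a: float, b: float) -> float:
    return max(0.0, min(hi, b) - max(lo, a))


def make_airway_phantom(spec: AirwayPhantomSpec
                        ) -> tuple[VoxelMask, LandmarkSet, AirwayMeasurement]:
    """Voxelize the tube, place the landmarks and compute analytic truth.

    For planes sharing a normal tilted by θ about +X, the slab between two
    planes cuts the tube in an oblique segment whose volume is
    π r² × (axis height) and whose lateral area is 2π r × (axis height),
    where the axis height is the Z distance between the plane/axis
    intersections — so truth is closed-form even for tilted planes.
    """
    segs = spec.segments()
    z_lo = min(a for a, _, _ in segs)
    z_hi = max(b for _, b, _ in segs)
    if not (z_lo < spec.z_c4s and z_hi > spec.z_base):
        raise ValidationError("landmark levels lie outside the tube extent")
    rmax = max(r for _, _, r in segs)
    h = spec.spacing
    half = rmax + spec.margin
    nxy = int(np.ceil(2 * half / h))
    nz = int(np.ceil((z_hi - z_lo) / h))
    off = np.asarray(spec.grid_offset, dtype=float) * h
    origin = np.array([-half, -half, z_lo]) + off
    affine = np.diag([h, h, h, 1.0])
    affine[:3, 3] = origin

    xs = origin[0] + h * np.arange(nxy)
    ys = origin[1] + h * np.arange(nxy)
    zs = origin[2] + h * np.arange(nz)
    r_of_z = spec.radius_at(zs)
    rho2 = xs[:, None] ** 2 + ys[None, :] ** 2
    grid = (rho2[:, :, None] <= r_of_z[None, None, :] ** 2) & (r_of_z[None, None, :] > 0)
    mask = VoxelMask(grid=grid.astype(np.uint8), affine=affine)

    # landmarks: Ba posterior / PNS anterior on the (possibly tilted) base plane
    tan_t = float(np.tan(np.deg2rad(spec.tilt_deg)))
    c = rmax + 2.0
    lm = LandmarkSet(points={
        "Ba": (0.0, -c, spec.z_base - c * tan_t),
        "PNS": (0.0, c, spec.z_base + c * tan_t),
        "C2I": (0.0, 0.0, spec.z_c2i),
        "C4S": (0.0, 0.0, spec.z_c4s),
    }, frame_tag="head", patient_id=spec.patient_id, timepoint=spec.timepoint)

    def region(z_top: float, z_bot: float) -> tuple[float, float]:
        vol = area = 0.0
        for lo, hi, rad in segs:
            ov = _segment_overlap(lo, hi, z_bot, z_top)
            vol += np.pi * rad ** 2 * ov
            area += 2.0 * np.pi * rad * ov
        return vol, area

    v_sup, a_sup = region(spec.z_base, spec.z_c2i)
    v_inf, a_inf = region(spec.z_c2i, spec.z_c4s)
    truth = AirwayMeasurement(
        patient_id=spec.patient_id, timepoint=spec.timepoint,
        total_volume=v_sup + v_inf, superior_volume=v_sup, inferior_volume=v_inf,
        total_area=a_sup + a_inf, superior_area=a_sup, inferior_area=a_inf)
    return mask, lm, truth


def make_registration_phantom(spacing: float = 0.8, half_extent: float = 30.0,
                              motion: RigidTransform | None = None) -> VoxelMask:
    """Asymmetric multi-ellipsoid mask for exercising voxel registration.

    A tube is rotationally symmetric about its axis, which leaves one
    rotation unconstrained; this phantom has no symmetry, so a programmed
    rigid motion is fully identifiable.  When ``motion`` is given the object
    is voxelized *analytically* in its moved pose (each voxel centre is
    pulled back through the inverse motion), so the moved mask is exact to
    voxelization — resampling a binary grid instead would itself shift the
    object by up to half a voxel and contaminate recovery error estimates.
    """
    if spacing <= 0:
        raise ValidationError("spacing must be positive")
    n = int(np.ceil(2 * half_extent / spacing))
    c = (np.arange(n) - n / 2) * spacing
    X, Y, Z = np.meshgrid(c, c, c, indexing="ij")
    if motion is not None:
        pts = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
        pts = motion.inverse().apply(pts)
        X, Y, Z = (pts[:, i].reshape(n, n, n) for i in range(3))
    grid = np.zeros((n, n, n), dtype=bool)
    for cx, cy, cz, a, b, cc in [(0, 0, 0, 16, 12, 9), (10, 8, 10, 6, 5, 7),
                                 (-12, -4, 6, 5, 8, 4), (4, -12, -8, 7, 4, 6)]:
        grid |= ((X - cx) ** 2 / a ** 2 + (Y - cy) ** 2 / b ** 2
                 + (Z - cz) ** 2 / cc ** 2) <= 1.0
    affine = np.diag([spacing, spacing, spacing, 1.0])
    affine[:3, 3] = (-half_extent, -half_extent, -half_extent)
    return VoxelMask(grid=grid.astype(np.uint8), affine=affine)


# ---------------------------------------------------------------------------
# mandible motion phantom

#: T0 template in the oriented head frame (mm): condyles near the origin,
#: gonia inferior-posterior, B point anterior-inferior at the midline.
DEFAULT_MANDIBLE_TEMPLATE: dict[str, tuple[float, float, float]] = {
    "CoR": (50.0, -5.0, -5.0),
    "CoL": (-50.0, -5.0, -5.0),
    "GoR": (45.0, -10.0, -50.0),
    "GoL": (-45.0, -10.0, -50.0),
    "B": (0.0, 60.0, -65.0),
}


@dataclass
class MandibleCaseSpec:
    """A programmed rigid mandibular motion: pitch + AP/SI translation.

    The motion rotates by ``pitch_deg`` about the +X axis through the
    mid-condylar point, then translates by (0, ``advance_mm``, ``raise_mm``).
    """

    pitch_deg: float = 0.0
    advance_mm: float = 0.0
    raise_mm: float = 0.0
    template: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MANDIBLE_TEMPLATE))
    patient_id: str = "phantom"


def make_mandible_case(spec: MandibleCaseSpec
                       ) -> tuple[LandmarkSet, LandmarkSet, MandibleChange]:
    """Apply the programmed motion to the template; return T0, T1 and truth.

    The truth pitch equals the programmed angle on all four mandibular lines
    (a rigid pitch rotation turns every sagittal projection by the same
    angle); the truth displacement is the B-point image minus B.
    """
    lm_t0 = LandmarkSet(points=dict(spec.template), frame_tag="head",
                        patient_id=spec.patient_id, timepoint="T0")
    center = 0.5 * (lm_t0["CoR"] + lm_t0["CoL"])
    motion = RigidTransform(np.eye(3), np.array([0.0, spec.advance_mm, spec.raise_mm])
                            ).compose(RigidTransform.about_axis((1, 0, 0), spec.pitch_deg, center))
    lm_t1 = lm_t0.transformed(motion)
    lm_t1.timepoint = "T1"
    d = motion.apply(lm_t0["B"]) - lm_t0["B"]
    truth = MandibleChange(
        patient_id=spec.patient_id, delta_ap=float(d[1]), delta_si=float(d[2]),
        ramus_pitch_R=spec.pitch_deg, ramus_pitch_L=spec.pitch_deg,
        anterior_pitch_R=spec.pitch_deg, anterior_pitch_L=spec.pitch_deg)
    return lm_t0, lm_t1, truth


def jitter_landmarks(lm: LandmarkSet, sigma: float, n_repeats: int,
                     seed: int | np.random.Generator = 0) -> list[LandmarkSet]:
    """Repeated landmarkings with i.i.d. isotropic Gaussian displacement.

    Emulates intra-rater relocation error of magnitude ``sigma`` mm per
    coordinate; the same seed reproduces the same repeats bit-for-bit.
    """
    if sigma < 0:
        raise ValidationError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_repeats):
        pts = {n: p + rng.normal(0.0, sigma, size=3) if sigma > 0 else p.copy()
               for n, p in lm.points.items()}
        out.append(replace(lm, points=pts))
    return out


# ---------------------------------------------------------------------------
# cohort simulator

#: Published group summaries used as simulation defaults: T0 mean/SD per
#: airway variable (mm³ volumes, mm² areas) and T1−T0 change mean per
#: variable.  Change SDs are not published; they are derived from the T0/T1
#: SDs under an assumed longitudinal correlation (see ``CohortSpec``).
_T0_T1_TABLE = {
    # variable: {group: ((t0_mean, t0_sd), (t1_mean, t1_sd))}
    "total_volume": {"MAD": ((12860.12, 4442.52), (14130.82, 4258.66)),
                     "MMA": ((13485.22, 8376.86), (19984.25, 8906.67))},
    "total_area": {"MAD": ((5380.06, 1245.42), (5685.71, 1297.52)),
                   "MMA": ((5153.73, 1790.80), (6662.65, 1992.15))},
    "superior_volume": {"MAD": ((7993.69, 2397.96), (10049.33, 3555.98)),
                        "MMA": ((10030.88, 6559.56), (15248.59, 6946.79))},
    "superior_area": {"MAD": ((3440.90, 736.27), (3836.44, 860.38)),
                      "MMA": ((3780.54, 1665.06), (5100.30, 1821.71))},
    "inferior_volume": {"MAD": ((4863.08, 2382.66), (4311.76, 2267.63)),
                        "MMA": ((4105.69, 2019.74), (6183.29, 2338.97))},
    "inferior_area": {"MAD": ((2279.50, 722.15), (2082.07, 707.66)),
                      "MMA": ((2034.82, 515.63), (2731.81, 709.37))},
}

#: Mandibular change summaries (mean, sd) per group: mm for displacements,
#: degrees for pitches (negative = clockwise).
_MANDIBLE_TABLE = {
    "delta_ap": {"MAD": (2.75, 3.08), "MMA": (6.47, 4.67)},
    "delta_si": {"MAD": (-9.29, 3.06), "MMA": (1.66, 4.32)},
    "ramus_pitch": {"MAD": (-3.97, 1.07), "MMA": (2.40, 3.43)},
    "anterior_pitch": {"MAD": (-4.08, 1.30), "MMA": (3.41, 2.79)},
}

#: Demographics per group: (age mean, sd), (weight mean, sd), (height mean,
#: sd), P(male).
_DEMOGRAPHICS = {
    "MAD": {"age": (47.35, 9.33), "weight": (70.76, 16.01), "height": (1.65, 0.13),
            "p_male": 9 / 17},
    "MMA": {"age": (34.00, 11.20), "weight": (68.59, 15.89), "height": (1.67, 0.11),
            "p_male": 7 / 17},
}

#: Default inter-variable correlation targets among change scores, per group.
#: The reported pairwise correlations of the target study are not jointly
#: realizable as a correlation matrix with zeros elsewhere, so the MMA
#: defaults are the nearest valid correlation matrix to those targets
#: (Higham projection, frozen here); the MAD triple is realizable as printed.
DEFAULT_CORRELATIONS: dict[str, dict[tuple[str, str], float]] = {
    "MAD": {
        ("delta_ap", "d_superior_volume"): -0.697,
        ("delta_ap", "d_inferior_volume"): 0.658,
        ("delta_si", "anterior_pitch"): 0.557,
    },
    "MMA": {
        ("delta_ap", "delta_si"): 0.415,
        ("delta_ap", "d_superior_volume"): -0.468,
        ("delta_ap", "ramus_pitch"): 0.667,
        ("delta_ap", "anterior_pitch"): 0.839,
        ("delta_si", "d_superior_volume"): 0.414,
        ("delta_si", "ramus_pitch"): 0.092,
        ("delta_si", "anterior_pitch"): 0.688,
        ("d_superior_volume", "ramus_pitch"): -0.066,
        ("d_superior_volume", "anterior_pitch"): 0.047,
        ("ramus_pitch", "anterior_pitch"): 0.743,
    },
}


def _default_group_variables(group: str, longitudinal_rho: float
                             ) -> dict[str, dict]:
    out: dict[str, dict] = {}
    for var, per_group in _T0_T1_TABLE.items():
        (m0, s0), (m1, s1) = per_group[group]
        sd_change = float(np.sqrt(max(s0 ** 2 + s1 ** 2 - 2 * longitudinal_rho * s0 * s1,
                                      (0.1 * min(s0, s1)) ** 2)))
        out[var] = {"t0": (m0, s0), "change": (m1 - m0, sd_change)}
    for var, per_group in _MANDIBLE_TABLE.items():
        out[var] = {"t0": None, "change": per_group[group]}
    return out


@dataclass
class GroupSpec:
    """One simulated treatment group.

    ``variables`` maps variable name → ``{"t0": (mean, sd) or None,
    "change": (mean, sd)}``.  Variables with a T0 distribution get
    ``<var>_t0`` and ``<var>_t1`` columns (T1 = T0 + change); change-only
    variables (displacements, rotations) get a single column.
    ``correlations`` are target Pearson correlations between change scores;
    change variables of airway measures are addressed as ``d_<var>``.
    """

    name: str
    n: int = 17
    variables: dict[str, dict] = field(default_factory=dict)
    correlations: dict[tuple[str, str], float] = field(default_factory=dict)
    demographics: dict = field(default_factory=dict)


@dataclass
class CohortSpec:
    """Two-group cohort simulation specification.

    With no arguments this reproduces the target study's conditions: n = 17
    per group, published T0 means/SDs and change means, change SDs derived
    under ``longitudinal_rho`` (default 0.8, a typical test–retest
    correlation for anatomical volumes), published demographics, and the
    default correlation structure.
    """

    groups: list[GroupSpec] = field(default_factory=list)
    longitudinal_rho: float = 0.8
    #: anything numpy's default_rng accepts: int, SeedSequence, Generator
    seed: int | np.random.SeedSequence | np.random.Generator = 0

    def __post_init__(self):
        if not self.groups:
            self.groups = [
                GroupSpec(name=g, n=17,
                          variables=_default_group_variables(g, self.longitudinal_rho),
                          correlations=dict(DEFAULT_CORRELATIONS[g]),
                          demographics=dict(_DEMOGRAPHICS[g]))
                for g in ("MAD", "MMA")
            ]
        for g in self.groups:
            if g.n < 2:
                raise ValidationError(f"group {g.name}: need n >= 2")
            for var, vs in g.variables.items():
                if vs["change"][1] <= 0 or (vs["t0"] is not None and vs["t0"][1] <= 0):
                    raise ValidationError(f"group {g.name}, variable {var}: SDs must be > 0")
            for (a, b), r in g.correlations.items():
                if not abs(r) < 1:
                    raise ValidationError(f"correlation target |r({a},{b})| must be < 1")


def _change_key(var: str, variables: Mapping[str, dict]) -> str:
    return f"d_{var}" if variables[var]["t0"] is not None else var


def _correlation_matrix(g: GroupSpec) -> tuple[list[str], np.ndarray]:
    names = [_change_key(v, g.variables) for v in g.variables]
    ix = {n: i for i, n in enumerate(names)}
    C = np.eye(len(names))
    for (a, b), r in g.correlations.items():
        if a not in ix or b not in ix:
            raise ValidationError(f"correlation target references unknown variable: {(a, b)}")
        C[ix[a], ix[b]] = C[ix[b], ix[a]] = r
    try:
        np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        raise ValidationError(
            f"group {g.name}: correlation targets are not positive definite") from None
    return names, C


def simulate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a cohort: returns ``(manifest, measurements)`` data frames.

    Change scores are multivariate normal with the group's means/SDs and
    correlation targets; T1 = T0 + change with T0 drawn independently per
    variable.  Demographics are drawn from the configured normals (BMI is
    computed from weight and height, so the manifest is self-consistent);
    everything is deterministic under the spec seed.
    """
    rng = np.random.default_rng(spec.seed)
    manifest_rows, measure_rows = [], []
    for g in spec.groups:
        names, C = _correlation_matrix(g)
        L = np.linalg.cholesky(C)
        z = rng.standard_normal((g.n, len(names))) @ L.T
        means = np.array([g.variables[v]["change"][0] for v in g.variables])
        sds = np.array([g.variables[v]["change"][1] for v in g.variables])
        changes = z * sds + means

        demo = g.demographics or _DEMOGRAPHICS.get(g.name, _DEMOGRAPHICS["MAD"])
        age = rng.normal(*demo["age"], size=g.n)
        weight = np.clip(rng.normal(*demo["weight"], size=g.n), 35.0, None)
        height = np.clip(rng.normal(*demo["height"], size=g.n), 1.3, None)
        sex = np.where(rng.random(g.n) < demo["p_male"], "M", "F")

        for i in range(g.n):
            pid = f"{g.name}{i + 1:03d}"
            mrow = {"patient_id": pid, "group": g.name, "sex": sex[i],
                    "age": round(float(age[i]), 1), "weight": round(float(weight[i]), 1),
                    "height": round(float(height[i]), 2),
                    "bmi": round(float(weight[i] / height[i] ** 2), 2)}
            if g.name == "MAD":
                ahi0 = float(np.clip(rng.normal(30.0, 10.0), 6.0, None))
                frac = float(np.clip(rng.normal(0.30, 0.15), 0.05, 1.2))
                mrow["ahi_t0"] = round(ahi0, 1)
                mrow["ahi_t1"] = round(ahi0 * frac, 1)
            manifest_rows.append(mrow)

            row = {"patient_id": pid, "group": g.name}
            for j, var in enumerate(g.variables):
                t0_spec = g.variables[var]["t0"]
                if t0_spec is not None:
                    t0 = float(rng.normal(*t0_spec))
                    row[f"{var}_t0"] = t0
                    row[f"{var}_t1"] = t0 + float(changes[i, j])
                else:
                    row[var] = float(changes[i, j])
            measure_rows.append(row)
    manifest = pd.DataFrame(manifest_rows)
    measurements = pd.DataFrame(measure_rows)
    return manifest, measurements
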