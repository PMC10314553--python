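"""Orchestration: per-patient measurement and whole-study statistics.

``measure_patient`` runs the geometric chain for one patient — orient T0,
register T1 onto it, measure the airway at both timepoints and the
mandibular change.  ``run_study`` takes a cohort manifest plus per-patient
measurements and reproduces the study's statistical tables: demographics,
airway comparisons (paired within group, unpaired between groups,
age-adjusted ANCOVA), mandibular comparisons, and the per-group correlation
matrix between mandibular displacement and the other changes.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as amio
from .airway import measure_airway
from .errors import AirwayMorphError, ValidationError
from .frames import (apply_transform, build_head_frame, register_landmarks_rigid,
                     register_voxel_rigid)
from .mandible import measure_mandible
from .model import (AIRWAY_LANDMARKS, LandmarkSet, MandibleChange,
                    ORIENTATION_LANDMARKS, RigidTransform, VoxelMask)
from .stats import (ancova_group_age, chi_square_2x2, paired_t,
                    pearson_correlation, student_t)

log = logging.getLogger(__name__)

#: Landmarks used for the deterministic cranial-base rigid fit (treatment
#: does not move them, so they define the common frame).
REGISTRATION_LANDMARKS = ("Ba", "PNS", "PoR", "PoL", "OrR", "OrL")

AIRWAY_VARIABLES = ("total_volume", "total_area", "superior_volume",
                    "superior_area", "inferior_volume", "inferior_area")
MANDIBLE_VARIABLES = ("delta_ap", "delta_si", "ramus_pitch", "anterior_pitch")


@dataclass
class StudyConfig:
    """Options for a study run.

    ``registration``: "landmark" (least-squares fit over cranial-base
    fiducials; deterministic default), "voxel" (mask-based rigid
    registration), "provided" (a transform supplied per patient) or "none"
    (inputs already share a frame, e.g. phantoms).
    """

    manifest: str | Path | None = None
    measurements: str | Path | None = None
    output_dir: str | Path = "study_out"
    registration: str = "landmark"
    welch: bool = False
    icc_model: str = "ICC3"
    lilliefors_reps: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if self.registration not in ("landmark", "voxel", "provided", "none"):
            raise ValidationError(f"unknown registration strategy {self.registration!r}")


class StageError(AirwayMorphError):
    """An error in a named pipeline stage, wrapping the original exception."""

    def __init__(self, stage: str, exc: Exception):
        self.stage = stage
        super().__init__(f"[{stage}] {exc}")


def _stage(name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except AirwayMorphError as exc:
        raise StageError(name, exc) from exc


def measure_patient(t0_mask: VoxelMask, t1_mask: VoxelMask,
                    lm_t0: LandmarkSet, lm_t1: LandmarkSet,
                    config: StudyConfig | None = None,
                    provided_transform: RigidTransform | None = None) -> dict:
    """Measure one patient end-to-end; returns a provenance-carrying record.

    T0 is oriented via its Po/Or landmarks when they are present (otherwise
    the inputs are taken as already oriented); T1 is mapped into the oriented
    T0 frame by the configured registration strategy.  The returned dict
    holds the two airway measurements, the mandibular change, and the
    transforms used.
    """
    config = config or StudyConfig()
    t_start = time.perf_counter()

    # stage: orientation
    if all(n in lm_t0 for n in ("PoR", "PoL")) and \
            any(n in lm_t0 for n in ("OrR", "OrL")):
        frame = _stage("orientation", build_head_frame, lm_t0)
        orient = frame.transform
    else:
        orient = RigidTransform.identity()
    lm_t0_o = lm_t0.transformed(orient, frame_tag="head")
    mask_t0_o = _stage("orientation", apply_transform, t0_mask, orient) \
        if orient.rotation_angle_deg() > 1e-12 or orient.translation_magnitude() > 1e-12 \
        else t0_mask

    # stage: registration (T1 -> oriented T0)
    if config.registration == "landmark":
        shared = [n for n in REGISTRATION_LANDMARKS if n in lm_t1 and n in lm_t0_o]
        reg = _stage("registration", register_landmarks_rigid,
                     lm_t1.subset(shared) if len(shared) >= 3 else lm_t1,
                     lm_t0_o, shared if len(shared) >= 3 else None)
    elif config.registration == "voxel":
        reg = _stage("registration", register_voxel_rigid, mask_t0_o, t1_mask)
    elif config.registration == "provided":
        if provided_transform is None:
            raise StageError("registration", ValidationError(
                "registration='provided' but no transform given"))
        reg = provided_transform
    else:
        reg = RigidTransform.identity()
    lm_t1_o = lm_t1.transformed(reg, frame_tag="head")
    mask_t1_o = _stage("registration", apply_transform, t1_mask, reg) \
        if config.registration != "none" else t1_mask

    # stage: airway measurement
    lm_t0_o.require(AIRWAY_LANDMARKS, "airway measurement (T0)")
    lm_t1_o.require(AIRWAY_LANDMARKS, "airway measurement (T1)")
    airway_t0 = _stage("airway", measure_airway, mask_t0_o, lm_t0_o,
                       lm_t0.patient_id, "T0")
    # regions at T1 are delimited by the registered T0 planes per the common frame
    airway_t1 = _stage("airway", measure_airway, mask_t1_o, lm_t0_o,
                       lm_t0.patient_id, "T1")

    # stage: mandible kinematics
    mandible = _stage("mandible", measure_mandible, lm_t0_o, lm_t1_o)

    return {
        "patient_id": lm_t0.patient_id,
        "airway_t0": airway_t0,
        "airway_t1": airway_t1,
        "mandible": mandible,
        "orientation_transform": orient.as_matrix().tolist(),
        "registration_transform": reg.as_matrix().tolist(),
        "registration_strategy": config.registration,
        "seed": config.seed,
        "elapsed_s": time.perf_counter() - t_start,
    }


def patient_record_row(result: dict) -> dict:
    """Flatten a ``measure_patient`` result into one measurement-table row."""
    row = {"patient_id": result["patient_id"]}
    for tp in ("t0", "t1"):
        m = result[f"airway_{tp}"]
        for var in AIRWAY_VARIABLES:
            row[f"{var}_{tp}"] = getattr(m, var)
    md: MandibleChange = result["mandible"]
    row.update({"delta_ap": md.delta_ap, "delta_si": md.delta_si,
                "ramus_pitch": md.ramus_pitch_mean,
                "ramus_pitch_R": md.ramus_pitch_R, "ramus_pitch_L": md.ramus_pitch_L,
                "anterior_pitch": md.anterior_pitch_mean,
                "anterior_pitch_R": md.anterior_pitch_R,
                "anterior_pitch_L": md.anterior_pitch_L})
    return row


# ---------------------------------------------------------------------------
# study-level statistics


def _fmt_mean_sd(x: np.ndarray) -> str:
    return f"{np.mean(x):.2f} ± {np.std(x, ddof=1):.2f}"


def demographics_table(manifest: pd.DataFrame) -> pd.DataFrame:
    """Between-group demographics: t tests for the continuous variables,
    chi-square for the sex split."""
    groups = sorted(manifest["group"].unique())
    if len(groups) != 2:
        raise ValidationError(f"demographics table needs two groups, got {groups}")
    a = manifest[manifest["group"] == groups[0]]
    b = manifest[manifest["group"] == groups[1]]
    rows = []
    counts = np.array([[int((g["sex"] == "M").sum()), int((g["sex"] == "F").sum())]
                       for g in (a, b)])
    chi = chi_square_2x2(counts)
    rows.append({"variable": "sex (M/F)",
                 groups[0]: f"{counts[0, 0]}/{counts[0, 1]}",
                 groups[1]: f"{counts[1, 0]}/{counts[1, 1]}",
                 "test": "chi_square", "p": chi.p})
    for var in ("age", "weight", "height", "bmi"):
        res = student_t(a[var].to_numpy(), b[var].to_numpy())
        rows.append({"variable": var, groups[0]: _fmt_mean_sd(a[var]),
                     groups[1]: _fmt_mean_sd(b[var]), "test": res.test, "p": res.p})
    return pd.DataFrame(rows)


def airway_table(manifest: pd.DataFrame, measurements: pd.DataFrame,
                 welch: bool = False) -> pd.DataFrame:
    """Airway comparisons shaped like the study's volumetric table.

    Per variable and timepoint: group mean ± SD, unpaired between-group t
    (p_between), age-adjusted ANCOVA p_age/p_group; per variable and group:
    paired T0-vs-T1 t (p_paired).
    """
    df = measurements.merge(manifest[["patient_id", "group", "age"]], on="patient_id",
                            suffixes=("", "_manifest"))
    if "group_manifest" in df:
        df["group"] = df["group"].fillna(df["group_manifest"])
    groups = sorted(df["group"].unique())
    rows = []
    for var in AIRWAY_VARIABLES:
        cols = (f"{var}_t0", f"{var}_t1")
        if not all(c in df.columns for c in cols):
            continue
        sub = {g: df[df["group"] == g] for g in groups}
        paired = {g: paired_t(sub[g][cols[0]].to_numpy(), sub[g][cols[1]].to_numpy()).p
                  for g in groups}
        for tp, col in zip(("T0", "T1"), cols):
            res = student_t(sub[groups[0]][col].to_numpy(), sub[groups[1]][col].to_numpy(),
                            welch=welch)
            p_age, p_group = ancova_group_age(df[col], df["group"], df["age"])
            rows.append({
                "variable": var, "timepoint": tp,
                groups[0]: _fmt_mean_sd(sub[groups[0]][col]),
                groups[1]: _fmt_mean_sd(sub[groups[1]][col]),
                "p_between": res.p,
                f"p_paired_{groups[0]}": paired[groups[0]],
                f"p_paired_{groups[1]}": paired[groups[1]],
                "p_age": p_age, "p_group": p_group,
            })
    return pd.DataFrame(rows)


def mandible_table(manifest: pd.DataFrame, measurements: pd.DataFrame,
                   welch: bool = False) -> pd.DataFrame:
    """Mandibular change comparisons: between-group t and ANCOVA per variable."""
    df = _with_mandible_columns(measurements).merge(
        manifest[["patient_id", "group", "age"]], on="patient_id", suffixes=("", "_m"))
    groups = sorted(df["group"].unique())
    rows = []
    for var in MANDIBLE_VARIABLES:
        if var not in df.columns:
            continue
        sub = {g: df[df["group"] == g][var].to_numpy() for g in groups}
        res = student_t(sub[groups[0]], sub[groups[1]], welch=welch)
        p_age, p_group = ancova_group_age(df[var], df["group"], df["age"])
        rows.append({"variable": var,
                     groups[0]: _fmt_mean_sd(sub[groups[0]]),
                     groups[1]: _fmt_mean_sd(sub[groups[1]]),
                     "p_between": res.p, "p_age": p_age, "p_group": p_group})
    return pd.DataFrame(rows)


def correlation_table(measurements: pd.DataFrame,
                      group_col: pd.Series | None = None) -> pd.DataFrame:
    """Per-group correlations of the change variables with B-point displacement."""
    df = _with_mandible_columns(measurements)
    targets = []
    for var in ("superior_volume", "inferior_volume"):
        if f"{var}_t0" in df.columns and f"{var}_t1" in df.columns:
            df[f"d_{var}"] = df[f"{var}_t1"] - df[f"{var}_t0"]
            targets.append(f"d_{var}")
    targets += [v for v in ("ramus_pitch", "anterior_pitch") if v in df.columns]
    rows = []
    for group, sub in df.groupby("group"):
        for target in targets:
            for against in ("delta_ap", "delta_si"):
                if against not in sub.columns:
                    continue
                res = pearson_correlation(sub[against].to_numpy(), sub[target].to_numpy())
                rows.append({"group": group, "variable": target, "against": against,
                             "r": res.estimate, "p": res.p, "n": res.n[0]})
    return pd.DataFrame(rows)


def _with_mandible_columns(measurements: pd.DataFrame) -> pd.DataFrame:
    df = measurements.copy()
    for var in ("ramus_pitch", "anterior_pitch"):
        if var not in df.columns and f"{var}_mean" in df.columns:
            df[var] = df[f"{var}_mean"]
    return df


def run_study(config: StudyConfig,
              manifest: pd.DataFrame | None = None,
              measurements: pd.DataFrame | None = None) -> dict[str, pd.DataFrame]:
    """Produce the full study report from a manifest and measurements.

    ``manifest``/``measurements`` can be passed directly or read from the
    paths in ``config``; when the manifest carries per-patient mask and
    landmark file paths and no measurement table is given, each patient is
    measured from the image data first.  Tables are written to
    ``config.output_dir`` as CSV plus a JSON mirror.
    """
    if manifest is None:
        if config.manifest is None:
            raise ValidationError("no manifest given")
        manifest = amio.read_cohort_manifest(config.manifest)
    counts = manifest["group"].value_counts()
    if (counts < 2).any() or len(counts) < 2:
        raise ValidationError(f"each group needs >= 2 patients, got {counts.to_dict()}")

    if measurements is None:
        if config.measurements is not None:
            measurements = amio.read_measurements(config.measurements)
        else:
            measurements = _measure_cohort(manifest, config)

    missing = [c for c in ("patient_id",) if c not in measurements.columns]
    if missing:
        raise ValidationError(f"measurement table missing columns {missing}")
    if "group" not in measurements.columns:
        measurements = measurements.merge(manifest[["patient_id", "group"]], on="patient_id")

    report = {
        "demographics": demographics_table(manifest),
        "airway": airway_table(manifest, measurements, welch=config.welch),
        "mandible": mandible_table(manifest, measurements, welch=config.welch),
        "correlations": correlation_table(measurements),
    }
    n_tests = int(sum(len(t.filter(regex="^p").columns) * len(t) for t in report.values()))
    log.info("study report: %d hypothesis tests, no multiplicity correction applied", n_tests)

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    mirror = {}
    for name, table in report.items():
        table.to_csv(outdir / f"{name}.csv", index=False)
        mirror[name] = json.loads(table.to_json(orient="records"))
    mirror["meta"] = {"n_tests": n_tests, "registration": config.registration,
                      "seed": config.seed, "alpha": 0.05}
    (outdir / "report.json").write_text(json.dumps(mirror, indent=2) + "\n")
    return report


def _measure_cohort(manifest: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    needed = {"mask_t0", "mask_t1", "landmarks_t0", "landmarks_t1"}
    if not needed.issubset(manifest.columns):
        raise ValidationError(
            f"manifest lacks measurement columns and file-path columns {sorted(needed)}")
    rows = []
    for _, r in manifest.iterrows():
        t0_mask = amio.read_mask(r["mask_t0"])
        t1_mask = amio.read_mask(r["mask_t1"])
        lm_t0 = amio.read_landmarks(r["landmarks_t0"], patient_id=r["patient_id"],
                                    timepoint="T0")
        lm_t1 = amio.read_landmarks(r["landmarks_t1"], patient_id=r["patient_id"],
                                    timepoint="T1")
        result = measure_patient(t0_mask, t1_mask, lm_t0, lm_t1, config)
        row = patient_record_row(result)
        row["group"] = r["group"]
        rows.append(row)
        log.info("measured patient %s in %.1fs", r["patient_id"], result["elapsed_s"])
    return pd.DataFrame(rows)
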