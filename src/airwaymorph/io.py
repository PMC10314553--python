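"""Readers and writers for the on-disk formats.

Masks arrive as NIfTI (.nii/.nii.gz), fiducials as 3D Slicer FCSV or markups
JSON, cohort manifests and result tables as CSV (with a JSON mirror for the
latter).  Every reader normalizes into the internal RAS-millimetre world
frame, so the rest of the package never sees LPS coordinates or non-canonical
voxel orderings.
"""
from __future__ import annotations

import csv
import json
import logging
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .errors import EmptySegmentationError, FormatError, ValidationError
from .model import LandmarkSet, VoxelMask

log = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# landmark name aliases

#: Default mapping from free-text Slicer fiducial labels to canonical names.
#: Users can extend/override it with a YAML file via :func:`load_alias_table`.
DEFAULT_ALIASES: dict[str, str] = {
    "basion": "Ba", "ba": "Ba",
    "pns": "PNS", "posterior nasal spine": "PNS",
    "c2i": "C2I", "c2 inferior": "C2I",
    "c4s": "C4S", "c4 superior": "C4S",
    "b": "B", "b point": "B", "b-point": "B", "point b": "B",
    "cor": "CoR", "condylion r": "CoR", "condylion right": "CoR", "co r": "CoR",
    "col": "CoL", "condylion l": "CoL", "condylion left": "CoL", "co l": "CoL",
    "gor": "GoR", "gonion r": "GoR", "gonion right": "GoR", "go r": "GoR",
    "gol": "GoL", "gonion l": "GoL", "gonion left": "GoL", "go l": "GoL",
    "por": "PoR", "porion r": "PoR", "porion right": "PoR", "po r": "PoR",
    "pol": "PoL", "porion l": "PoL", "porion left": "PoL", "po l": "PoL",
    "orr": "OrR", "orbitale r": "OrR", "orbitale right": "OrR", "or r": "OrR",
    "orl": "OrL", "orbitale l": "OrL", "orbitale left": "OrL", "or l": "OrL",
}


def load_alias_table(path: str | Path | None = None) -> dict[str, str]:
    """Return the landmark alias table, optionally extended from a YAML file.

    The YAML file maps free-text labels to canonical names and takes
    precedence over the built-in defaults.
    """
    table = dict(DEFAULT_ALIASES)
    if path is not None:
        with open(path) as fh:
            extra = yaml.safe_load(fh) or {}
        if not isinstance(extra, dict):
            raise FormatError(f"alias table {path} must be a mapping")
        table.update({str(k).strip().lower(): str(v) for k, v in extra.items()})
    return table


def canonical_name(label: str, aliases: Mapping[str, str] | None = None) -> str:
    aliases = aliases if aliases is not None else DEFAULT_ALIASES
    key = label.strip().lower()
    return aliases.get(key, label.strip())


# ---------------------------------------------------------------------------
# masks


def read_mask(path: str | Path) -> VoxelMask:
    """Load a binary NIfTI segmentation as a :class:`VoxelMask` in RAS.

    The image is reoriented to canonical RAS axis order, the data thresholded
    at 0.5, and the affine taken as the voxel-centre → world map.  Raises
    :class:`FormatError` for unreadable files and
    :class:`EmptySegmentationError` when no voxel is foreground.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got shape {data.shape}")
    grid = (np.nan_to_num(np.asarray(data, dtype=float)) > 0.5).astype(np.uint8)
    if grid.sum() == 0:
        raise EmptySegmentationError(f"{path}: segmentation contains no foreground voxels")
    return VoxelMask(grid=grid, affine=np.asarray(img.affine, dtype=float))


def write_mask(mask: VoxelMask, path: str | Path) -> None:
    """Save a :class:`VoxelMask` as NIfTI (uint8 data, RAS affine)."""
    img = nib.Nifti1Image(mask.grid.astype(np.uint8), mask.affine)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# fiducials

_FCSV_MAGIC = "# Markups fiducial file version"


def read_landmarks(path: str | Path, aliases: Mapping[str, str] | None = None,
                   patient_id: str = "", timepoint: str = "T0") -> LandmarkSet:
    """Read a Slicer FCSV or markups-JSON fiducial file into RAS mm.

    The file's declared coordinate system is honoured: LPS coordinates are
    converted by flipping the signs of X and Y.  Labels are normalized via
    the alias table; duplicate canonical names are an error.
    """
    path = Path(path)
    if path.suffix.lower() == ".json" or path.name.lower().endswith(".mrk.json"):
        raw = _read_markups_json(path)
    else:
        raw = _read_fcsv(path)
    points: dict[str, np.ndarray] = {}
    for label, xyz in raw:
        name = canonical_name(label, aliases)
        if name in points:
            raise ValidationError(f"{path}: duplicate landmark {name!r} (label {label!r})")
        points[name] = xyz
    return LandmarkSet(points=points, frame_tag="scanner-RAS",
                       patient_id=patient_id, timepoint=timepoint)


def _read_fcsv(path: Path) -> list[tuple[str, np.ndarray]]:
    try:
        lines = path.read_text().splitlines()
    except OSError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    if not lines or not lines[0].startswith(_FCSV_MAGIC):
        raise FormatError(f"{path}: missing FCSV header {_FCSV_MAGIC!r}")
    lps = False  # Slicer default for FCSV without a CoordinateSystem line is RAS (0)
    rows: list[tuple[str, np.ndarray]] = []
    for line in lines:
        if line.startswith("#"):
            if "CoordinateSystem" in line:
                val = line.split("=")[-1].strip().lower()
                lps = val in ("1", "lps")
            continue
        if not line.strip():
            continue
        cols = line.split(",")
        if len(cols) < 12:
            raise FormatError(f"{path}: malformed FCSV row {line!r}")
        try:
            xyz = np.array([float(cols[1]), float(cols[2]), float(cols[3])])
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric coordinates in {line!r}") from exc
        label = cols[11].strip() or cols[0].strip()
        if lps:
            xyz = xyz * np.array([-1.0, -1.0, 1.0])
        rows.append((label, xyz))
    return rows


def _read_markups_json(path: Path) -> list[tuple[str, np.ndarray]]:
    try:
        doc = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot read markups JSON {path}: {exc}") from exc
    rows: list[tuple[str, np.ndarray]] = []
    markups = doc.get("markups", [])
    if not markups:
        raise FormatError(f"{path}: no markups in file")
    for markup in markups:
        system = str(markup.get("coordinateSystem", "LPS")).upper()
        if system not in ("RAS", "LPS"):
            raise FormatError(f"{path}: unknown coordinateSystem {system!r}")
        flip = np.array([-1.0, -1.0, 1.0]) if system == "LPS" else np.ones(3)
        for cp in markup.get("controlPoints", []):
            xyz = np.asarray(cp["position"], dtype=float) * flip
            rows.append((str(cp.get("label", "")), xyz))
    return rows


def write_landmarks_fcsv(lm: LandmarkSet, path: str | Path,
                         coordinate_system: str = "RAS") -> None:
    """Write a landmark set as a Slicer FCSV file in RAS or LPS dialect."""
    coordinate_system = coordinate_system.upper()
    if coordinate_system not in ("RAS", "LPS"):
        raise ValidationError("coordinate_system must be RAS or LPS")
    flip = np.array([-1.0, -1.0, 1.0]) if coordinate_system == "LPS" else np.ones(3)
    lines = [
        f"{_FCSV_MAGIC} = 4.11",
        f"# CoordinateSystem = {coordinate_system}",
        "# columns = id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,associatedNodeID",
    ]
    for i, (name, p) in enumerate(lm.points.items(), start=1):
        q = p * flip
        lines.append(f"vtkMRMLMarkupsFiducialNode_{i},{q[0]:.6f},{q[1]:.6f},{q[2]:.6f},"
                     f"0,0,0,1,1,1,0,{name},,")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# cohort manifest

REQUIRED_MANIFEST_COLUMNS = ("patient_id", "group", "sex", "age", "weight", "height", "bmi")
VALID_GROUPS = ("MAD", "MMA")


def read_cohort_manifest(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort manifest CSV.

    Required columns: patient_id, group (MAD/MMA), sex (M/F), age (yr),
    weight (kg), height (m), bmi (kg/m²).  Optional: ahi_t0, ahi_t1 and
    per-timepoint mask/landmark file paths.  BMI is cross-checked against
    weight/height to within 5% and a warning logged on mismatch.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"cannot read manifest {path}: {exc}") from exc
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in REQUIRED_MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: manifest missing columns {missing}")
    if df["patient_id"].duplicated().any():
        dups = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValidationError(f"{path}: duplicated patient_id {dups}")
    bad = set(df["group"]) - set(VALID_GROUPS)
    if bad:
        raise ValidationError(f"{path}: unknown group labels {sorted(bad)}; expected {VALID_GROUPS}")
    bad_sex = set(df["sex"]) - {"M", "F"}
    if bad_sex:
        raise ValidationError(f"{path}: unknown sex labels {sorted(bad_sex)}")
    for col in ("age", "weight", "height", "bmi"):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"{path}: non-numeric values in column {col!r}") from exc
    ok = np.isfinite(df[["weight", "height", "bmi"]]).all(axis=1)
    computed = df.loc[ok, "weight"] / df.loc[ok, "height"] ** 2
    rel = np.abs(df.loc[ok, "bmi"] - computed) / computed
    for pid, r, c, stated in zip(df.loc[ok, "patient_id"], rel, computed, df.loc[ok, "bmi"]):
        if r > 0.05:
            log.warning("manifest %s: patient %s BMI %.1f inconsistent with weight/height "
                        "(computed %.1f)", path.name, pid, stated, c)
    counts = df["group"].value_counts().to_dict()
    log.info("manifest %s: group counts %s", path.name, counts)
    return df


# ---------------------------------------------------------------------------
# measurement tables


def write_measurements(records: Sequence[Mapping], path: str | Path) -> None:
    """Write per-patient measurement rows as CSV with a JSON mirror.

    ``path`` names the CSV; a sibling ``.json`` file with identical content
    is written next to it.  NaN values serialize as empty CSV cells / JSON
    nulls and read back as missing.
    """
    path = Path(path)
    records = list(records)
    if records:
        keys = list(records[0].keys())
        for r in records:
            if list(r.keys()) != keys:
                raise ValidationError("measurement records are not homogeneous")
    df = pd.DataFrame.from_records(records)
    try:
        df.to_csv(path, index=False)
    except OSError as exc:
        raise ValidationError(f"cannot write {path}: {exc}") from exc
    clean = [{k: (None if isinstance(v, float) and math.isnan(v) else v)
              for k, v in r.items()} for r in records]
    path.with_suffix(".json").write_text(json.dumps(clean, indent=2) + "\n")


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read back a measurement CSV written by :func:`write_measurements`."""
    try:
        return pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()
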