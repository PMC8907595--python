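"""CSV/YAML input-output.

Annotation CSV schema (one row per photograph, UTF-8, header required,
decimal point):

    rat_id, group, day, lcx, lcy, rcx, rcy, nx, ny, outline, img_w, img_h

where ``outline`` is a semicolon-separated ``x:y`` vertex list.  Floats
are written with shortest round-trip precision, so write→read is exact.

Calibration / cohort configuration lives in a small YAML file, e.g. ::

    calibration:
      le_ref: 300.0          # omit (or null) to derive from the cohort
      h1_ref: 350.0
      rotation_exponent: 1.0
      reference_policy: median   # median | mean | explicit
    cohort:
      n_control: 6
      n_model: 5
      ...

Readers are lenient by default (malformed rows are returned as
line-numbered diagnostics); the CLI switches them to strict.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .calibration import CalibratedMeasurement
from .errors import RowParseError, SchemaError
from .geometry import FaceAnnotation, FaceMeasurement
from .study import CohortConfig, TrajectoryParams
from .synthetic import CameraModel, HeadModel3D

__all__ = [
    "ANNOTATION_COLUMNS",
    "read_annotations",
    "write_annotations",
    "write_measurements",
    "read_measurements",
    "write_calibrated",
    "load_config",
]

ANNOTATION_COLUMNS = (
    "rat_id",
    "group",
    "day",
    "lcx",
    "lcy",
    "rcx",
    "rcy",
    "nx",
    "ny",
    "outline",
    "img_w",
    "img_h",
)

MEASUREMENT_COLUMNS = ("rat_id", "group", "day", "S", "Le", "H1", "H2")


def _fmt(x: float) -> str:
    return repr(float(x))


def _serialize_outline(outline: np.ndarray) -> str:
    return ";".join(f"{_fmt(x)}:{_fmt(y)}" for x, y in np.asarray(outline, dtype=float))


def _parse_outline(text: str) -> np.ndarray:
    verts = []
    for tok in text.strip().split(";"):
        if not tok:
            continue
        try:
            xs, ys = tok.split(":")
            verts.append((float(xs), float(ys)))
        except ValueError:
            raise ValueError(f"malformed outline vertex {tok!r}") from None
    if len(verts) < 3:
        raise ValueError(f"outline has {len(verts)} vertices, need >= 3")
    return np.array(verts, dtype=float)


def write_annotations(annotations: Iterable[FaceAnnotation], path) -> Path:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(ANNOTATION_COLUMNS)
        for a in annotations:
            w.writerow(
                [
                    a.rat_id,
                    a.group,
                    a.day,
                    _fmt(a.left_canthus.x),
                    _fmt(a.left_canthus.y),
                    _fmt(a.right_canthus.x),
                    _fmt(a.right_canthus.y),
                    _fmt(a.nose_tip.x),
                    _fmt(a.nose_tip.y),
                    _serialize_outline(a.outline),
                    a.image_size[0],
                    a.image_size[1],
                ]
            )
    return path


def read_annotations(
    path, strict: bool = False
) -> tuple[list[FaceAnnotation], list[RowParseError]]:
    """Parse an annotation CSV; row order is preserved.

    Lenient mode (default) returns ``(annotations, diagnostics)`` where
    each diagnostic carries the 1-based line number of a malformed row;
    strict mode raises on the first malformed row.  A missing column is
    always a SchemaError naming the column; a header-only file yields an
    empty list with a warning.
    """
    path = Path(path)
    annotations: list[FaceAnnotation] = []
    errors: list[RowParseError] = []
    with path.open("r", newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, expected header {ANNOTATION_COLUMNS}")
        missing = [c for c in ANNOTATION_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
        for row in reader:
            line = reader.line_num
            try:
                annotations.append(_parse_row(row))
            except (ValueError, TypeError, KeyError) as e:
                err = RowParseError(line, str(e))
                if strict:
                    raise err from e
                errors.append(err)
    if not annotations and not errors:
        warnings.warn(f"{path}: no annotation rows found", stacklevel=2)
    return annotations, errors


def _parse_row(row: dict) -> FaceAnnotation:
    for col in ANNOTATION_COLUMNS:
        if row.get(col) in (None, ""):
            raise ValueError(f"missing value in column {col!r}")
    return FaceAnnotation(
        rat_id=row["rat_id"],
        group=row["group"],
        day=int(row["day"]),
        left_canthus=(float(row["lcx"]), float(row["lcy"])),
        right_canthus=(float(row["rcx"]), float(row["rcy"])),
        nose_tip=(float(row["nx"]), float(row["ny"])),
        outline=_parse_outline(row["outline"]),
        image_size=(int(row["img_w"]), int(row["img_h"])),
    )


def write_measurements(measurements: Iterable[FaceMeasurement], path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [(m.rat_id, m.group, m.day, m.S, m.Le, m.H1, m.H2) for m in measurements],
        columns=list(MEASUREMENT_COLUMNS),
    )
    df.to_csv(path, index=False)
    return path


def read_measurements(path) -> list[FaceMeasurement]:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    return [
        FaceMeasurement(
            rat_id=str(r.rat_id),
            group=str(r.group),
            day=int(r.day),
            S=float(r.S),
            Le=float(r.Le),
            H1=float(r.H1),
            H2=float(r.H2),
        )
        for r in df.itertuples()
    ]


def write_calibrated(calibrated: Iterable[CalibratedMeasurement], path) -> Path:
    path = Path(path)
    df = pd.DataFrame([c.__dict__ for c in calibrated])
    df.to_csv(path, index=False)
    return path


# --------------------------------------------------------------------------
# configuration


def load_config(path) -> dict:
    """Load the YAML run configuration into plain keyword dictionaries.

    Returns ``{"calibration": {...}, "cohort": CohortConfig}`` with
    defaults filled in for anything omitted.  Unknown keys raise
    SchemaError so typos fail loudly.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: top level must be a mapping")
    unknown = set(raw) - {"calibration", "cohort"}
    if unknown:
        raise SchemaError(f"{path}: unknown top-level key(s) {sorted(unknown)}")
    cal = raw.get("calibration") or {}
    allowed_cal = {"le_ref", "h1_ref", "rotation_exponent", "reference_policy"}
    unknown = set(cal) - allowed_cal
    if unknown:
        raise SchemaError(f"{path}: unknown calibration key(s) {sorted(unknown)}")
    cal = {
        "le_ref": cal.get("le_ref"),
        "h1_ref": cal.get("h1_ref"),
        "rotation_exponent": float(cal.get("rotation_exponent", 1.0)),
        "reference_policy": cal.get("reference_policy", "median"),
    }
    cohort = _cohort_from_mapping(raw.get("cohort") or {}, path)
    return {"calibration": cal, "cohort": cohort}


_COHORT_SCALARS = {
    "n_control",
    "n_model",
    "n_positive",
    "n_model_phase1",
    "days",
    "z_ref",
    "sigma_z",
    "sigma_pose_deg",
    "jitter_sd",
    "reference_policy",
    "gamma_policy",
    "rotation_exponent",
    "seed",
}


def _cohort_from_mapping(m: dict, path) -> CohortConfig:
    unknown = set(m) - _COHORT_SCALARS - {"trajectory", "head", "camera"}
    if unknown:
        raise SchemaError(f"{path}: unknown cohort key(s) {sorted(unknown)}")
    kwargs = {k: m[k] for k in _COHORT_SCALARS if k in m}
    if "days" in kwargs:
        kwargs["days"] = tuple(int(d) for d in kwargs["days"])
    try:
        if "trajectory" in m:
            kwargs["trajectory"] = TrajectoryParams(**m["trajectory"])
        if "head" in m:
            kwargs["head"] = HeadModel3D(**_tupled(m["head"], "outline_semiaxes"))
        if "camera" in m:
            kwargs["camera"] = CameraModel(**_tupled(m["camera"], "image_size"))
        return CohortConfig(**kwargs)
    except (TypeError, ValueError) as e:
        raise SchemaError(f"{path}: {e}") from e


def _tupled(d: dict, key: str) -> dict:
    d = dict(d)
    if key in d:
        d[key] = tuple(d[key])
    return d
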