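"""Readers and writers for landmark and results files.

CSV is the canonical interchange format (spreadsheet-compatible, matching how
digitization data is typically shared); JSON mirrors it record-for-record for
programmatic use, and ``.xlsx`` files with the same column layout are read
through openpyxl.  Coordinates in files are raw image pixels (y down) so the
stored data stays faithful to the digitization tool — every frame convention
is applied only during normalization.

Landmark schema (one row per eye per rater)::

    subject_id, rater_id, laterality,
    bez_0_x_px, bez_0_y_px, ..., bez_3_x_px, bez_3_y_px,
    limbus_a_x_px, limbus_a_y_px, limbus_b_x_px, limbus_b_y_px,
    pupil_x_px, pupil_y_px
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .frame import LandmarkSet
from .metrics import CANONICAL_ANGLES_DEG, TN_RATIO_PAIRS, EyelidMetrics

__all__ = [
    "LANDMARK_COLUMNS",
    "read_landmarks",
    "write_landmarks",
    "metrics_to_frame",
    "mpld_long_frame",
    "write_metrics",
    "write_reliability_report",
]

_BEZ_COLS = [f"bez_{i}_{ax}_px" for i in range(4) for ax in ("x", "y")]
_POINT_COLS = _BEZ_COLS + [
    "limbus_a_x_px",
    "limbus_a_y_px",
    "limbus_b_x_px",
    "limbus_b_y_px",
    "pupil_x_px",
    "pupil_y_px",
]
LANDMARK_COLUMNS = ["subject_id", "rater_id", "laterality"] + _POINT_COLS


def _row_to_landmarks(row: pd.Series, row_label: str) -> LandmarkSet:
    try:
        vals = {c: float(row[c]) for c in _POINT_COLS}
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{row_label}: non-numeric coordinate ({exc})") from exc
    lat = str(row["laterality"]).strip()
    if lat not in ("OD", "OS"):
        raise ValidationError(f"{row_label}: unknown laterality {lat!r}")
    bez = np.array(
        [[vals[f"bez_{i}_x_px"], vals[f"bez_{i}_y_px"]] for i in range(4)]
    )
    try:
        return LandmarkSet(
            bezier_px=bez,
            limbus_a_px=np.array([vals["limbus_a_x_px"], vals["limbus_a_y_px"]]),
            limbus_b_px=np.array([vals["limbus_b_x_px"], vals["limbus_b_y_px"]]),
            pupil_px=np.array([vals["pupil_x_px"], vals["pupil_y_px"]]),
            laterality=lat,  # type: ignore[arg-type]
            subject_id=str(row["subject_id"]),
            rater_id=str(row["rater_id"]),
        )
    except ValidationError as exc:
        raise ValidationError(f"{row_label}: {exc}") from exc


def read_landmarks(path: str | Path) -> list[LandmarkSet]:
    """Read a landmark file (.csv, .json or .xlsx) into validated records.

    Errors name the offending row (by subject/rater when available) and
    column, so a bad cell in a large digitization table is findable.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".csv":
        df = pd.read_csv(path)
    elif suffix == ".json":
        df = pd.DataFrame(json.loads(path.read_text()))
    elif suffix == ".xlsx":
        df = pd.read_excel(path)
    else:
        raise ValidationError(f"unsupported landmark format {suffix!r}")
    missing = [c for c in LANDMARK_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing column(s) {', '.join(missing)}")
    records = []
    for idx, row in df.iterrows():
        label = f"{path.name} row {idx} (subject {row.get('subject_id', '?')})"
        records.append(_row_to_landmarks(row, label))
    return records


def _landmarks_to_frame(records: Iterable[LandmarkSet]) -> pd.DataFrame:
    rows = []
    for lm in records:
        row: dict[str, object] = {
            "subject_id": lm.subject_id,
            "rater_id": lm.rater_id,
            "laterality": lm.laterality,
        }
        for i in range(4):
            row[f"bez_{i}_x_px"] = lm.bezier_px[i, 0]
            row[f"bez_{i}_y_px"] = lm.bezier_px[i, 1]
        row["limbus_a_x_px"], row["limbus_a_y_px"] = lm.limbus_a_px
        row["limbus_b_x_px"], row["limbus_b_y_px"] = lm.limbus_b_px
        row["pupil_x_px"], row["pupil_y_px"] = lm.pupil_px
        rows.append(row)
    return pd.DataFrame(rows, columns=LANDMARK_COLUMNS)


def write_landmarks(records: Sequence[LandmarkSet], path: str | Path) -> None:
    """Write landmark records to .csv or .json (format from the suffix)."""
    path = Path(path)
    df = _landmarks_to_frame(records)
    if path.suffix.lower() == ".csv":
        df.to_csv(path, index=False)
    elif path.suffix.lower() == ".json":
        path.write_text(json.dumps(df.to_dict(orient="records"), indent=1) + "\n")
    else:
        raise ValidationError(f"unsupported landmark format {path.suffix!r}")


def _angle_col(angle: float) -> str:
    return f"mpld_{angle:g}_mm"


def metrics_to_frame(
    metrics: Sequence[EyelidMetrics], precision: int | None = None
) -> pd.DataFrame:
    """Wide table: one row per eye, scalar metrics + MPLD columns + ratios.

    ``precision`` rounds the numeric display (2 decimals matches how such
    cohort tables are conventionally reported); ``None`` keeps full
    precision.
    """
    if not metrics:
        raise ValidationError("no metrics to tabulate")
    rows = []
    for m in metrics:
        row: dict[str, object] = {
            "subject_id": m.subject_id,
            "rater_id": m.rater_id,
            "laterality": m.laterality,
            "eye_width_mm": m.eye_width_mm,
            "mrd1_mm": m.mrd1_mm,
            "peak_temporal_offset_mm": m.peak_temporal_offset_mm,
            "peak_height_mm": m.peak_height_mm,
            "fissure_obliquity_deg": m.fissure_obliquity_deg,
        }
        for a in m.mpld.angles:
            row[_angle_col(a)] = m.mpld[a]
        for tem, nas in TN_RATIO_PAIRS:
            if (tem, nas) in m.tn_ratios.ratios:
                row[f"ratio_{tem:g}_{nas:g}"] = m.tn_ratios[(tem, nas)]
        row["ratio_total"] = m.tn_ratios.ratio_total
        row["ratio_total_definition"] = m.tn_ratios.definition
        rows.append(row)
    df = pd.DataFrame(rows)
    if precision is not None:
        num = df.select_dtypes(include="number").columns
        df[num] = df[num].round(precision)
    return df


def mpld_long_frame(metrics: Sequence[EyelidMetrics]) -> pd.DataFrame:
    """Long table: one row per (eye, angle) for plotting/statistics."""
    rows = [
        {
            "subject_id": m.subject_id,
            "rater_id": m.rater_id,
            "laterality": m.laterality,
            "angle_deg": a,
            "mpld_mm": m.mpld[a],
        }
        for m in metrics
        for a in m.mpld.angles
    ]
    return pd.DataFrame(rows)


def write_metrics(
    metrics: Sequence[EyelidMetrics],
    path: str | Path,
    long_path: str | Path | None = None,
    precision: int | None = 2,
) -> None:
    """Write the wide metrics CSV (and optionally the long MPLD CSV).

    Values display at 2 decimals by default; pass ``precision=None`` for the
    full-precision sidecar.
    """
    metrics_to_frame(metrics, precision=precision).to_csv(path, index=False)
    if long_path is not None:
        df = mpld_long_frame(metrics)
        if precision is not None:
            df["mpld_mm"] = df["mpld_mm"].round(precision)
        df.to_csv(long_path, index=False)


def write_reliability_report(report: dict, path: str | Path) -> None:
    """Serialize a reliability report (ICC forms, Bland-Altman) as JSON."""
    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(report, indent=1, default=_default) + "\n")
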