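"""CSV interchange formats.

Landmark CSV: one row per case x rater with columns
``case_id, rater_id, b1x, b1y, b2x, b2y[, b3x, b3y, ...], ios_x, ios_y,
eos_x, eos_y[, prom_x, prom_y, symph_x, symph_y]``.
Units are millimetres in the mid-sagittal plane; back points are listed
cranial → caudal; conjugate columns are optional and empty cells mark
missing optional landmarks.

Labels CSV: ``case_id, adhesion, ga_weeks`` (adhesion in {0, 1}, GA in
decimal weeks) plus optional strata columns such as ``pas``.

Measurement CSV: ``case_id, n_raters, angle_deg, version``.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .measurement import SagittalLandmarks

__all__ = [
    "LANDMARK_FIXED_COLUMNS",
    "CONJUGATE_COLUMNS",
    "LABEL_COLUMNS",
    "landmarks_to_frame",
    "frame_to_landmarks",
    "read_landmarks_csv",
    "write_landmarks_csv",
    "read_labels_csv",
    "write_labels_csv",
    "write_measurements_csv",
    "read_measurements_csv",
]

LANDMARK_FIXED_COLUMNS = ["case_id", "rater_id", "ios_x", "ios_y", "eos_x", "eos_y"]
CONJUGATE_COLUMNS = ["prom_x", "prom_y", "symph_x", "symph_y"]
LABEL_COLUMNS = ["case_id", "adhesion", "ga_weeks"]

_BACK_COL_RE = re.compile(r"^b(\d+)([xy])$")


def landmarks_to_frame(landmark_sets: Sequence[SagittalLandmarks]) -> pd.DataFrame:
    """Wide one-row-per-rater frame; unused back columns are left empty."""
    sets = list(landmark_sets)
    if not sets:
        raise ValueError("no landmark sets to write")
    max_back = max(ls.back_points.shape[0] for ls in sets)
    back_cols = [f"b{i}{ax}" for i in range(1, max_back + 1) for ax in ("x", "y")]
    columns = ["case_id", "rater_id"] + back_cols + [
        "ios_x", "ios_y", "eos_x", "eos_y",
    ] + CONJUGATE_COLUMNS
    rows = []
    for ls in sets:
        row: dict[str, object] = {"case_id": ls.case_id, "rater_id": ls.rater_id}
        for i, (x, y) in enumerate(ls.back_points, start=1):
            row[f"b{i}x"] = x
            row[f"b{i}y"] = y
        row["ios_x"], row["ios_y"] = ls.internal_os
        row["eos_x"], row["eos_y"] = ls.external_os
        if ls.has_conjugate:
            row["prom_x"], row["prom_y"] = ls.promontory
            row["symph_x"], row["symph_y"] = ls.symphysis
        rows.append(row)
    return pd.DataFrame(rows, columns=columns)


def _row_to_landmarks(row: pd.Series) -> SagittalLandmarks:
    back = []
    i = 1
    while f"b{i}x" in row.index:
        x, y = row.get(f"b{i}x"), row.get(f"b{i}y")
        if pd.isna(x) or pd.isna(y):
            break
        back.append((float(x), float(y)))
        i += 1
    conj = [row.get(c) for c in CONJUGATE_COLUMNS]
    has_conj = all(c in row.index for c in CONJUGATE_COLUMNS) and not any(
        pd.isna(v) for v in conj
    )
    return SagittalLandmarks(
        case_id=str(row["case_id"]),
        rater_id=str(row["rater_id"]),
        back_points=np.asarray(back, dtype=float),
        internal_os=(float(row["ios_x"]), float(row["ios_y"])),
        external_os=(float(row["eos_x"]), float(row["eos_y"])),
        promontory=(float(conj[0]), float(conj[1])) if has_conj else None,
        symphysis=(float(conj[2]), float(conj[3])) if has_conj else None,
    )


def frame_to_landmarks(df: pd.DataFrame) -> dict[str, list[SagittalLandmarks]]:
    """Parse a landmark frame into per-case lists, preserving row order."""
    missing = [c for c in LANDMARK_FIXED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"landmark table missing required columns: {missing}")
    if not any(_BACK_COL_RE.match(c) for c in df.columns):
        raise ValueError("landmark table has no back-point columns (b1x, b1y, ...)")
    by_case: dict[str, list[SagittalLandmarks]] = {}
    for _, row in df.iterrows():
        ls = _row_to_landmarks(row)
        by_case.setdefault(ls.case_id, []).append(ls)
    return by_case


def read_landmarks_csv(path: str | Path) -> dict[str, list[SagittalLandmarks]]:
    return frame_to_landmarks(pd.read_csv(path))


def write_landmarks_csv(
    landmark_sets: Sequence[SagittalLandmarks], path: str | Path
) -> None:
    landmarks_to_frame(landmark_sets).to_csv(path, index=False)


def read_labels_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in LABEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"labels table missing required columns: {missing}")
    return df


def write_labels_csv(
    rows: Iterable[tuple[str, int, float]], path: str | Path
) -> None:
    pd.DataFrame(list(rows), columns=LABEL_COLUMNS).to_csv(path, index=False)


def write_measurements_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_measurements_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = ["case_id", "n_raters", "angle_deg", "version"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"measurement table missing required columns: {missing}")
    return df
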