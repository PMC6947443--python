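"""Landmark geometry for the cervical canal angle on mid-sagittal images.

The measurement protocol works on four constructs drawn on a mid-sagittal
view of the gravid pelvis:

* the **back line** (A): a straight line through the broad of the maternal
  back, fitted by orthogonal regression to two or more digitised points
  listed cranial → caudal;
* the **perpendicular** (B): the line orthogonal to A at the internal os;
* the **canal line** (C): the line from the internal to the external os;
* the **cervical canal angle** (D): the signed angle between B and C.

The angle is 0° when the canal is perpendicular to the back line, positive
when the external os tilts toward the caudal end of the back line and
negative when it tilts cranially; its range is (−90°, 90°].  The sign is
defined anatomically (via the documented cranial → caudal ordering of the
back points) so it does not depend on image handedness.

Protractor readings are recorded in 5° steps using a numeric ceiling
(7.5° → 10°, −7.5° → −5°), and the per-rater readings are averaged and
re-quantised to give the per-case angle.

Cervix version (anteverted / retroverted) is classified against the
anatomical conjugate: the line from the sacral promontory to the pubic
symphysis.  A perpendicular to the conjugate is dropped at the internal os,
and the cervix is anteverted when the external os lies on the symphysis
("anterior") side of that perpendicular, retroverted when it lies on the
opposite side.  An external os exactly on the perpendicular is classified
anteverted (fixed tie rule).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ANTEVERTED",
    "RETROVERTED",
    "UNKNOWN",
    "DEFAULT_QUANTUM_DEG",
    "DegenerateGeometryError",
    "Line2D",
    "SagittalLandmarks",
    "AngleMeasurement",
    "fit_back_line",
    "perpendicular_at",
    "raw_canal_angle",
    "quantize_angle",
    "combine_raters",
    "classify_version",
    "measure_case",
]

ANTEVERTED = "anteverted"
RETROVERTED = "retroverted"
UNKNOWN = "unknown"

#: protractor resolution used throughout the protocol (degrees)
DEFAULT_QUANTUM_DEG = 5.0

# relative tolerance (in quantum units) below which a raw angle is snapped to
# the nearest multiple instead of ceiled; guards exact multiples against
# floating-point representation error
_SNAP_TOL = 1e-9


class DegenerateGeometryError(ValueError):
    """Landmarks do not define the geometric construction (coincident points,
    zero-length lines, undefined half-planes, ...)."""


def _point(p, name: str = "point") -> np.ndarray:
    arr = np.asarray(p, dtype=float).reshape(-1)
    if arr.shape != (2,):
        raise ValueError(f"{name} must be a 2D point, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} has non-finite coordinates: {arr}")
    return arr


@dataclass(frozen=True)
class Line2D:
    """A line in the sagittal plane given by a point and a unit direction."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "point", _point(self.point, "line point"))
        d = _point(self.direction, "line direction")
        norm = float(np.hypot(*d))
        if norm == 0.0:
            raise DegenerateGeometryError("line direction has zero length")
        object.__setattr__(self, "direction", d / norm)

    @classmethod
    def through(cls, p, q) -> "Line2D":
        p = _point(p, "p")
        q = _point(q, "q")
        return cls(point=p, direction=q - p)

    def normal(self) -> np.ndarray:
        """Unit normal: the direction rotated +90° (counter-clockwise)."""
        dx, dy = self.direction
        return np.array([-dy, dx])


@dataclass
class SagittalLandmarks:
    """One rater's digitised landmarks for one case.

    ``back_points`` are listed cranial → caudal; coordinates are millimetres
    in the mid-sagittal plane.  The conjugate endpoints (sacral promontory
    and pubic symphysis) are optional but must be given together.
    """

    case_id: str
    rater_id: str
    back_points: np.ndarray
    internal_os: np.ndarray
    external_os: np.ndarray
    promontory: np.ndarray | None = None
    symphysis: np.ndarray | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.back_points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise ValueError("back_points must be an (n >= 2, 2) array")
        if not np.all(np.isfinite(pts)):
            raise ValueError("back_points contain non-finite coordinates")
        if np.unique(pts, axis=0).shape[0] < 2:
            raise DegenerateGeometryError("back points span zero distance")
        self.back_points = pts
        self.internal_os = _point(self.internal_os, "internal_os")
        self.external_os = _point(self.external_os, "external_os")
        if np.array_equal(self.internal_os, self.external_os):
            raise DegenerateGeometryError("internal and external os coincide")
        if (self.promontory is None) != (self.symphysis is None):
            raise ValueError("promontory and symphysis must be given together")
        if self.promontory is not None:
            self.promontory = _point(self.promontory, "promontory")
            self.symphysis = _point(self.symphysis, "symphysis")
            if np.array_equal(self.promontory, self.symphysis):
                raise DegenerateGeometryError("promontory and symphysis coincide")

    @property
    def has_conjugate(self) -> bool:
        return self.promontory is not None


@dataclass
class AngleMeasurement:
    """Per-case cervical canal angle: quantised per-rater readings, their
    combined (re-quantised mean) value, and the cervix version call."""

    case_id: str
    per_rater_deg: list[float]
    combined_deg: float
    version: str = UNKNOWN

    def __post_init__(self) -> None:
        self.per_rater_deg = [float(v) for v in self.per_rater_deg]
        self.combined_deg = float(self.combined_deg)
        if not -90.0 <= self.combined_deg <= 90.0:
            raise ValueError(f"combined angle {self.combined_deg} outside [-90, 90]")
        if self.version not in (ANTEVERTED, RETROVERTED, UNKNOWN):
            raise ValueError(f"unknown version label {self.version!r}")


def fit_back_line(back_points) -> Line2D:
    """Fit the back line (line A) through digitised back points.

    Total least squares (orthogonal regression): the returned line passes
    through the centroid along the principal eigenvector of the 2x2 scatter
    matrix, so it treats the points as samples of a geometric axis rather
    than a response function.  The direction is oriented from the first
    (cranial) toward the last (caudal) listed point.
    """
    pts = np.asarray(back_points, dtype=float)
    pts = np.atleast_2d(pts)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("back_points must be an (n, 2) array")
    if not np.all(np.isfinite(pts)):
        raise ValueError("back_points contain non-finite coordinates")
    if pts.shape[0] < 2 or np.unique(pts, axis=0).shape[0] < 2:
        raise DegenerateGeometryError("need at least 2 distinct back points")

    centroid = pts.mean(axis=0)
    centered = pts - centroid
    scatter = centered.T @ centered
    _, vecs = np.linalg.eigh(scatter)
    direction = vecs[:, -1]  # principal axis

    chord = pts[-1] - pts[0]
    proj = float(chord @ direction)
    if proj < 0:
        direction = -direction
    elif proj == 0:
        # first and last points coincide (or chord happens to be orthogonal);
        # orient so projections increase with listing order on average
        idx = np.arange(pts.shape[0]) - (pts.shape[0] - 1) / 2.0
        if float(idx @ (centered @ direction)) < 0:
            direction = -direction
    return Line2D(point=centroid, direction=direction)


def perpendicular_at(line: Line2D, p) -> Line2D:
    """Line through ``p`` perpendicular to ``line`` (e.g. line B at the
    internal os, or line ② on the anatomical conjugate)."""
    return Line2D(point=_point(p), direction=line.normal())


def raw_canal_angle(back: Line2D, internal_os, external_os) -> float:
    """Signed cervical canal angle (degrees) in (−90, 90].

    Line B is the perpendicular to ``back`` at the internal os; line C runs
    from the internal to the external os.  The returned angle is between the
    undirected line C (taking the representative within 90° of line B) and
    line B, positive when the canal tilts toward the caudal direction of the
    back line.  Invariant to rotation, translation and uniform scaling of
    all landmarks.
    """
    ios = _point(internal_os, "internal_os")
    eos = _point(external_os, "external_os")
    c = eos - ios
    if c[0] == 0.0 and c[1] == 0.0:
        raise DegenerateGeometryError("internal and external os coincide")
    d = back.direction
    along = float(c @ d)  # caudal component
    across = abs(float(c @ back.normal()))  # component along line B
    angle = math.degrees(math.atan2(along, across))
    if angle <= -90.0:
        # canal parallel to the back line: the undirected line is the same
        # for both orientations, represented as +90
        angle = 90.0
    return angle


def quantize_angle(raw: float, quantum: float = DEFAULT_QUANTUM_DEG) -> float:
    """Protractor reading: smallest multiple of ``quantum`` >= ``raw``.

    Numeric ceiling, so 7.5 → 10 and −7.5 → −5; idempotent on multiples.
    Values within a hair (1e-9 quanta) of an exact multiple are snapped to
    it so that angles reconstructed through floating-point arithmetic do
    not spill into the next step.
    """
    if quantum <= 0:
        raise ValueError("quantum must be positive")
    r = float(raw) / quantum
    nearest = round(r)
    if abs(r - nearest) <= _SNAP_TOL:
        return float(quantum * nearest)
    return float(quantum * math.ceil(r))


def combine_raters(
    per_rater_deg: Sequence[float], quantum: float = DEFAULT_QUANTUM_DEG
) -> float:
    """Combine independent quantised readings: mean, then re-quantise.

    With two readings that are multiples of 5 the mean is a multiple of
    2.5, so the result is the mean itself when it lands on the grid and the
    next multiple up otherwise (15 and 0 → 7.5 → 10).
    """
    vals = [float(v) for v in per_rater_deg]
    if not vals:
        raise ValueError("need at least one rater reading")
    for v in vals:
        if abs(v / quantum - round(v / quantum)) > 1e-9:
            raise ValueError(f"reading {v} is not a multiple of the quantum {quantum}")
    return quantize_angle(sum(vals) / len(vals), quantum)


def classify_version(promontory, symphysis, internal_os, external_os) -> str:
    """Anteverted/retroverted call from the anatomical conjugate.

    Line ① runs through the sacral promontory and pubic symphysis; line ②
    is its perpendicular at the internal os.  The cervix (witnessed by the
    external os) is anteverted when the external os lies strictly in the
    open half-plane of line ② containing the symphysis, retroverted in the
    opposite half-plane, and anteverted when exactly on line ② (tie rule).
    """
    prom = _point(promontory, "promontory")
    symph = _point(symphysis, "symphysis")
    ios = _point(internal_os, "internal_os")
    eos = _point(external_os, "external_os")
    u = symph - prom
    if u[0] == 0.0 and u[1] == 0.0:
        raise DegenerateGeometryError("promontory and symphysis coincide")
    s_ref = float((symph - ios) @ u)
    if s_ref == 0.0:
        raise DegenerateGeometryError(
            "internal os lies on the perpendicular through the symphysis; "
            "the anterior side is undefined"
        )
    s = float((eos - ios) @ u)
    if s == 0.0:
        return ANTEVERTED
    return ANTEVERTED if (s > 0) == (s_ref > 0) else RETROVERTED


def measure_case(
    landmark_sets: Sequence[SagittalLandmarks],
    quantum: float = DEFAULT_QUANTUM_DEG,
) -> AngleMeasurement:
    """Full per-case protocol over one or more raters' landmark sets.

    Per rater: fit the back line, measure the raw canal angle, quantise;
    then combine the readings.  The version call uses the first rater's
    conjugate landmarks when present, else ``unknown``.
    """
    sets = list(landmark_sets)
    if not sets:
        raise ValueError("need landmarks from at least one rater")
    case_id = sets[0].case_id
    mismatched = [ls.case_id for ls in sets if ls.case_id != case_id]
    if mismatched:
        raise ValueError(
            f"landmark sets mix case ids: {case_id!r} vs {sorted(set(mismatched))}"
        )

    per_rater: list[float] = []
    for ls in sets:
        try:
            back = fit_back_line(ls.back_points)
            raw = raw_canal_angle(back, ls.internal_os, ls.external_os)
        except DegenerateGeometryError as exc:
            raise DegenerateGeometryError(
                f"case {ls.case_id!r}, rater {ls.rater_id!r}: {exc}"
            ) from exc
        per_rater.append(quantize_angle(raw, quantum))

    combined = combine_raters(per_rater, quantum)

    first = sets[0]
    if first.has_conjugate:
        try:
            version = classify_version(
                first.promontory, first.symphysis, first.internal_os, first.external_os
            )
        except DegenerateGeometryError as exc:
            raise DegenerateGeometryError(
                f"case {first.case_id!r}, rater {first.rater_id!r}: {exc}"
            ) from exc
    else:
        version = UNKNOWN

    return AngleMeasurement(
        case_id=case_id,
        per_rater_deg=per_rater,
        combined_deg=combined,
        version=version,
    )
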