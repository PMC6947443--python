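"""Diagnostic-accuracy analysis of the cervical canal angle.

Implements the statistical workstream around the horizontal cervix sign:

* sign rules (angle <= threshold; default 10°, alternative 0°),
* 2x2 contingency tables and sensitivity/specificity/PPV/NPV,
* ROC analysis over the quantised angle grid with trapezoidal AUC, the
  Youden-optimal cutoff and a Hanley–McNeil confidence interval,
* Fisher's exact test, Pearson chi-square and Mann–Whitney U group
  comparisons,
* ordinary least squares of angle on gestational age (the physiological
  ~3.3°/week decline in the non-adhesion stratum), and
* mean angles by gestational-age window.

Gestational-age groups follow the obstetric completed-weeks convention:
group 1 = floor(GA) <= 26 weeks, group 2 = 27–29, group 3 = 30–32,
group 4 = floor(GA) >= 33.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import stats

from .measurement import ANTEVERTED, RETROVERTED, UNKNOWN

__all__ = [
    "CaseRecord",
    "ContingencyTable2x2",
    "DiagnosticMetrics",
    "ROCResult",
    "RegressionFit",
    "horizontal_cervix_sign",
    "sign_predictor",
    "retroversion_predictor",
    "build_table",
    "diagnostic_metrics",
    "roc_curve",
    "roc_from_scores",
    "fisher_exact",
    "chi_square",
    "mann_whitney",
    "fit_angle_vs_ga",
    "assign_ga_group",
    "group_means",
]

_Z975 = float(stats.norm.ppf(0.975))

GA_GROUP_LABELS = {1: "<=26 weeks", 2: "27-29 weeks", 3: "30-32 weeks", 4: ">=33 weeks"}


@dataclass
class CaseRecord:
    """One analysed patient: combined angle joined to ground truth."""

    case_id: str
    angle_deg: float
    adhesion: bool | None
    ga_weeks: float
    version: str = UNKNOWN
    strata: dict | None = None

    def __post_init__(self) -> None:
        self.angle_deg = float(self.angle_deg)
        self.ga_weeks = float(self.ga_weeks)
        if not -90.0 <= self.angle_deg <= 90.0:
            raise ValueError(f"angle {self.angle_deg} outside [-90, 90]")
        if not 10.0 < self.ga_weeks < 45.0:
            raise ValueError(f"gestational age {self.ga_weeks} outside (10, 45) weeks")
        if self.adhesion is not None:
            self.adhesion = bool(self.adhesion)
        if self.version not in (ANTEVERTED, RETROVERTED, UNKNOWN):
            raise ValueError(f"unknown version label {self.version!r}")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts of a binary sign against the adhesion ground truth."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
            object.__setattr__(self, name, int(v))

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_array(self) -> np.ndarray:
        return np.array([[self.tp, self.fp], [self.fn, self.tn]], dtype=int)


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Sensitivity, specificity, PPV, NPV as proportions in [0, 1].

    A metric whose denominator is zero is reported as ``nan``.
    """

    sensitivity: float
    specificity: float
    ppv: float
    npv: float

    def as_dict(self) -> dict[str, float]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
        }


@dataclass
class ROCResult:
    """ROC curve of the angle with a lower-angle-is-positive polarity."""

    thresholds: np.ndarray
    points: list[tuple[float, float]]  # (1 - specificity, sensitivity)
    auc: float
    auc_ci: tuple[float, float]
    optimal_threshold: float


@dataclass
class RegressionFit:
    """OLS fit of angle (degrees) on gestational age (weeks)."""

    slope: float
    intercept: float
    p_value: float
    n: int
    stderr: float


def horizontal_cervix_sign(angle_deg: float, threshold: float = 10.0) -> bool:
    """Positive horizontal cervix sign: angle <= threshold (inclusive)."""
    return angle_deg <= threshold


def sign_predictor(threshold: float = 10.0) -> Callable[[CaseRecord], bool]:
    """Predicate on records applying the horizontal cervix sign rule."""

    def predict(record: CaseRecord) -> bool:
        return horizontal_cervix_sign(record.angle_deg, threshold)

    return predict


def retroversion_predictor(record: CaseRecord) -> bool:
    """Retroverted cervix as the (positive) predictor of adhesion."""
    return record.version == RETROVERTED


def build_table(
    records: Sequence[CaseRecord], predictor: Callable[[CaseRecord], bool]
) -> ContingencyTable2x2:
    """Cross-tabulate a binary sign against the adhesion ground truth."""
    records = list(records)
    if not records:
        raise ValueError("no records to tabulate")
    missing = [r.case_id for r in records if r.adhesion is None]
    if missing:
        raise ValueError(f"records missing adhesion labels: {missing}")
    tp = fp = fn = tn = 0
    for r in records:
        positive = bool(predictor(r))
        if positive and r.adhesion:
            tp += 1
        elif positive:
            fp += 1
        elif r.adhesion:
            fn += 1
        else:
            tn += 1
    return ContingencyTable2x2(tp=tp, fp=fp, fn=fn, tn=tn)


def diagnostic_metrics(t: ContingencyTable2x2) -> DiagnosticMetrics:
    """Standard 2x2 proportions; nan where a denominator is zero."""
    if t.total == 0:
        raise ValueError("empty contingency table")

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else math.nan

    return DiagnosticMetrics(
        sensitivity=ratio(t.tp, t.tp + t.fn),
        specificity=ratio(t.tn, t.tn + t.fp),
        ppv=ratio(t.tp, t.tp + t.fp),
        npv=ratio(t.tn, t.tn + t.fn),
    )


def roc_from_scores(angle_deg, adhesion) -> ROCResult:
    """ROC over the observed angle grid; positive call is angle <= t.

    Thresholds are the unique observed angles plus ±inf sentinels, so the
    curve runs from (0, 0) to (1, 1).  AUC is the trapezoidal area, which
    on this grid equals the tie-corrected rank statistic U'/(n1*n2).  The
    optimal threshold maximises Youden's J = sensitivity + specificity − 1,
    ties broken toward the larger threshold.  The confidence interval uses
    the Hanley–McNeil normal approximation.
    """
    a = np.asarray(angle_deg, dtype=float)
    y = np.asarray(adhesion, dtype=bool)
    if a.shape != y.shape or a.ndim != 1:
        raise ValueError("angle and adhesion arrays must be 1D and aligned")
    n1 = int(y.sum())  # adhesion (positive class)
    n0 = int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("ROC analysis needs both classes present")

    uniq = np.unique(a)
    thresholds = np.concatenate(([-np.inf], uniq, [np.inf]))
    pos = a[y]
    neg = a[~y]
    tpr = np.array([(pos <= t).mean() for t in thresholds])
    fpr = np.array([(neg <= t).mean() for t in thresholds])
    auc = float(np.trapezoid(tpr, fpr))

    best_j = -np.inf
    optimal = uniq[0]
    for t, se, sp1 in zip(uniq, tpr[1:-1], fpr[1:-1]):
        j = se - sp1
        if j >= best_j:  # >= : ties resolve to the larger threshold
            best_j = j
            optimal = float(t)

    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n1 - 1) * (q1 - auc * auc)
        + (n0 - 1) * (q2 - auc * auc)
    ) / (n1 * n0)
    se_auc = math.sqrt(max(var, 0.0))
    ci = (max(0.0, auc - _Z975 * se_auc), min(1.0, auc + _Z975 * se_auc))

    return ROCResult(
        thresholds=thresholds,
        points=list(zip(fpr.tolist(), tpr.tolist())),
        auc=auc,
        auc_ci=ci,
        optimal_threshold=float(optimal),
    )


def roc_curve(records: Sequence[CaseRecord]) -> ROCResult:
    """ROC analysis of the cervical canal angle for adhesion detection."""
    records = list(records)
    return roc_from_scores(
        [r.angle_deg for r in records], [bool(r.adhesion) for r in records]
    )


def _coerce_table(t) -> np.ndarray:
    if isinstance(t, ContingencyTable2x2):
        return t.as_array()
    arr = np.asarray(t, dtype=int)
    if arr.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    return arr


def fisher_exact(t) -> float:
    """Two-sided Fisher's exact test p-value for a 2x2 table.

    Sums the hypergeometric probabilities (same margins) of all tables at
    most as probable as the observed one.
    """
    arr = _coerce_table(t)
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def chi_square(t) -> float:
    """Pearson chi-square p-value (no continuity correction)."""
    arr = _coerce_table(t)
    res = stats.chi2_contingency(arr, correction=False)
    return float(res[1])


def _mann_whitney_exact(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided p by enumerating all labelings of the pooled sample.

    Uses midranks, so ties are handled exactly; the two-sided p-value is
    the permutation probability of a U statistic at least as far from its
    null mean as the observed one.
    """
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    mu = n1 * n2 / 2.0
    offset = n1 * (n1 + 1) / 2.0
    u_obs = float(ranks[:n1].sum() - offset)
    d_obs = abs(u_obs - mu)
    count = 0
    total = 0
    for combo in itertools.combinations(range(n1 + n2), n1):
        u = float(ranks[list(combo)].sum() - offset)
        if abs(u - mu) >= d_obs - 1e-12:
            count += 1
        total += 1
    return count / total


def mann_whitney(group_a, group_b, exact_max_n: int = 12) -> float:
    """Two-sided Mann–Whitney U p-value.

    Exact enumeration (tie-aware, via midranks) when the pooled sample has
    at most ``exact_max_n`` observations, otherwise the tie-corrected
    normal approximation.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if a.size + b.size <= exact_max_n:
        return _mann_whitney_exact(a, b)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def fit_angle_vs_ga(
    records: Sequence[CaseRecord], adhesion_stratum: bool
) -> RegressionFit:
    """OLS of combined angle on gestational age within one stratum."""
    sub = [r for r in records if bool(r.adhesion) == adhesion_stratum]
    if len(sub) < 3:
        raise ValueError(
            f"need >=3 records in the {'adhesion' if adhesion_stratum else 'non-adhesion'}"
            f" stratum, got {len(sub)}"
        )
    x = np.array([r.ga_weeks for r in sub])
    yv = np.array([r.angle_deg for r in sub])
    if np.ptp(x) == 0.0:
        raise ValueError("gestational age has zero variance; slope undefined")
    res = stats.linregress(x, yv)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        p_value=float(res.pvalue),
        n=len(sub),
        stderr=float(res.stderr),
    )


def assign_ga_group(ga_weeks: float) -> int:
    """Gestational-age window from completed weeks (floor)."""
    w = math.floor(ga_weeks)
    if w <= 26:
        return 1
    if w <= 29:
        return 2
    if w <= 32:
        return 3
    return 4


def group_means(
    records: Sequence[CaseRecord], non_adhesion_only: bool = True
) -> dict[int, float | None]:
    """Mean combined angle per gestational-age group (1-4).

    Empty groups are reported as ``None`` (missing), never zero.  By
    default only the non-adhesion stratum is averaged, matching the
    physiological-change analysis.
    """
    sub = [r for r in records if not (non_adhesion_only and r.adhesion)]
    sums: dict[int, list[float]] = {1: [], 2: [], 3: [], 4: []}
    for r in sub:
        sums[assign_ga_group(r.ga_weeks)].append(r.angle_deg)
    return {
        g: (float(np.mean(vals)) if vals else None) for g, vals in sums.items()
    }
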