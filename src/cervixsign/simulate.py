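"""Synthetic cohorts with the statistical structure of the study population.

Generates labels, latent angles, quantised rater readings and consistent
landmark geometries, so that the measurement and evaluation modules can be
exercised end to end without any imaging data.

The generative model, per case:

1. adhesion status ~ Bernoulli(prevalence), default 21/96;
2. gestational age at imaging drawn from a four-window mixture of uniforms
   (windows [22, 26.99], [27, 29.99], [30, 32.99], [33, 37] weeks, weights
   10/26/29/31 out of 96), giving a mean near 30.4 weeks;
3. latent angle: non-adhesion cases decline 3.3°/week around 38.41° at the
   anchor GA of 30.4 weeks with Gaussian case scatter (sd 12°); adhesion
   cases sit near 5.95° with a shallow +0.19°/week drift and tighter
   scatter (sd 12/2.4 = 5°); angles are clamped to [−30°, 90°];
4. each rater reads the latent angle with Gaussian error (sd 2.5°) and a
   5° ceiling protractor;
5. per rater, a landmark geometry (back line, os pair, conjugate) is
   constructed whose measured raw angle reproduces the reading to 1e-9°,
   with the conjugate placed so the version call is anteverted exactly when
   the reading exceeds the version boundary (default 10°).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .measurement import SagittalLandmarks, quantize_angle

__all__ = [
    "GA_WINDOWS",
    "GA_ANCHOR_WEEKS",
    "CohortParams",
    "SyntheticCase",
    "sample_ga",
    "sample_true_angle",
    "rater_reading",
    "landmarks_from_angle",
    "generate_cohort",
    "write_cohort",
    "expected_non_adhesion_group_means",
]

#: gestational-age windows (weeks) mirroring the four imaging-week groups
GA_WINDOWS: tuple[tuple[float, float], ...] = (
    (22.0, 26.99),
    (27.0, 29.99),
    (30.0, 32.99),
    (33.0, 37.0),
)

#: cohort mean gestational age at imaging (weeks); anchor of the linear model
GA_ANCHOR_WEEKS = 30.4


class CohortParams(BaseModel):
    """Generative parameters of the synthetic study population.

    Defaults reproduce the reported cohort structure: 96 cases, 21/96
    adhesion prevalence, the four imaging-week window counts, the
    −3.3°/week non-adhesion decline anchored at 38.41° (GA 30.4 weeks),
    and the 5.95° adhesion-group mean with a +0.19°/week drift.  Noise
    scales are modelling choices (see docs/methods.md), not reported data.
    """

    model_config = ConfigDict(frozen=True)

    n_cases: int = Field(default=96, ge=1)
    adhesion_prevalence: float = Field(default=21 / 96, ge=0.0, le=1.0)
    ga_window_weights: tuple[float, float, float, float] = (
        10 / 96,
        26 / 96,
        29 / 96,
        31 / 96,
    )
    non_adhesion_slope: float = -3.3  # degrees per week
    non_adhesion_angle_at_anchor: float = 38.41  # degrees at GA 30.4 weeks
    adhesion_mean_angle: float = 5.95  # degrees at GA 30.4 weeks
    adhesion_slope: float = 0.19  # degrees per week
    case_noise_sd: float = Field(default=12.0, ge=0.0)
    adhesion_noise_divisor: float = Field(default=2.4, gt=0.0)
    rater_noise_sd: float = Field(default=2.5, ge=0.0)
    n_raters: int = Field(default=2, ge=1)
    version_boundary_deg: float = 10.0
    quantum_deg: float = Field(default=5.0, gt=0.0)
    seed: int = 0

    @field_validator("ga_window_weights")
    @classmethod
    def _weights_valid(cls, w):
        arr = np.asarray(w, dtype=float)
        if np.any(arr < 0):
            raise ValueError("window weights must be non-negative")
        if abs(arr.sum() - 1.0) > 1e-6:
            raise ValueError(f"window weights must sum to 1, got {arr.sum()}")
        return tuple(float(x) for x in arr)


@dataclass
class SyntheticCase:
    """One simulated patient with full measurement provenance."""

    case_id: str
    adhesion: bool
    ga_weeks: float
    true_angle_deg: float
    rater_readings: list[float]
    landmarks: list[SagittalLandmarks]


def sample_ga(params: CohortParams, rng: np.random.Generator) -> float:
    """Gestational age at imaging: window by weight, uniform within."""
    w = np.asarray(params.ga_window_weights, dtype=float)
    idx = int(rng.choice(len(GA_WINDOWS), p=w / w.sum()))
    lo, hi = GA_WINDOWS[idx]
    return float(np.clip(rng.uniform(lo, hi), 22.0, 37.0))


def sample_true_angle(
    adhesion: bool, ga_weeks: float, params: CohortParams, rng: np.random.Generator
) -> float:
    """Latent cervical canal angle for one case, clamped to [−30°, 90°]."""
    if adhesion:
        mu = params.adhesion_mean_angle + params.adhesion_slope * (
            ga_weeks - GA_ANCHOR_WEEKS
        )
        sd = params.case_noise_sd / params.adhesion_noise_divisor
    else:
        mu = params.non_adhesion_angle_at_anchor + params.non_adhesion_slope * (
            ga_weeks - GA_ANCHOR_WEEKS
        )
        sd = params.case_noise_sd
    return float(np.clip(mu + rng.normal(0.0, sd), -30.0, 90.0))


def rater_reading(
    true_angle: float, params: CohortParams, rng: np.random.Generator
) -> float:
    """One protractor reading: Gaussian rater error, then 5° ceiling."""
    noisy = true_angle + rng.normal(0.0, params.rater_noise_sd)
    return float(np.clip(quantize_angle(noisy, params.quantum_deg), -90.0, 90.0))


# epsilon (degrees) pulled off the version boundary so a reading exactly at
# the boundary classifies anteverted deterministically (the tie rule) rather
# than by floating-point sign noise at sin(0)
_BOUNDARY_EPS_DEG = 1e-4


def landmarks_from_angle(
    target_angle_deg: float,
    rng: np.random.Generator,
    *,
    version_boundary_deg: float = 10.0,
    case_id: str = "synthetic",
    rater_id: str = "rater1",
) -> SagittalLandmarks:
    """Inverse of the measurement construction.

    Emits a back line of 3-6 collinear points (cranial → caudal) at a random
    pose, an internal os offset from the back line, an external os placed by
    rotating the perpendicular drop by ``target_angle_deg`` toward caudal,
    and conjugate endpoints oriented so the version call flips at
    ``version_boundary_deg`` (anteverted at and above the boundary).
    Measuring the output recovers the target angle to 1e-9°.
    """
    if not -90.0 <= target_angle_deg <= 90.0:
        raise ValueError("target angle must lie in [-90, 90] degrees")

    phi = rng.uniform(0.0, 2.0 * math.pi)
    d = np.array([math.cos(phi), math.sin(phi)])  # cranial -> caudal
    n = np.array([-d[1], d[0]])  # perpendicular (ventral side)
    origin = rng.uniform(-100.0, 100.0, size=2)

    n_back = int(rng.integers(3, 7))
    ts = np.sort(np.linspace(-70.0, 70.0, n_back) + rng.uniform(-5.0, 5.0, n_back))
    back_points = origin[None, :] + ts[:, None] * d[None, :]

    ios = origin + rng.uniform(-40.0, 40.0) * d + rng.uniform(25.0, 60.0) * n
    canal_len = rng.uniform(25.0, 40.0)
    th = math.radians(target_angle_deg)
    canal_dir = math.sin(th) * d - math.cos(th) * n
    eos = ios + canal_len * canal_dir

    beta = math.radians(version_boundary_deg - _BOUNDARY_EPS_DEG)
    u1 = math.cos(beta) * d + math.sin(beta) * n  # conjugate direction
    m = np.array([-u1[1], u1[0]])
    symphysis = ios + 85.0 * u1 + 30.0 * m
    promontory = ios - 85.0 * u1 + 30.0 * m

    return SagittalLandmarks(
        case_id=case_id,
        rater_id=rater_id,
        back_points=back_points,
        internal_os=ios,
        external_os=eos,
        promontory=promontory,
        symphysis=symphysis,
    )


def generate_cohort(params: CohortParams) -> list[SyntheticCase]:
    """Deterministically generate a cohort for ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    cases: list[SyntheticCase] = []
    for i in range(params.n_cases):
        case_id = f"case{i + 1:05d}"
        adhesion = bool(rng.random() < params.adhesion_prevalence)
        ga = sample_ga(params, rng)
        true_angle = sample_true_angle(adhesion, ga, params, rng)
        readings = [
            rater_reading(true_angle, params, rng) for _ in range(params.n_raters)
        ]
        landmarks = [
            landmarks_from_angle(
                readings[j],
                rng,
                version_boundary_deg=params.version_boundary_deg,
                case_id=case_id,
                rater_id=f"rater{j + 1}",
            )
            for j in range(params.n_raters)
        ]
        cases.append(
            SyntheticCase(
                case_id=case_id,
                adhesion=adhesion,
                ga_weeks=ga,
                true_angle_deg=true_angle,
                rater_readings=readings,
                landmarks=landmarks,
            )
        )
    return cases


def write_cohort(
    cases: list[SyntheticCase], params: CohortParams, out_dir: str | Path
) -> dict[str, Path]:
    """Write landmarks.csv, labels.csv and params.json for a cohort."""
    from .io import write_labels_csv, write_landmarks_csv  # avoid cycle at import

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    landmark_sets = [ls for c in cases for ls in c.landmarks]
    paths = {
        "landmarks": out / "landmarks.csv",
        "labels": out / "labels.csv",
        "params": out / "params.json",
    }
    write_landmarks_csv(landmark_sets, paths["landmarks"])
    write_labels_csv(
        [(c.case_id, int(c.adhesion), c.ga_weeks) for c in cases], paths["labels"]
    )
    paths["params"].write_text(
        json.dumps(params.model_dump(), sort_keys=True, indent=2) + "\n"
    )
    return paths


def expected_non_adhesion_group_means(params: CohortParams) -> dict[int, float]:
    """Closed-form group means of the non-adhesion linear model.

    Integrates the latent mean over each (uniform) GA window; clamping and
    quantisation are ignored, which is negligible at the default noise
    scales.
    """
    out = {}
    for g, (lo, hi) in enumerate(GA_WINDOWS, start=1):
        mid = (lo + hi) / 2.0
        out[g] = params.non_adhesion_angle_at_anchor + params.non_adhesion_slope * (
            mid - GA_ANCHOR_WEEKS
        )
    return out
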