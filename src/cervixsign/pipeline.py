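"""End-to-end pipeline: validate → measure → evaluate → report.

Every number in the JSON report is produced by a module operation; this
layer only orchestrates, formats and accounts for cases.  Reports are
written with sorted keys so identical inputs give byte-identical output.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import evaluation as ev
from . import io as csvio
from .evaluation import CaseRecord
from .measurement import UNKNOWN, measure_case

__all__ = [
    "RunConfig",
    "PipelineError",
    "validate_inputs",
    "measure_landmarks",
    "records_from_frames",
    "evaluate_records",
    "run_pipeline",
]

logger = logging.getLogger("cervixsign")

#: coordinates beyond this magnitude (mm) are flagged as implausible
COORD_LIMIT_MM = 500.0


class RunConfig(BaseModel):
    """Configuration of one analysis run; thresholds are config, not code."""

    model_config = ConfigDict(frozen=True)

    threshold_deg: float = 10.0
    alt_threshold_deg: float = 0.0
    quantum_deg: float = Field(default=5.0, gt=0.0)
    ga_max_weeks: float | None = None
    landmarks_csv: Path | None = None
    measurements_csv: Path | None = None
    labels_csv: Path | None = None
    out_dir: Path = Path("cervixsign_out")
    seed: int = 0
    log_level: str = "INFO"


class PipelineError(RuntimeError):
    """Raised when inputs fail validation or joining; carries diagnostics."""

    def __init__(self, message: str, issues: list[dict] | None = None):
        super().__init__(message)
        self.issues = issues or []


def _issue(code: str, severity: str, message: str, **extra) -> dict:
    d = {"code": code, "severity": severity, "message": message}
    d.update(extra)
    return d


def validate_inputs(
    landmarks_csv: str | Path | None, labels_csv: str | Path | None
) -> list[dict]:
    """Machine-readable schema and plausibility checks; never drops rows."""
    issues: list[dict] = []

    if landmarks_csv is not None:
        try:
            ldf = pd.read_csv(landmarks_csv)
        except Exception as exc:  # noqa: BLE001 - reported, not masked
            return [_issue("landmarks-unreadable", "error", str(exc))]
        missing = [c for c in csvio.LANDMARK_FIXED_COLUMNS if c not in ldf.columns]
        if missing:
            issues.append(
                _issue(
                    "landmarks-missing-columns",
                    "error",
                    f"missing required columns: {missing}",
                )
            )
        coord_cols = [
            c for c in ldf.columns if c not in ("case_id", "rater_id")
        ]
        if coord_cols:
            coords = ldf[coord_cols].apply(pd.to_numeric, errors="coerce")
            extreme = (coords.abs() > COORD_LIMIT_MM).any(axis=1)
            for ridx in ldf.index[extreme]:
                issues.append(
                    _issue(
                        "coordinate-implausible",
                        "warning",
                        f"row {ridx}: coordinate magnitude exceeds "
                        f"{COORD_LIMIT_MM:g} mm",
                        row=int(ridx),
                    )
                )
        if {"case_id", "rater_id"}.issubset(ldf.columns):
            dup = ldf.duplicated(subset=["case_id", "rater_id"], keep="first")
            for ridx in ldf.index[dup]:
                issues.append(
                    _issue(
                        "duplicate-case-rater",
                        "error",
                        f"row {ridx}: duplicate case x rater "
                        f"({ldf.loc[ridx, 'case_id']}, {ldf.loc[ridx, 'rater_id']})",
                        row=int(ridx),
                    )
                )

    if labels_csv is not None:
        try:
            labdf = pd.read_csv(labels_csv)
        except Exception as exc:  # noqa: BLE001
            issues.append(_issue("labels-unreadable", "error", str(exc)))
            return issues
        missing = [c for c in csvio.LABEL_COLUMNS if c not in labdf.columns]
        if missing:
            issues.append(
                _issue(
                    "labels-missing-columns",
                    "error",
                    f"missing required columns: {missing}",
                )
            )
        if "adhesion" in labdf.columns:
            bad = ~labdf["adhesion"].isin([0, 1])
            for ridx in labdf.index[bad]:
                issues.append(
                    _issue(
                        "label-domain",
                        "error",
                        f"row {ridx}: adhesion={labdf.loc[ridx, 'adhesion']!r} "
                        "not in {0, 1}",
                        row=int(ridx),
                    )
                )
        if "case_id" in labdf.columns:
            dup = labdf.duplicated(subset=["case_id"], keep="first")
            for ridx in labdf.index[dup]:
                issues.append(
                    _issue(
                        "duplicate-case-label",
                        "error",
                        f"row {ridx}: duplicate case_id {labdf.loc[ridx, 'case_id']}",
                        row=int(ridx),
                    )
                )
    return issues


def measure_landmarks(
    by_case: dict[str, list], quantum: float = 5.0
) -> pd.DataFrame:
    """Apply the measurement protocol to every case."""
    rows = []
    for case_id, sets in by_case.items():
        m = measure_case(sets, quantum=quantum)
        rows.append(
            {
                "case_id": case_id,
                "n_raters": len(m.per_rater_deg),
                "angle_deg": m.combined_deg,
                "version": m.version,
            }
        )
    return pd.DataFrame(rows, columns=["case_id", "n_raters", "angle_deg", "version"])


def records_from_frames(
    measurements: pd.DataFrame, labels: pd.DataFrame
) -> list[CaseRecord]:
    """Join measurements to labels on case_id; orphans are fatal."""
    m_ids = set(measurements["case_id"].astype(str))
    l_ids = set(labels["case_id"].astype(str))
    unlabeled = sorted(m_ids - l_ids)
    unmeasured = sorted(l_ids - m_ids)
    if unlabeled or unmeasured:
        raise PipelineError(
            "join failure: "
            f"measured cases without labels: {unlabeled}; "
            f"labelled cases without measurements: {unmeasured}",
            issues=[
                _issue("join-orphans", "error", f"unlabeled={unlabeled}, "
                       f"unmeasured={unmeasured}")
            ],
        )
    lab = labels.copy()
    lab["case_id"] = lab["case_id"].astype(str)
    lab = lab.set_index("case_id")
    records = []
    for _, row in measurements.iterrows():
        cid = str(row["case_id"])
        lrow = lab.loc[cid]
        strata = {
            k: lrow[k] for k in lab.columns if k not in ("adhesion", "ga_weeks")
        } or None
        records.append(
            CaseRecord(
                case_id=cid,
                angle_deg=float(row["angle_deg"]),
                adhesion=bool(int(lrow["adhesion"])),
                ga_weeks=float(lrow["ga_weeks"]),
                version=str(row["version"]),
                strata=strata,
            )
        )
    return records


def _metrics_dict(t: ev.ContingencyTable2x2) -> dict:
    m = ev.diagnostic_metrics(t)
    return {
        "table": {"tp": t.tp, "fp": t.fp, "fn": t.fn, "tn": t.tn},
        "sensitivity": m.sensitivity,
        "specificity": m.specificity,
        "ppv": m.ppv,
        "npv": m.npv,
        "fisher_p": _safe(lambda: ev.fisher_exact(t)),
        "chi_square_p": _safe(lambda: ev.chi_square(t)),
    }


def _safe(fn):
    try:
        v = fn()
    except (ValueError, ZeroDivisionError):
        return None
    if isinstance(v, float) and math.isnan(v):
        return None
    return v


def _regression_dict(records: Sequence[CaseRecord], stratum: bool):
    try:
        fit = ev.fit_angle_vs_ga(records, adhesion_stratum=stratum)
    except ValueError as exc:
        return {"error": str(exc)}
    return {
        "slope_deg_per_week": fit.slope,
        "intercept_deg": fit.intercept,
        "p_value": fit.p_value,
        "stderr": fit.stderr,
        "n": fit.n,
    }


def _analysis(records: Sequence[CaseRecord], config: RunConfig) -> dict:
    records = list(records)
    out: dict = {"n_cases": len(records)}
    n_adh = sum(bool(r.adhesion) for r in records)
    out["n_adhesion"] = n_adh
    out["prevalence"] = n_adh / len(records) if records else None

    signs = {
        f"angle_le_{config.threshold_deg:g}": ev.sign_predictor(config.threshold_deg),
        f"angle_le_{config.alt_threshold_deg:g}": ev.sign_predictor(
            config.alt_threshold_deg
        ),
    }
    out["signs"] = {
        name: _safe(lambda p=pred: _metrics_dict(ev.build_table(records, p)))
        for name, pred in signs.items()
    }

    known_version = [r for r in records if r.version != UNKNOWN]
    if known_version:
        out["retroversion"] = _safe(
            lambda: _metrics_dict(
                ev.build_table(known_version, ev.retroversion_predictor)
            )
        )
        if out["retroversion"] is not None:
            t = out["retroversion"]["table"]
            n_retro = t["tp"] + t["fp"]
            n_ante = t["fn"] + t["tn"]
            out["retroversion"]["adhesion_rate_retroverted"] = (
                t["tp"] / n_retro if n_retro else None
            )
            out["retroversion"]["adhesion_rate_anteverted"] = (
                t["fn"] / n_ante if n_ante else None
            )
    else:
        out["retroversion"] = None

    adh_angles = [r.angle_deg for r in records if r.adhesion]
    non_angles = [r.angle_deg for r in records if not r.adhesion]
    out["angle_by_group"] = {
        "adhesion_mean": float(np.mean(adh_angles)) if adh_angles else None,
        "non_adhesion_mean": float(np.mean(non_angles)) if non_angles else None,
        "mann_whitney_p": _safe(lambda: ev.mann_whitney(adh_angles, non_angles)),
    }

    roc = _safe(lambda: ev.roc_curve(records))
    if roc is not None:
        out["roc"] = {
            "auc": roc.auc,
            "auc_ci_95": list(roc.auc_ci),
            "optimal_threshold_deg": roc.optimal_threshold,
            "n_thresholds": int(len(roc.thresholds)),
        }
        out["_roc_object"] = roc  # stripped before serialisation
    else:
        out["roc"] = None

    out["regression"] = {
        "non_adhesion": _regression_dict(records, False),
        "adhesion": _regression_dict(records, True),
    }
    gm = ev.group_means(records, non_adhesion_only=True)
    out["group_means_non_adhesion"] = {
        ev.GA_GROUP_LABELS[g].replace(" ", "_"): v for g, v in gm.items()
    }
    return out


def evaluate_records(records: Sequence[CaseRecord], config: RunConfig) -> dict:
    """Full report: whole-cohort analysis plus optional GA-limited subset."""
    records = list(records)
    report: dict = {
        "config": {
            "threshold_deg": config.threshold_deg,
            "alt_threshold_deg": config.alt_threshold_deg,
            "quantum_deg": config.quantum_deg,
            "ga_max_weeks": config.ga_max_weeks,
        },
        "all_cases": _analysis(records, config),
        "warnings": [],
    }
    if config.ga_max_weeks is not None:
        subset = [r for r in records if r.ga_weeks <= config.ga_max_weeks]
        if not subset:
            msg = (
                f"no cases with gestational age <= {config.ga_max_weeks} weeks; "
                "subset analysis skipped"
            )
            logger.warning(msg)
            report["warnings"].append(msg)
            report["subset_ga_limited"] = None
        else:
            report["subset_ga_limited"] = _analysis(subset, config)
    return report


def _strip_objects(report: dict) -> dict:
    out = {}
    for k, v in report.items():
        if k.startswith("_"):
            continue
        out[k] = _strip_objects(v) if isinstance(v, dict) else v
    return out


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj


def _pct(x) -> str:
    return "undefined" if x is None else f"{100 * x:.1f}%"


def _prop(x) -> str:
    return "undefined" if x is None else f"{x:.2f}"


def _summary_text(report: dict) -> str:
    lines = []
    for section in ("all_cases", "subset_ga_limited"):
        block = report.get(section)
        if not block:
            continue
        title = (
            "All cases"
            if section == "all_cases"
            else f"Cases imaged at <= {report['config']['ga_max_weeks']:g} weeks"
        )
        lines.append(f"== {title} (n={block['n_cases']}, "
                     f"adhesions={block['n_adhesion']}) ==")
        for name, sign in (block.get("signs") or {}).items():
            if sign is None:
                continue
            lines.append(
                f"  sign {name}: sensitivity {_pct(sign['sensitivity'])}, "
                f"specificity {_pct(sign['specificity'])}, "
                f"PPV {_prop(sign['ppv'])}, NPV {_prop(sign['npv'])}"
            )
        retro = block.get("retroversion")
        if retro:
            lines.append(
                f"  retroverted cervix: sensitivity {_pct(retro['sensitivity'])}, "
                f"specificity {_pct(retro['specificity'])}, "
                f"adhesion rate {_pct(retro['adhesion_rate_retroverted'])} vs "
                f"{_pct(retro['adhesion_rate_anteverted'])} (anteverted)"
            )
        roc = block.get("roc")
        if roc:
            lines.append(
                f"  ROC: AUC {roc['auc']:.3f} "
                f"(95% CI {roc['auc_ci_95'][0]:.3f}-{roc['auc_ci_95'][1]:.3f}), "
                f"Youden-optimal threshold {roc['optimal_threshold_deg']:g} deg"
            )
        reg = block.get("regression", {}).get("non_adhesion", {})
        if "slope_deg_per_week" in reg:
            lines.append(
                f"  non-adhesion angle vs GA: {reg['slope_deg_per_week']:.2f} deg/week "
                f"(p={reg['p_value']:.3g}, n={reg['n']})"
            )
    for w in report.get("warnings", []):
        lines.append(f"WARNING: {w}")
    return "\n".join(lines) + "\n"


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run measure + evaluate and write all report files.

    Inputs are either a landmark CSV (measured here) or a precomputed
    measurement CSV, joined to a label CSV.  Outputs: measurements.csv,
    report.json, operating_points.csv, summary.txt.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    if config.labels_csv is None:
        raise PipelineError("labels_csv is required")
    if (config.landmarks_csv is None) == (config.measurements_csv is None):
        raise PipelineError(
            "provide exactly one of landmarks_csv or measurements_csv"
        )

    issues = validate_inputs(config.landmarks_csv, config.labels_csv)
    errors = [i for i in issues if i["severity"] == "error"]
    for i in issues:
        (logger.error if i["severity"] == "error" else logger.warning)(i["message"])
    if errors:
        raise PipelineError(
            f"{len(errors)} validation error(s); see issues", issues=issues
        )

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    if config.landmarks_csv is not None:
        by_case = csvio.read_landmarks_csv(config.landmarks_csv)
        measurements = measure_landmarks(by_case, quantum=config.quantum_deg)
        paths["measurements"] = out_dir / "measurements.csv"
        csvio.write_measurements_csv(measurements, paths["measurements"])
    else:
        measurements = csvio.read_measurements_csv(config.measurements_csv)

    labels = csvio.read_labels_csv(config.labels_csv)
    records = records_from_frames(measurements, labels)
    logger.info(
        "evaluating %d cases (%d adhesions), thresholds %g/%g deg",
        len(records),
        sum(r.adhesion for r in records),
        config.threshold_deg,
        config.alt_threshold_deg,
    )

    report = evaluate_records(records, config)

    roc = report["all_cases"].pop("_roc_object", None)
    report = _strip_objects(report)
    paths["report"] = out_dir / "report.json"
    paths["report"].write_text(
        json.dumps(_jsonify(report), sort_keys=True, indent=2) + "\n"
    )

    if roc is not None:
        finite = np.isfinite(roc.thresholds)
        op = pd.DataFrame(
            {
                "threshold_deg": roc.thresholds[finite],
                "fpr": [p[0] for p, f in zip(roc.points, finite) if f],
                "sensitivity": [p[1] for p, f in zip(roc.points, finite) if f],
            }
        )
        op["specificity"] = 1.0 - op["fpr"]
        op["youden_j"] = op["sensitivity"] - op["fpr"]
        paths["operating_points"] = out_dir / "operating_points.csv"
        op.to_csv(paths["operating_points"], index=False)

    paths["summary"] = out_dir / "summary.txt"
    paths["summary"].write_text(_summary_text(report))
    return paths
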