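"""Readers and writers for the package's plain-text formats.

Two CSV dialects, both with dot decimal separators, a ``#``-comment schema
line, and tolerance for CRLF endings and comment lines on input:

* trajectory CSV — columns ``time_s, cop_x_mm, cop_y_mm``, one row per
  sample of one trial;
* study CSV — the long-format trial table (one row per subject x session x
  condition x trial) consumed by the pipeline.

Plus a YAML run configuration mirroring :class:`~copsway.synthetic.StudyDesign`
(seed mandatory), and report/provenance writers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError
from .metrics import COPTrajectory
from .synthetic import OUParams, ScaleModel, StudyDesign

__all__ = [
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_study_csv",
    "read_study_csv",
    "write_subjects_csv",
    "read_subjects_csv",
    "design_from_yaml",
    "design_to_yaml",
    "write_report",
    "provenance_block",
]

TRAJECTORY_SCHEMA = "# copsway-trajectory v1"
STUDY_SCHEMA = "# copsway-study v1"
_TRAJ_COLUMNS = ["time_s", "cop_x_mm", "cop_y_mm"]


def write_trajectory_csv(traj: COPTrajectory, path) -> None:
    path = Path(path)
    with path.open("w", newline="\n") as fh:
        fh.write(TRAJECTORY_SCHEMA + "\n")
        fh.write(",".join(_TRAJ_COLUMNS) + "\n")
        for t, x, y in zip(traj.t, traj.x, traj.y):
            # shortest round-tripping decimal representation
            fh.write(f"{float(t)!r},{float(x)!r},{float(y)!r}\n")


def read_trajectory_csv(path) -> COPTrajectory:
    path = Path(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    df.columns = [c.strip() for c in df.columns]
    if list(df.columns) != _TRAJ_COLUMNS:
        if any("cm" in c for c in df.columns):
            raise SchemaError(
                f"{path}: trajectory coordinates must be in mm "
                f"(columns {_TRAJ_COLUMNS}), got {list(df.columns)}"
            )
        raise SchemaError(
            f"{path}: expected columns {_TRAJ_COLUMNS}, got {list(df.columns)}"
        )
    try:
        return COPTrajectory(
            t=df["time_s"].to_numpy(float),
            x=df["cop_x_mm"].to_numpy(float),
            y=df["cop_y_mm"].to_numpy(float),
        )
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def write_study_csv(study: pd.DataFrame, path) -> None:
    path = Path(path)
    with path.open("w", newline="\n") as fh:
        fh.write(STUDY_SCHEMA + "\n")
        # default float formatting = shortest round-tripping repr
        study.to_csv(fh, index=False, lineterminator="\n")


def read_study_csv(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if "subject_id" not in df.columns:
        raise SchemaError(f"{path}: not a study table (no subject_id column)")
    return df


def write_subjects_csv(subjects: pd.DataFrame, path) -> None:
    Path(path).write_text(subjects.to_csv(index=False, lineterminator="\n"))


def read_subjects_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", float_precision="round_trip")


# ---------------------------------------------------------------------------
# configuration


def design_from_yaml(path_or_text) -> StudyDesign:
    """Load a StudyDesign from YAML; unknown keys are rejected and the seed
    is mandatory."""
    text = (
        Path(path_or_text).read_text()
        if isinstance(path_or_text, (str, Path)) and "\n" not in str(path_or_text)
        else str(path_or_text)
    )
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise SchemaError("design config must be a YAML mapping")
    if "seed" not in data:
        raise SchemaError("design config must set an explicit seed")
    known = {f.name for f in dataclasses.fields(StudyDesign)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise SchemaError(f"unknown design keys: {unknown}")
    if "ou" in data and isinstance(data["ou"], dict):
        data["ou"] = OUParams(
            theta=tuple(data["ou"].get("theta", OUParams().theta)),
            sigma=tuple(data["ou"].get("sigma", OUParams().sigma)),
        )
    if "scale_models" in data:
        data["scale_models"] = tuple(
            ScaleModel(**m) for m in data["scale_models"]
        )
    if "sessions_per_subject" in data and isinstance(
        data["sessions_per_subject"], list
    ):
        data["sessions_per_subject"] = tuple(data["sessions_per_subject"])
    return StudyDesign(**data)


def design_to_yaml(design: StudyDesign) -> str:
    data = dataclasses.asdict(design)
    data["ou"] = {"theta": list(design.ou.theta), "sigma": list(design.ou.sigma)}
    data["scale_models"] = [dataclasses.asdict(m) for m in design.scale_models]
    if isinstance(data.get("sessions_per_subject"), tuple):
        data["sessions_per_subject"] = list(data["sessions_per_subject"])
    return yaml.safe_dump(data, sort_keys=True)


def provenance_block(design: StudyDesign | None, extra: dict | None = None) -> dict:
    """Provenance for an output directory: package version, seed, config
    hash and every effective parameter value."""
    from . import __version__

    block = {"copsway_version": __version__}
    if design is not None:
        cfg = design_to_yaml(design)
        block["seed"] = design.seed
        block["config_sha256"] = hashlib.sha256(cfg.encode()).hexdigest()
        block["design"] = yaml.safe_load(cfg)
    if extra:
        block.update(extra)
    return block


# ---------------------------------------------------------------------------
# report output


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_report(report, out_dir, provenance: dict | None = None) -> dict[str, Path]:
    """Write every table of an :class:`~copsway.pipeline.EvaluationReport`
    as CSV, plus a JSON summary, the exclusion log, and provenance.

    Returns a name -> path map of everything written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def _csv(name: str, df: pd.DataFrame, index: bool = False) -> None:
        p = out / f"{name}.csv"
        df.to_csv(p, index=index, lineterminator="\n", float_format="%.10g")
        written[name] = p

    from .pipeline import table_with_margins

    _csv("cv_table", table_with_margins(report.cv_table), index=True)
    _csv("reliability_table", report.reliability_table)
    _csv("scales_reliability", report.scales_reliability)
    _csv("validity_table", report.validity_table)
    _csv("validity_summary", report.validity_summary)
    _csv(
        "responsiveness_table",
        table_with_margins(report.responsiveness_table),
        index=True,
    )
    _csv("scales_responsiveness", report.scales_responsiveness)

    summary: dict = {}
    if report.condition_effects is not None:
        eff = report.condition_effects
        _csv("mean_v_by_condition", eff.mean_v_by_condition)
        summary["anova_v"] = dataclasses.asdict(eff.anova)
    if report.hd_results is not None:
        hd = report.hd_results
        _csv("hd_scale_correlations", hd.scale_correlations)
        _csv("hd_per_subject", hd.per_subject)
        summary["heel_distance"] = {
            "mean_correlation": hd.mean_correlation,
            "mean_slope_cm_per_day": hd.mean_slope_cm_per_day,
            "n_subjects_longitudinal": hd.n_subjects_longitudinal,
        }
    if report.demographics is not None:
        _csv("demographic_screen", report.demographics)

    _csv("exclusion_accounting", report.exclusions.to_frame())
    log_path = out / "evaluation.log"
    log_path.write_text("\n".join(report.exclusions.messages) + "\n")
    written["log"] = log_path

    summary_path = out / "summary.json"
    summary_path.write_text(
        json.dumps(summary, indent=2, default=_json_default) + "\n"
    )
    written["summary"] = summary_path

    if provenance is not None:
        prov_path = out / "provenance.json"
        prov_path.write_text(
            json.dumps(provenance, indent=2, default=_json_default) + "\n"
        )
        written["provenance"] = prov_path
    return written
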