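"""File formats and the end-to-end analysis pipeline.

All tabular artifacts are comma-separated UTF-8 text with a header row;
configuration is YAML; a run manifest (JSON) records the configuration
hash, seed and stage counts so that a run is fully reproducible and
silent truncation is impossible.

Pipeline order mirrors the analysis: simulate a cohort → assess
procedures → run the integer LC-CUSUM program per learner → trajectory
export → 2x2 diagnostic accuracy of the program verdict against the
career outcome.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd
import yaml

from . import diagnostics, synth
from .charts import (
    IntegerProgramDesign,
    ProgramResult,
    default_integer_design,
)
from .synth import CohortConfig, LearnerProfile, LearnerRecord

__all__ = [
    "ProcedureLogError",
    "PipelineConfig",
    "PipelineResult",
    "MANDATORY_COLUMNS",
    "read_procedure_log",
    "write_procedure_log",
    "export_trajectories",
    "read_trajectories",
    "outcomes_by_level_from_log",
    "run_pipeline",
    "load_pipeline_config",
]

logger = logging.getLogger("lccusum")

MANDATORY_COLUMNS = ("learner_id", "procedure_index", "competency_level", "passed")


class ProcedureLogError(ValueError):
    """Schema or row-level validation failure in a procedure log."""

    def __init__(self, errors: Sequence[str]) -> None:
        super().__init__("; ".join(errors))
        self.errors = list(errors)


def read_procedure_log(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate a procedure log.

    Mandatory columns: learner_id, procedure_index (positive integer),
    competency_level (0/1/2), passed (0/1); metric columns are optional
    and pass through untouched.  All row-level violations are collected
    and reported with their line numbers (header is line 1).
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ProcedureLogError(
            [f"missing mandatory column(s): {', '.join(missing)}"]
        )
    errors: list[str] = []
    for pos, (_, row) in enumerate(df.iterrows()):
        line = pos + 2  # header occupies line 1
        lvl = row["competency_level"]
        if not (lvl == lvl and float(lvl).is_integer() and int(lvl) in (0, 1, 2)):
            errors.append(f"line {line}: competency_level must be 0, 1 or 2, got {lvl}")
        p = row["passed"]
        if not (p == p and float(p).is_integer() and int(p) in (0, 1)):
            errors.append(f"line {line}: passed must be 0 or 1, got {p}")
        idx = row["procedure_index"]
        if not (idx == idx and float(idx).is_integer() and int(idx) >= 1):
            errors.append(f"line {line}: procedure_index must be >= 1, got {idx}")
    if errors:
        raise ProcedureLogError(errors)
    if len(df):
        df["procedure_index"] = df["procedure_index"].astype(int)
        df["competency_level"] = df["competency_level"].astype(int)
        df["passed"] = df["passed"].astype(int)
    return df


def write_procedure_log(df: pd.DataFrame, path: Union[str, Path]) -> Path:
    """Write a procedure log (CSV, UTF-8, header; mandatory columns first)."""
    path = Path(path)
    ordered = [c for c in MANDATORY_COLUMNS if c in df.columns] + [
        c for c in df.columns if c not in MANDATORY_COLUMNS
    ]
    df.loc[:, ordered].to_csv(path, index=False, lineterminator="\n")
    return path


def outcomes_by_level_from_log(
    df: pd.DataFrame, n_levels: int = 3
) -> dict[str, list[list[bool]]]:
    """Group a validated log into per-learner, per-level outcome streams."""
    result: dict[str, list[list[bool]]] = {}
    for learner_id, g in df.groupby("learner_id", sort=True):
        g = g.sort_values("procedure_index")
        streams: list[list[bool]] = [[] for _ in range(n_levels)]
        for lvl, passed in zip(g["competency_level"], g["passed"]):
            streams[int(lvl)].append(bool(passed))
        result[str(learner_id)] = streams
    return result


def export_trajectories(
    results: Mapping[str, ProgramResult], path: Union[str, Path]
) -> Path:
    """Write per-procedure cumulative chart scores in program units (0–39).

    One row per (learner, procedure): learner_id, competency_level,
    procedure_index (cumulative across levels, 1-based), score.  The
    integer-variant score already lives on the program scale because
    each level's band starts at its floor, so the rows are sufficient to
    redraw the program-wide trajectory chart.
    """
    rows = []
    for learner_id in results:
        res = results[learner_id]
        idx = 0
        for level, trace in enumerate(res.per_level_traces):
            for score in trace:
                idx += 1
                rows.append(
                    {
                        "learner_id": learner_id,
                        "competency_level": level,
                        "procedure_index": idx,
                        "score": score,
                    }
                )
    path = Path(path)
    pd.DataFrame(
        rows, columns=["learner_id", "competency_level", "procedure_index", "score"]
    ).to_csv(path, index=False, lineterminator="\n")
    return path


def read_trajectories(path: Union[str, Path]) -> pd.DataFrame:
    """Read a trajectory export back into a DataFrame."""
    df = pd.read_csv(path)
    expected = ["learner_id", "competency_level", "procedure_index", "score"]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ProcedureLogError(
            [f"missing trajectory column(s): {', '.join(missing)}"]
        )
    return df


# --- pipeline --------------------------------------------------------------


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one full synthetic-cohort analysis run."""

    seed: int
    out_dir: Path
    n_learners: int = 32
    profile_mixture: Optional[tuple[tuple[LearnerProfile, float], ...]] = None
    integer_design: IntegerProgramDesign = field(
        default_factory=default_integer_design
    )
    generate_metrics: bool = True
    allow_overrun: bool = False

    def cohort_config(self) -> CohortConfig:
        kwargs = dict(
            seed=self.seed,
            n_learners=self.n_learners,
            integer_design=self.integer_design,
            generate_metrics=self.generate_metrics,
            allow_overrun=self.allow_overrun,
        )
        if self.profile_mixture is not None:
            kwargs["profile_mixture"] = self.profile_mixture
        return CohortConfig(**kwargs)


def load_pipeline_config(path: Union[str, Path]) -> PipelineConfig:
    """Load a pipeline configuration from a YAML file.

    Recognised keys: seed (mandatory), out_dir, n_learners, design
    (mapping of IntegerProgramDesign fields), profiles (list of
    {profile-fields, weight}), generate_metrics, allow_overrun.
    """
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if "seed" not in doc:
        raise ValueError("pipeline config must declare an explicit seed")
    design = IntegerProgramDesign(**doc.get("design", {}))
    mixture = None
    if "profiles" in doc:
        mixture = tuple(
            (
                LearnerProfile(**{k: v for k, v in p.items() if k != "weight"}),
                float(p["weight"]),
            )
            for p in doc["profiles"]
        )
    return PipelineConfig(
        seed=int(doc["seed"]),
        out_dir=Path(doc.get("out_dir", "lccusum_run")),
        n_learners=int(doc.get("n_learners", 32)),
        profile_mixture=mixture,
        integer_design=design,
        generate_metrics=bool(doc.get("generate_metrics", True)),
        allow_overrun=bool(doc.get("allow_overrun", False)),
    )


@dataclass(frozen=True)
class PipelineResult:
    """Paths of emitted artifacts plus the in-memory summaries."""

    out_dir: Path
    procedure_log_path: Path
    cohort_summary_path: Path
    trajectories_path: Path
    diagnostics_path: Path
    manifest_path: Path
    records: tuple[LearnerRecord, ...]
    table: Optional[diagnostics.ContingencyTable]
    summary: Optional[diagnostics.DiagnosticSummary]


def _config_hash(config: PipelineConfig) -> str:
    def encode(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: encode(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, (tuple, list)):
            return [encode(x) for x in obj]
        if isinstance(obj, Path):
            return str(obj)
        return obj

    payload = encode(config)
    payload.pop("out_dir", None)  # hash the analysis, not the output location
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run simulate → assess → chart → diagnostics and write all artifacts.

    Emits into ``config.out_dir`` (created if absent):
    ``procedure_log.csv``, ``cohort_summary.csv``, ``trajectories.csv``,
    ``diagnostics.json`` and ``manifest.json``.  Measures whose
    denominator is zero in the cohort (e.g. NPV when every learner
    passes) are reported as null rather than aborting the run.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "simulate-cohort"
    try:
        records = synth.simulate_cohort(config.cohort_config())
        logger.info("%s: %d learners simulated", stage, len(records))

        stage = "procedure-log"
        log_df = synth.procedure_log(records)
        log_path = write_procedure_log(log_df, out / "procedure_log.csv")
        logger.info("%s: %d procedures written", stage, len(log_df))

        stage = "trajectories"
        traj_path = export_trajectories(
            {r.learner_id: r.program for r in records}, out / "trajectories.csv"
        )

        stage = "cohort-summary"
        summary_df = synth.cohort_summary(records)
        summary_path = out / "cohort_summary.csv"
        summary_df.to_csv(summary_path, index=False, lineterminator="\n")

        stage = "diagnostics"
        n_passed = int(summary_df["passed_program"].sum())
        table = diagnostics.contingency_from_cohort(summary_df)
        summary = diagnostics.diagnostic_measures(table, strict=False)
        arr = table.to_array()
        margins_ok = arr.sum(axis=0).min() > 0 and arr.sum(axis=1).min() > 0
        if margins_ok:
            fisher_p = diagnostics.fisher_exact(table)
            chi2_stat, chi2_p = diagnostics.chi_square(table)
        else:  # a degenerate cohort (e.g. everyone passed) has no 2x2 test
            fisher_p = chi2_stat = chi2_p = None
        diag = {
            "table": {
                "passed_stayed": table.passed_stayed,
                "passed_left": table.passed_left,
                "failed_stayed": table.failed_stayed,
                "failed_left": table.failed_left,
            },
            "measures": {
                "ppv": summary.ppv,
                "npv": summary.npv,
                "sensitivity": summary.sensitivity,
                "specificity": summary.specificity,
                "ppv_ci": summary.ppv_ci,
                "npv_ci": summary.npv_ci,
                "sensitivity_ci": summary.sensitivity_ci,
                "specificity_ci": summary.specificity_ci,
                "ci_method": summary.ci_method,
            },
            "fisher_exact_p": fisher_p,
            "chi_square": {"statistic": chi2_stat, "p": chi2_p},
        }
        diag_path = out / "diagnostics.json"
        diag_path.write_text(json.dumps(diag, indent=2) + "\n", encoding="utf-8")

        stage = "manifest"
        design = config.integer_design
        manifest = {
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "n_learners": len(records),
            "n_procedures": int(len(log_df)),
            "n_passed_program": n_passed,
            "program_min_procedures": design.program_target,
            "per_level_cap": design.per_level_cap,
            "signals_per_level": [
                sum(r.program.per_level_signalled[k] for r in records)
                for k in range(design.n_levels)
            ],
        }
        manifest_path = out / "manifest.json"
        manifest_path.write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return PipelineResult(
        out_dir=out,
        procedure_log_path=log_path,
        cohort_summary_path=summary_path,
        trajectories_path=traj_path,
        diagnostics_path=diag_path,
        manifest_path=manifest_path,
        records=tuple(records),
        table=table,
        summary=summary,
    )
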