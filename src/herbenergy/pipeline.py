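"""One-command replication of the study workflow.

``run_study_replica`` chains the whole analysis on synthetic or user data:
summarise the dataset, develop the full-data equations, refit them on a
two-thirds development split, score the refits on the held-out third,
benchmark the literature equations on the same hold-out, and emit residual
series for the main ME equations — one tab-separated table per stage plus a
manifest recording seeds, counts and warnings.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import DomainError, _as_frame, read_records_csv, summarize_dataset, write_records_csv
from .model_development import ModelSpec, develop_equation
from .registry import LinearEquation, load_builtin_registry, serialize_registry
from .simulate import GeneratorConfig, generate_dataset
from .validation import (DEFAULT_SPLIT_SEED, average_mpe_by_response,
                         benchmark_registry, residual_plot_data, split_dataset,
                         validate_equation)

__all__ = ["StudyRunConfig", "PipelineError", "run_study_replica", "report_table",
           "default_model_specs"]

log = logging.getLogger("herbenergy")

# exit-code classes for the command-line layer
EXIT_CONFIG, EXIT_DATA, EXIT_FIT, EXIT_VALIDATION = 2, 3, 4, 5


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str, exit_code: int = 1):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage
        self.exit_code = exit_code


def default_model_specs(random=("sheep", "season", "year")) -> list[tuple[str, ModelSpec]]:
    """The study's model forms: (original equation id, spec) for every
    whole-data equation row."""
    specs = []
    for table in ("table2", "table3", "table4", "table5"):
        for eq in load_builtin_registry(table):
            specs.append((eq.id, ModelSpec(response=eq.response,
                                           fixed=eq.predictors, random=random)))
    # order by original id (1a..1h, 2a..2o, 3a..3h, 4a..4h) so the refit
    # letter labels A.. line up with the study's mapping
    specs.sort(key=lambda s: (int(s[0][:1]), s[0][1:]))
    return specs


@dataclass
class StudyRunConfig:
    """Configuration of one study replica run."""

    data_path: str | None = None          # None -> generate synthetically
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    split_fraction: float = 2.0 / 3.0
    split_seed: int = DEFAULT_SPLIT_SEED
    model_specs: list | None = None       # None -> the study's forms
    benchmark_registries: tuple = ("table8",)
    residual_equations: tuple = ("I", "N", "L")  # refit ids to export residuals for
    out_dir: str = "study_replica"

    def validate(self):
        if not 0 < self.split_fraction < 1:
            raise PipelineError("config", "split fraction must lie in (0, 1)",
                                EXIT_CONFIG)
        if self.model_specs is not None and len(self.model_specs) == 0:
            raise PipelineError("config", "at least one model spec is required",
                                EXIT_CONFIG)


# display rounding per table layout: (column -> decimals)
_LAYOUTS = {
    "table1": None,  # summary layout handled separately
    "equations": None,
    "validation": {
        "predicted_mean": 2, "actual_mean": 2, "mpe": 3, "se": 3,
        "r2": 2, "rc": 2, "residual_mean": 3, "residual_sd": 3,
        "residual_min": 3, "residual_max": 3,
    },
}

_VALIDATION_COLUMNS = ["equation_id", "response", "n_test", "predicted_mean",
                       "actual_mean", "mpe", "se", "r2", "rc", "residual_mean",
                       "residual_sd", "residual_min", "residual_max"]


def report_table(items, layout: str) -> str:
    """Render reports/summaries/equations as a tab-separated table.

    ``validation`` mirrors the study's internal-validation layout (equation,
    parameters, predicted/actual means, MPE, SE, R2, Rc, residual summary)
    with the study's display rounding (MPE to 3 decimals); ``table1`` the
    summary layout; ``equations`` a coefficient table.
    """
    if layout not in _LAYOUTS:
        raise DomainError(f"unknown layout {layout!r}; valid: {sorted(_LAYOUTS)}")
    if layout == "table1":
        return items.table.to_csv(sep="\t", index_label="variable",
                                  float_format="%.4g")
    if layout == "equations":
        rows = []
        for eq in items:
            rows.append({
                "equation": eq.id, "response": eq.response,
                "formula": eq.formula(), "source": eq.source,
                "r2": "" if eq.reported_r2 is None else f"{eq.reported_r2:.3f}",
                "notes": eq.notes,
            })
        return pd.DataFrame(rows, columns=["equation", "response", "formula",
                                           "source", "r2", "notes"]) \
            .to_csv(sep="\t", index=False)
    rounding = _LAYOUTS["validation"]
    frame = pd.DataFrame([r.to_dict() for r in items], columns=_VALIDATION_COLUMNS)
    for col, d in rounding.items():
        if col in frame.columns and len(frame):
            frame[col] = frame[col].map(lambda v: f"{v:.{d}f}")
    return frame.to_csv(sep="\t", index=False)


def run_study_replica(config: StudyRunConfig) -> dict:
    """Execute the whole workflow; returns the manifest dictionary.

    Deterministic given the configured seeds: a fixed-seed run writes a
    byte-identical bundle.  Any stage failure aborts with the stage name;
    files already written are preserved.  Per-equation failures inside the
    develop/validate stages are demoted to manifest warnings so one bad spec
    (e.g. a response column absent from user data) does not sink the rest.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seeds": {"generator": config.generator.seed,
                          "split": config.split_seed},
                "stages": {}, "warnings": [], "files": []}

    def _write(name: str, text: str):
        (out / name).write_text(text)
        manifest["files"].append(name)

    # -- data ---------------------------------------------------------------
    stage = "data"
    try:
        if config.data_path is None:
            data = generate_dataset(config.generator)
            log.info("generated %d synthetic records", len(data))
        else:
            data = read_records_csv(config.data_path)
            log.info("loaded %d records from %s", len(data), config.data_path)
        write_records_csv(data, out / "dataset.csv")
        manifest["files"].append("dataset.csv")
        manifest["stages"][stage] = {"n_records": len(data)}
    except DomainError as exc:
        raise PipelineError(stage, str(exc), EXIT_DATA) from exc

    # -- summary ------------------------------------------------------------
    stage = "summary"
    try:
        summary = summarize_dataset(data)
        _write("table1_summary.tsv", report_table(summary, "table1"))
        manifest["stages"][stage] = {"n_variables": len(summary.variables)}
    except DomainError as exc:
        raise PipelineError(stage, str(exc), EXIT_DATA) from exc

    # -- develop on full data ----------------------------------------------
    stage = "develop"
    specs = config.model_specs if config.model_specs is not None \
        else default_model_specs()
    full_equations, refit_pairs = [], []
    for orig_id, spec in specs:
        try:
            eq = develop_equation(data, spec, equation_id=f"{orig_id}*")
            full_equations.append(eq)
            refit_pairs.append((orig_id, spec))
        except DomainError as exc:
            manifest["warnings"].append(f"develop {orig_id} "
                                        f"({spec.response}): {exc}")
    if not full_equations:
        raise PipelineError(stage, "no model spec could be fitted; "
                            + "; ".join(manifest["warnings"]), EXIT_FIT)
    _write("equations_full.tsv", report_table(full_equations, "equations"))
    manifest["stages"][stage] = {"n_equations": len(full_equations),
                                 "n_failed": len(specs) - len(full_equations)}

    # -- split and refit ----------------------------------------------------
    stage = "refit"
    try:
        train, test = split_dataset(data, fraction=config.split_fraction,
                                    seed=config.split_seed)
    except DomainError as exc:
        raise PipelineError(stage, str(exc), EXIT_DATA) from exc
    refit_equations = []
    _refit_ids = _letter_ids(len(refit_pairs))
    for (orig_id, spec), new_id in zip(refit_pairs, _refit_ids):
        try:
            refit_equations.append(develop_equation(train, spec, equation_id=new_id))
        except DomainError as exc:
            manifest["warnings"].append(f"refit {orig_id}: {exc}")
    if not refit_equations:
        raise PipelineError(stage, "no refit equation could be fitted", EXIT_FIT)
    _write("equations_refit.tsv", report_table(refit_equations, "equations"))
    _write("equations_refit.json", serialize_registry(refit_equations))
    manifest["stages"][stage] = {"n_train": len(train), "n_test": len(test),
                                 "n_equations": len(refit_equations)}

    # -- internal validation -------------------------------------------------
    stage = "validate"
    reports, errors = benchmark_registry(refit_equations, test)
    for eq_id, msg in errors.items():
        manifest["warnings"].append(f"validate {eq_id}: {msg}")
    if not reports:
        raise PipelineError(stage, "no refit equation could be validated",
                            EXIT_VALIDATION)
    _write("validation_internal.tsv", report_table(reports, "validation"))
    internal_mpe = average_mpe_by_response(reports)
    manifest["stages"][stage] = {"n_reports": len(reports),
                                 "mean_mpe_by_response": internal_mpe}

    # -- literature benchmark ------------------------------------------------
    stage = "benchmark"
    bench_reports = []
    for name in config.benchmark_registries:
        registry = load_builtin_registry(name)
        for eq in registry:
            if eq.anomaly:
                manifest["warnings"].append(
                    f"benchmark {eq.id}: flagged anomalous transcription")
        rep, errs = benchmark_registry(registry, test)
        bench_reports.extend(rep)
        for eq_id, msg in errs.items():
            manifest["warnings"].append(f"benchmark {eq_id}: {msg}")
    _write("validation_literature.tsv", report_table(bench_reports, "validation"))
    manifest["stages"][stage] = {
        "n_reports": len(bench_reports),
        "mean_mpe_by_response": (average_mpe_by_response(bench_reports)
                                 if bench_reports else {}),
    }

    # -- residual series -----------------------------------------------------
    stage = "residuals"
    frames = []
    by_id = {eq.id: eq for eq in refit_equations}
    for eq_id in config.residual_equations:
        eq = by_id.get(eq_id)
        if eq is None:
            manifest["warnings"].append(f"residuals: no refit equation {eq_id!r}")
            continue
        series = residual_plot_data(eq, test)
        series.insert(0, "equation", eq_id)
        frames.append(series)
    residuals = pd.concat(frames) if frames else pd.DataFrame(
        columns=["equation", "predicted", "residual"])
    _write("residuals_me.tsv", residuals.to_csv(sep="\t", index=False))
    manifest["stages"][stage] = {"n_points": len(residuals)}

    manifest["config"] = {
        "data_path": config.data_path,
        "split_fraction": config.split_fraction,
        "benchmark_registries": list(config.benchmark_registries),
        "generator_seed": config.generator.seed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _letter_ids(n: int) -> list[str]:
    """A, B, ..., Z, AA, AB, ... — refit equation labels."""
    ids = []
    for i in range(n):
        s, j = "", i
        while True:
            s = chr(ord("A") + j % 26) + s
            j = j // 26 - 1
            if j < 0:
                break
        ids.append(s)
    return ids
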