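"""Internal and external validation of prediction equations.

The harness splits a trial dataset into development and evaluation subsets,
scores an equation's predictions P against the actual values A with the mean
square prediction error MSPE = (1/n) sum (P - A)^2, expresses accuracy as the
mean prediction error MPE = sqrt(MSPE) / mean(A), and measures agreement with
Lin's concordance correlation coefficient

    R_c = 2 cov(P, A) / (var(P) + var(A) + (mean(P) - mean(A))^2)

using population (1/n) moments, so that |R_c| <= |r| holds exactly with
equality iff the means and variances of P and A coincide.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .core import DomainError, _as_frame
from .registry import RESPONSE_COLUMNS, LinearEquation, evaluate_frame

__all__ = [
    "ValidationReport",
    "split_dataset",
    "mspe",
    "mpe",
    "lins_ccc",
    "residual_summary",
    "validate_equation",
    "benchmark_registry",
    "average_mpe_by_response",
    "residual_plot_data",
    "reference_validation_reports",
    "DEFAULT_SPLIT_SEED",
]

DEFAULT_SPLIT_SEED = 11


@dataclass
class ValidationReport:
    """One validation row: agreement between predicted and actual values."""

    equation_id: str
    response: str
    n_test: int
    predicted_mean: float
    actual_mean: float
    mpe: float
    se: float          # standard error of the paired differences P - A
    r2: float          # squared Pearson correlation of P and A
    rc: float          # Lin's concordance correlation coefficient
    residual_mean: float
    residual_sd: float
    residual_min: float
    residual_max: float

    def to_dict(self) -> dict:
        return asdict(self)


def _paired(P, A):
    P = np.asarray(P, dtype=float)
    A = np.asarray(A, dtype=float)
    if P.shape != A.shape or P.ndim != 1:
        raise DomainError(f"P and A must be 1-d and equal length "
                          f"(got {P.shape} vs {A.shape})")
    if len(P) == 0:
        raise DomainError("P and A must be non-empty")
    return P, A


def mspe(P, A) -> float:
    """Mean square prediction error, (1/n) sum (P - A)^2 (squared units)."""
    P, A = _paired(P, A)
    return float(np.mean((P - A) ** 2))


def mpe(P, A) -> float:
    """Mean prediction error, sqrt(MSPE) / mean(A) (dimensionless).

    Scale-invariant: multiplying P and A by any c > 0 leaves it unchanged.
    """
    P, A = _paired(P, A)
    mean_a = float(np.mean(A))
    if mean_a <= 0:
        raise DomainError(f"MPE undefined: mean of actual values {mean_a} <= 0")
    return float(np.sqrt(mspe(P, A)) / mean_a)


def lins_ccc(P, A) -> float:
    """Lin's concordance correlation coefficient (population moments)."""
    P, A = _paired(P, A)
    if len(P) < 2:
        raise DomainError("concordance requires at least 2 pairs")
    var_p, var_a = np.var(P), np.var(A)
    location = (np.mean(P) - np.mean(A)) ** 2
    denom = var_p + var_a + location
    if denom == 0:
        raise DomainError("concordance undefined: zero variance and equal means")
    cov = np.mean((P - np.mean(P)) * (A - np.mean(A)))
    return float(2.0 * cov / denom)


def residual_summary(P, A):
    """(mean, sample SD, min, max) of the signed residuals P - A."""
    P, A = _paired(P, A)
    d = P - A
    sd = float(np.std(d, ddof=1)) if len(d) > 1 else 0.0
    return float(np.mean(d)), sd, float(np.min(d)), float(np.max(d))


def split_dataset(records, fraction: float = 2.0 / 3.0,
                  seed: int | None = DEFAULT_SPLIT_SEED,
                  stratify_by_trial: bool = True):
    """Random development/evaluation partition of a trial dataset.

    With trial stratification (the default) every trial contributes its
    proportional share of records to the development subset, preserving the
    seasonal balance between subsets; 66 records in 11 trials of 6 sheep
    split 2:1 give exactly 44 development and 22 evaluation records.
    Deterministic given the seed; the two subsets are disjoint and exhaustive.
    """
    frame = _as_frame(records)
    if not 0.0 < fraction < 1.0:
        raise DomainError(f"fraction must lie in (0, 1), got {fraction}")
    if len(frame) == 0:
        raise DomainError("cannot split an empty dataset")
    rng = np.random.default_rng(seed)
    if stratify_by_trial:
        train_idx = []
        for trial, grp in frame.groupby("trial_id", sort=True):
            if len(grp) < 2:
                raise DomainError(f"trial {trial!r} has fewer than 2 records; "
                                  "cannot stratify")
            k = int(np.floor(fraction * len(grp) + 0.5))
            k = min(max(k, 1), len(grp) - 1)
            perm = rng.permutation(len(grp))
            train_idx.extend(grp.index[perm[:k]])
        train_mask = frame.index.isin(train_idx)
    else:
        k = int(np.floor(fraction * len(frame) + 0.5))
        perm = rng.permutation(len(frame))
        train_mask = np.zeros(len(frame), dtype=bool)
        train_mask[perm[:k]] = True
    return frame[train_mask].copy(), frame[~train_mask].copy()


def _actuals(eq: LinearEquation, frame: pd.DataFrame) -> np.ndarray:
    col = RESPONSE_COLUMNS[eq.response]
    if col not in frame.columns:
        raise DomainError(f"test records lack the actual response "
                          f"{eq.response!r} (column {col!r})")
    A = frame[col].to_numpy(dtype=float)
    if np.any(np.isnan(A)):
        raise DomainError(f"actual response {eq.response!r} has missing values")
    return A


def validate_equation(eq: LinearEquation, test_records) -> ValidationReport:
    """Score one equation on an evaluation subset (one report row)."""
    frame = _as_frame(test_records)
    P = evaluate_frame(eq, frame)
    A = _actuals(eq, frame)
    n = len(frame)
    res_mean, res_sd, res_min, res_max = residual_summary(P, A)
    se = res_sd / np.sqrt(n) if n > 1 else 0.0
    if np.std(P) > 0 and np.std(A) > 0:
        r2 = float(np.corrcoef(P, A)[0, 1] ** 2)
        rc = lins_ccc(P, A)
    else:
        r2, rc = 0.0, 0.0
    return ValidationReport(
        equation_id=eq.id, response=eq.response, n_test=n,
        predicted_mean=float(np.mean(P)), actual_mean=float(np.mean(A)),
        mpe=mpe(P, A), se=float(se), r2=r2, rc=rc,
        residual_mean=res_mean, residual_sd=res_sd,
        residual_min=res_min, residual_max=res_max)


def benchmark_registry(equations, test_records):
    """Score every equation of a registry on the same evaluation subset.

    Per-row failures (e.g. a predictor the test data cannot supply) are
    collected, not fatal.  Returns ``(reports, errors)`` with ``errors``
    mapping equation id to the failure message.
    """
    frame = _as_frame(test_records)
    reports, errors = [], {}
    for eq in equations:
        try:
            reports.append(validate_equation(eq, frame))
        except DomainError as exc:
            errors[eq.id] = str(exc)
    return reports, errors


def average_mpe_by_response(reports, digits: int = 3) -> dict[str, float]:
    """Arithmetic mean MPE grouped by response, rounded for display."""
    if not reports:
        raise DomainError("no reports to average")
    acc: dict[str, list[float]] = {}
    for r in reports:
        acc.setdefault(r.response, []).append(r.mpe)
    return {resp: round(float(np.mean(v)), digits) for resp, v in acc.items()}


def residual_plot_data(eq: LinearEquation, test_records) -> pd.DataFrame:
    """Paired (predicted, residual P - A) series for a residual plot."""
    frame = _as_frame(test_records)
    P = evaluate_frame(eq, frame)
    A = _actuals(eq, frame)
    return pd.DataFrame({"predicted": P, "residual": P - A})


def reference_validation_reports() -> list[ValidationReport]:
    """The built-in study-scale internal-validation rows (one per refit equation)."""
    text = (importlib.resources.files("herbenergy.data")
            / "table7_validation.json").read_text()
    return [ValidationReport(**row) for row in json.loads(text)]
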