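"""Equation development: linear models with trial-structure random intercepts.

Fixed-effect prediction equations are developed by residual (restricted)
maximum likelihood.  Candidate random intercepts for the trial structure
(sheep, season, year, or the combined trial factor) are profiled out as
variance ratios gamma_k = sigma_k^2 / sigma_e^2:

    y = X beta + sum_k Z_k u_k + e,   u_k ~ N(0, sigma_e^2 gamma_k I)

so V = sigma_e^2 W with W = I + sum_k gamma_k Z_k Z_k'.  For fixed gamma the
GLS solution and the profiled residual variance are closed-form, leaving a
low-dimensional restricted-likelihood surface that is minimised by L-BFGS-B
from the corners of the unit box (gamma_k in {0, 1}) plus an interior start;
the zero corner makes every nested reduction a feasible point of the full
model, so the full-model deviance can never exceed a reduction's beyond
optimiser tolerance.  Nested random structures are compared by the change in
deviance (-2 restricted log-likelihood) against chi-square; fixed terms by
the Wald statistic (estimate/SE)^2 against chi-square with 1 df.

The deviance is reported only up to the fixed-effect model: comparing
deviances is meaningful solely between fits sharing the same response,
fixed terms and data.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .core import DomainError, _as_frame
from .registry import (PREDICTORS, RESPONSE_COLUMNS, LinearEquation, Term)

__all__ = [
    "ModelSpec",
    "FitResult",
    "FitError",
    "fit_reml",
    "compare_random_structures",
    "wald_test",
    "develop_equation",
]

#: grouping factor name -> record column
RANDOM_FACTORS = {
    "sheep": "sheep_id",
    "season": "season",
    "year": "year",
    "trial": "trial_id",
}

_SIGMA2_FLOOR = 1e-12
_GAMMA_MAX = 1e7


class FitError(DomainError):
    """Model fitting failed (rank deficiency or non-convergence)."""

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


@dataclass(frozen=True)
class ModelSpec:
    """A model to develop: response, ordered fixed terms, candidate random factors."""

    response: str
    fixed: tuple[str, ...]
    random: tuple[str, ...] = ("sheep", "season", "year")

    def __post_init__(self):
        object.__setattr__(self, "fixed", tuple(self.fixed))
        object.__setattr__(self, "random", tuple(self.random))
        if self.response not in RESPONSE_COLUMNS:
            raise DomainError(f"unknown response {self.response!r}")
        if self.response in self.fixed:
            raise DomainError("response cannot appear among the fixed terms")
        if len(set(self.fixed)) != len(self.fixed):
            raise DomainError("fixed terms must be unique")
        for p in self.fixed:
            if p not in PREDICTORS:
                raise DomainError(f"unknown predictor {p!r}")
        for r in self.random:
            if r not in RANDOM_FACTORS:
                raise DomainError(f"unknown random factor {r!r}; "
                                  f"valid: {sorted(RANDOM_FACTORS)}")

    @classmethod
    def from_config(cls, text: str) -> "ModelSpec":
        """Parse ``"response: DE; fixed: [DMD, N, GE]; random: [sheep, season, year]"``."""
        parts = {}
        for chunk in text.split(";"):
            if not chunk.strip():
                continue
            key, _, val = chunk.partition(":")
            parts[key.strip().lower()] = val.strip()
        if "response" not in parts or "fixed" not in parts:
            raise DomainError("model spec needs 'response:' and 'fixed:' entries")

        def _list(v):
            return tuple(x.strip() for x in v.strip("[]").split(",") if x.strip())

        random = _list(parts["random"]) if "random" in parts else ("sheep", "season", "year")
        return cls(response=parts["response"], fixed=_list(parts["fixed"]), random=random)


@dataclass
class FitResult:
    """A fitted mixed (or plain) linear model.

    ``deviance`` is -2 x restricted log-likelihood at the optimum;
    ``r2`` is the squared Pearson correlation of response and fitted values.
    """

    response: str
    fixed_terms: tuple[str, ...]          # without intercept
    random_factors: tuple[str, ...]
    n: int
    coefficients: dict[str, float]        # "Intercept" first
    std_errors: dict[str, float]
    variance_components: dict[str, float]  # sigma_k^2 per retained factor
    residual_variance: float
    deviance: float
    wald: dict[str, tuple[float, float]]  # term -> (statistic, p)
    r2: float
    converged: bool
    gamma: dict[str, float] = field(default_factory=dict)

    @property
    def terms(self) -> list[str]:
        return ["Intercept"] + list(self.fixed_terms)

    def coefficient_table(self) -> pd.DataFrame:
        rows = []
        for term in self.terms:
            stat, p = self.wald.get(term, (np.nan, np.nan))
            rows.append({"term": term, "estimate": self.coefficients[term],
                         "SE": self.std_errors[term], "Wald": stat, "p": p})
        return pd.DataFrame(rows)


def _predictor_column(frame: pd.DataFrame, name: str) -> np.ndarray:
    column, _ = PREDICTORS[name]
    if name == "CP":
        if "n" not in frame.columns:
            raise DomainError("missing predictor N (needed for CP)")
        x = 6.25 * frame["n"].to_numpy(dtype=float)
    else:
        if column not in frame.columns:
            raise DomainError(f"predictor {name!r} absent from records")
        x = frame[column].to_numpy(dtype=float)
    if np.any(np.isnan(x)):
        raise DomainError(f"predictor {name!r} has missing values")
    return x


def _design(frame: pd.DataFrame, spec: ModelSpec):
    ycol = RESPONSE_COLUMNS[spec.response]
    if ycol not in frame.columns:
        raise DomainError(f"response {spec.response!r} absent from records "
                          f"(column {ycol!r})")
    y = frame[ycol].to_numpy(dtype=float)
    if np.any(np.isnan(y)):
        raise DomainError(f"response {spec.response!r} has missing values")
    X = np.column_stack([np.ones(len(frame))] +
                        [_predictor_column(frame, p) for p in spec.fixed])
    n, p = X.shape
    if n <= p:
        raise FitError(f"n={n} observations cannot identify {p} fixed coefficients")
    if np.linalg.matrix_rank(X) < p:
        # name the columns whose removal restores full rank
        names = ["Intercept"] + list(spec.fixed)
        collinear = [names[j] for j in range(p)
                     if np.linalg.matrix_rank(np.delete(X, j, axis=1)) ==
                     np.linalg.matrix_rank(X)]
        raise FitError(f"design matrix is rank deficient; collinear terms: {collinear}")
    Zs, aliased = [], []
    for factor in spec.random:
        codes = pd.Categorical(frame[RANDOM_FACTORS[factor]]).codes
        Z = np.zeros((n, codes.max() + 1))
        Z[np.arange(n), codes] = 1.0
        # a factor with one observation per level is wholly confounded with
        # the residual (Z Z' = I); its component is unidentifiable and is
        # absorbed by sigma^2, so it is held at zero rather than optimised
        if Z.sum(axis=0).max() <= 1:
            aliased.append(factor)
        Zs.append(Z)
    return y, X, Zs, aliased


def _profiled(gamma: np.ndarray, y, X, Zs):
    """GLS solution and REML deviance at fixed variance ratios."""
    n, p = X.shape
    W = np.eye(n)
    for g, Z in zip(gamma, Zs):
        if g > 0:
            W += g * (Z @ Z.T)
    cW = cho_factor(W, lower=True)
    logdet_W = 2.0 * np.sum(np.log(np.diag(cW[0])))
    WiX = cho_solve(cW, X)
    Wiy = cho_solve(cW, y)
    XtWiX = X.T @ WiX
    cX = cho_factor(XtWiX, lower=True)
    logdet_X = 2.0 * np.sum(np.log(np.diag(cX[0])))
    beta = cho_solve(cX, X.T @ Wiy)
    r = y - X @ beta
    quad = float(r @ cho_solve(cW, r))
    sigma2 = max(quad / (n - p), _SIGMA2_FLOOR)
    dev = (n - p) * (math.log(2.0 * math.pi * sigma2) + 1.0) + logdet_W + logdet_X
    cov_beta = sigma2 * np.linalg.inv(XtWiX)
    return dev, beta, cov_beta, sigma2


def fit_reml(records, spec: ModelSpec, maxiter: int = 500,
             tol: float = 1e-10) -> FitResult:
    """Fit a fixed-effect model with the spec's random intercepts by REML.

    Variance ratios are profiled out and optimised; with no random factors
    this reduces exactly to ordinary least squares.  Deterministic given the
    data: no randomness enters the fit.
    """
    frame = _as_frame(records)
    y, X, Zs, aliased = _design(frame, spec)
    n, p = X.shape
    free = [k for k, f in enumerate(spec.random) if f not in aliased]
    K = len(free)

    converged = True
    if K == 0:
        gamma_full = np.zeros(len(Zs))
        dev, beta, cov_beta, sigma2 = _profiled(gamma_full, y, X, Zs)
    else:
        def expand(g):
            full = np.zeros(len(Zs))
            full[free] = np.maximum(g, 0.0)
            return full

        def objective(g):
            return _profiled(expand(g), y, X, Zs)[0]

        corners = [np.array(c, dtype=float)
                   for c in itertools.product((0.0, 1.0), repeat=K)]
        starts = corners + [np.full(K, 0.25)]
        best = None
        any_success = False
        for s in starts:
            res = optimize.minimize(
                objective, s, method="L-BFGS-B",
                bounds=[(0.0, _GAMMA_MAX)] * K,
                options={"maxiter": maxiter, "ftol": tol, "gtol": 1e-10})
            any_success = any_success or res.success
            for cand, val in ((res.x, res.fun), (s, objective(s))):
                if best is None or val < best[1] - 0.0:
                    best = (np.asarray(cand, dtype=float), float(val))
        gamma_hat = np.maximum(best[0], 0.0)
        converged = any_success
        # parsimony tie-break: zero any ratio whose removal costs no
        # deviance, so degenerate limits reduce to OLS exactly
        best_dev = objective(gamma_hat)
        changed = True
        while changed:
            changed = False
            for k in range(K):
                if gamma_hat[k] == 0.0:
                    continue
                candidate = gamma_hat.copy()
                candidate[k] = 0.0
                cand_dev = objective(candidate)
                if cand_dev <= best_dev + 1e-8:
                    gamma_hat, best_dev, changed = candidate, min(cand_dev, best_dev), True
        gamma_full = expand(gamma_hat)
        dev, beta, cov_beta, sigma2 = _profiled(gamma_full, y, X, Zs)
        if not converged:
            raise FitError("REML optimisation did not converge within the "
                           "iteration budget", last_iterate=dict(
                               gamma=dict(zip(spec.random, gamma_full)),
                               deviance=dev))

    se = np.sqrt(np.diag(cov_beta))
    names = ["Intercept"] + list(spec.fixed)
    fitted = X @ beta
    if np.std(fitted) > 0 and np.std(y) > 0:
        r2 = float(np.corrcoef(y, fitted)[0, 1] ** 2)
    else:
        r2 = 0.0
    wald = {}
    for name, b, s in zip(names, beta, se):
        stat = (b / s) ** 2 if s > 0 else math.inf
        wald[name] = (float(stat), float(stats.chi2.sf(stat, df=1)))
    return FitResult(
        response=spec.response, fixed_terms=tuple(spec.fixed),
        random_factors=tuple(spec.random), n=n,
        coefficients=dict(zip(names, map(float, beta))),
        std_errors=dict(zip(names, map(float, se))),
        variance_components={f: float(sigma2 * g)
                             for f, g in zip(spec.random, gamma_full)},
        residual_variance=float(sigma2), deviance=float(dev), wald=wald,
        r2=min(r2, 1.0), converged=converged,
        gamma=dict(zip(spec.random, map(float, gamma_full))),
    )


def compare_random_structures(full: FitResult, reduced: FitResult):
    """Deviance change between nested random structures, same fixed model.

    Returns ``(statistic, df, p)`` with the statistic referred to chi-square
    on df = difference in number of variance components.  A plain chi-square
    reference is used despite the boundary at zero, which makes the test
    conservative.
    """
    if (full.response != reduced.response
            or full.fixed_terms != reduced.fixed_terms or full.n != reduced.n):
        raise DomainError("models must share response, fixed terms and data")
    if not set(reduced.random_factors) <= set(full.random_factors):
        raise DomainError("reduced model's random factors must be a subset "
                          "of the full model's")
    df = len(full.random_factors) - len(reduced.random_factors)
    stat = max(reduced.deviance - full.deviance, 0.0)
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    return stat, df, p


def wald_test(fit: FitResult, term: str):
    """Wald statistic (estimate/SE)^2 and chi-square(1) p-value for a term."""
    if term not in fit.wald:
        raise DomainError(f"term {term!r} not in fit; terms: {fit.terms}")
    return fit.wald[term]


def develop_equation(records, spec: ModelSpec, alpha: float = 0.05,
                     equation_id: str | None = None) -> LinearEquation:
    """Develop a prediction equation the way the study equations were built.

    All candidate random intercepts are fitted, then backward-eliminated:
    the component whose removal changes the deviance least is dropped while
    that change is non-significant at ``alpha`` (chi-square, 1 df); the model
    is refitted after each drop.  The surviving fixed coefficients and SEs
    are packaged as a :class:`LinearEquation` with source ``"refit"``.
    """
    frame = _as_frame(records)
    current = fit_reml(frame, spec)
    factors = list(spec.random)
    while factors:
        candidates = []
        for f in factors:
            reduced_spec = ModelSpec(response=spec.response, fixed=spec.fixed,
                                     random=tuple(x for x in factors if x != f))
            reduced = fit_reml(frame, reduced_spec)
            stat, df, p = compare_random_structures(current, reduced)
            candidates.append((p, f, reduced))
        p, f, reduced = max(candidates, key=lambda c: c[0])
        if p < alpha:
            break
        factors.remove(f)
        current = reduced

    terms = tuple(
        Term(predictor=name, coefficient=current.coefficients[name],
             se=current.std_errors[name], unit=PREDICTORS[name][1])
        for name in spec.fixed)
    return LinearEquation(
        id=equation_id or f"refit:{spec.response}~{'+'.join(spec.fixed)}",
        response=spec.response, intercept=current.coefficients["Intercept"],
        intercept_se=current.std_errors["Intercept"], terms=terms,
        source="refit", reported_r2=current.r2,
        notes=("random intercepts retained: "
               + (", ".join(current.random_factors) or "none")),
    )
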