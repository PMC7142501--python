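"""Machine-readable registry of energy prediction equations.

Each :class:`LinearEquation` is one printed prediction equation: a response
(DE, ME, DE/GE or ME/GE), an intercept and ordered predictor terms, every one
carrying its coefficient, standard error and explicit predictor unit.  The
built-in registries ship as JSON package data; ``evaluate`` applies an
equation to a trial record after converting each predictor into the
equation's unit convention.

Predictor vocabulary
--------------------
DMD, OMD, DOMD, GED, N, GE, NDF, ADF, EE, Ash, DE, CP, tdCP, tdNDF.
CP is derived as 6.25 x N.  A term may declare ``basis = "printed_n"``, which
feeds the CP-derived quantity computed from the nitrogen column taken at face
value (i.e. without the 6.25 factor); several literature equations and the
total-digestible-nutrient rows are only numerically consistent with that
reading (each such row documents the evidence in its notes).
"""

from __future__ import annotations

import dataclasses
import hashlib
import importlib.resources
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import DomainError, _as_frame
from .units import UnitError, convert_predictor

__all__ = [
    "Term",
    "LinearEquation",
    "Prediction",
    "evaluate",
    "evaluate_frame",
    "load_builtin_registry",
    "serialize_registry",
    "parse_registry",
    "registry_checksum",
    "BUILTIN_REGISTRIES",
    "PREDICTORS",
    "RESPONSE_COLUMNS",
]

BUILTIN_REGISTRIES = ("table2", "table3", "table4", "table5", "table6", "table8")

#: predictor -> (record column, canonical unit).  CP has no column: 6.25 x n.
PREDICTORS: Mapping[str, tuple[str | None, str]] = {
    "DMD": ("dmd", "kg/kg"),
    "OMD": ("omd", "kg/kg"),
    "DOMD": ("domd", "kg/kg"),
    "GED": ("ged", "MJ/MJ"),
    "N": ("n", "kg/kg"),
    "GE": ("ge", "MJ/kg"),
    "NDF": ("ndf", "kg/kg"),
    "ADF": ("adf", "kg/kg"),
    "EE": ("ee", "kg/kg"),
    "Ash": ("ash", "kg/kg"),
    "DE": ("de", "MJ/kg"),
    "CP": (None, "kg/kg"),
    "tdCP": ("tdcp", "g/100g"),
    "tdNDF": ("tdndf", "g/100g"),
}

RESPONSE_COLUMNS = {"DE": "de", "ME": "me", "DE/GE": "de_ge", "ME/GE": "me_ge"}
RESPONSE_UNITS = {"DE": "MJ/kg", "ME": "MJ/kg", "DE/GE": "MJ/MJ", "ME/GE": "MJ/MJ"}


@dataclass(frozen=True)
class Term:
    predictor: str
    coefficient: float
    se: float | None
    unit: str
    basis: str = "standard"  # "standard" | "printed_n"

    def __post_init__(self):
        if self.predictor not in PREDICTORS:
            raise DomainError(f"unknown predictor {self.predictor!r}; "
                              f"vocabulary: {sorted(PREDICTORS)}")
        if self.basis not in ("standard", "printed_n"):
            raise DomainError(f"unknown basis {self.basis!r}")


@dataclass(frozen=True)
class LinearEquation:
    """One prediction equation with provenance and unit conventions."""

    id: str
    response: str
    intercept: float
    intercept_se: float | None
    terms: tuple[Term, ...]
    response_unit: str = ""
    source: str = "this-study-whole-data"
    reported_r2: float | None = None
    reported_mpe: float | None = None
    notes: str = ""
    anomaly: bool = False
    reported: Mapping[str, float] | None = None

    def __post_init__(self):
        if self.response not in RESPONSE_COLUMNS:
            raise DomainError(f"unknown response {self.response!r}")
        if not self.response_unit:
            object.__setattr__(self, "response_unit", RESPONSE_UNITS[self.response])

    @property
    def predictors(self) -> tuple[str, ...]:
        return tuple(t.predictor for t in self.terms)

    def formula(self) -> str:
        parts = [f"{self.intercept:g}"]
        for t in self.terms:
            sign = "+" if t.coefficient >= 0 else "-"
            parts.append(f" {sign} {abs(t.coefficient):g} {t.predictor}")
        return f"{self.response} = " + "".join(parts)


@dataclass(frozen=True)
class Prediction:
    value: float
    equation_id: str
    inputs: Mapping[str, float]


def _predictor_values(term: Term, frame: pd.DataFrame) -> np.ndarray:
    """Predictor values for one term, in the term's own unit."""
    column, canon_unit = PREDICTORS[term.predictor]
    if term.predictor in ("CP", "tdCP"):
        # CP-derived quantities; the printed-N basis strips the 6.25 factor
        if term.predictor == "CP":
            if "n" not in frame.columns:
                raise DomainError("missing predictor N (needed for CP)")
            base = 6.25 * frame["n"].to_numpy(dtype=float)
        else:
            if "tdcp" not in frame.columns:
                raise DomainError("missing predictor tdCP")
            base = frame["tdcp"].to_numpy(dtype=float)
        if term.basis == "printed_n":
            base = base / 6.25
    else:
        if column not in frame.columns:
            raise DomainError(f"missing predictor {term.predictor} (column {column!r})")
        base = frame[column].to_numpy(dtype=float)
    if np.any(np.isnan(base)):
        raise DomainError(f"predictor {term.predictor} has missing values")
    return convert_predictor(base, canon_unit, term.unit)


def evaluate_frame(eq: LinearEquation, data) -> np.ndarray:
    """Vectorised evaluation of an equation over a record frame."""
    frame = _as_frame(data)
    value = np.full(len(frame), float(eq.intercept))
    for term in eq.terms:
        value = value + term.coefficient * _predictor_values(term, frame)
    return value


def evaluate(eq: LinearEquation, record) -> Prediction:
    """Apply an equation to a single trial record.

    The record may be a :class:`~herbenergy.core.TrialRecord` or a one-row
    frame; predictors are converted to the equation's units before the linear
    combination is formed.
    """
    frame = _as_frame([record] if not isinstance(record, pd.DataFrame) else record)
    if isinstance(record, pd.DataFrame) and len(frame) != 1:
        raise DomainError("evaluate() expects a single record; use evaluate_frame()")
    inputs = {}
    for term in eq.terms:
        inputs[term.predictor] = float(_predictor_values(term, frame)[0])
    value = float(evaluate_frame(eq, frame)[0])
    if not np.isfinite(value):
        raise DomainError(f"equation {eq.id} produced a non-finite value")
    return Prediction(value=value, equation_id=eq.id, inputs=inputs)


# ---------------------------------------------------------------------------
# (de)serialization
# ---------------------------------------------------------------------------

_REQUIRED_EQ_FIELDS = ("id", "response", "intercept", "terms")
_REQUIRED_TERM_FIELDS = ("predictor", "coefficient", "unit")


def _equation_to_dict(eq: LinearEquation) -> dict:
    d = {
        "id": eq.id, "response": eq.response, "response_unit": eq.response_unit,
        "intercept": eq.intercept, "intercept_se": eq.intercept_se,
        "terms": [dataclasses.asdict(t) for t in eq.terms],
        "source": eq.source, "reported_r2": eq.reported_r2,
        "reported_mpe": eq.reported_mpe, "notes": eq.notes,
        "anomaly": eq.anomaly,
    }
    if eq.reported is not None:
        d["reported"] = dict(eq.reported)
    return d


def _equation_from_dict(d: dict, where: str) -> LinearEquation:
    for f in _REQUIRED_EQ_FIELDS:
        if f not in d:
            raise DomainError(f"{where}: missing field {f!r}")
    terms = []
    for j, t in enumerate(d["terms"]):
        for f in _REQUIRED_TERM_FIELDS:
            if f not in t:
                raise DomainError(f"{where}, term {j}: missing field {f!r}")
        terms.append(Term(predictor=t["predictor"], coefficient=t["coefficient"],
                          se=t.get("se"), unit=t["unit"],
                          basis=t.get("basis", "standard")))
    return LinearEquation(
        id=d["id"], response=d["response"], intercept=d["intercept"],
        intercept_se=d.get("intercept_se"), terms=tuple(terms),
        response_unit=d.get("response_unit", ""),
        source=d.get("source", "this-study-whole-data"),
        reported_r2=d.get("reported_r2"), reported_mpe=d.get("reported_mpe"),
        notes=d.get("notes", ""), anomaly=d.get("anomaly", False),
        reported=d.get("reported"),
    )


def serialize_registry(equations: Sequence[LinearEquation]) -> str:
    """Lossless JSON document for a list of equations."""
    return json.dumps([_equation_to_dict(e) for e in equations],
                      indent=1, sort_keys=True)


def parse_registry(text: str) -> tuple[LinearEquation, ...]:
    try:
        raw = json.loads(text)
    except json.JSONDecodeError as exc:
        raise DomainError(f"malformed registry document: {exc}") from exc
    if not isinstance(raw, list):
        raise DomainError("registry document must be a JSON array of equations")
    return tuple(_equation_from_dict(d, where=f"equation #{i}")
                 for i, d in enumerate(raw))


def registry_checksum(equations: Sequence[LinearEquation]) -> str:
    """SHA-256 of the canonical serialization; used to freeze built-ins."""
    return hashlib.sha256(serialize_registry(equations).encode()).hexdigest()


_cache: dict[str, tuple[LinearEquation, ...]] = {}


def load_builtin_registry(name: str) -> tuple[LinearEquation, ...]:
    """The complete, immutable equation list of one built-in table."""
    if name not in BUILTIN_REGISTRIES:
        raise DomainError(f"unknown registry {name!r}; valid names: "
                          f"{', '.join(BUILTIN_REGISTRIES)}")
    if name not in _cache:
        text = (importlib.resources.files("herbenergy.data") / f"{name}.json").read_text()
        _cache[name] = parse_registry(text)
    return _cache[name]
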