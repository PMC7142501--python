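"""Domain types, unit conventions and dataset summaries for digestibility trials.

A digestibility-trial record is one sheep x trial observation of herbage
chemical composition, apparent nutrient digestibilities and energy
concentrations.  Internally every mass fraction is stored in kg/kg DM,
energies in MJ/kg DM and digestibilities as fractions; delimited-text files
use g/kg DM for composition (converted at the I/O boundary).
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DomainError",
    "HerbageComposition",
    "DigestibilityProfile",
    "EnergyProfile",
    "TrialRecord",
    "DatasetSummary",
    "SEASONS",
    "crude_protein_from_n",
    "domd_from_components",
    "derive_energy_ratios",
    "total_digestible_cp",
    "total_digestible_ndf",
    "summarize_dataset",
    "fold_range",
    "validate_record",
    "frame_from_records",
    "records_from_frame",
    "read_records_csv",
    "write_records_csv",
    "reference_summary",
]


class DomainError(ValueError):
    """An input is outside its physically meaningful domain."""


SEASONS = ("june", "august", "december")

#: canonical numeric columns of a trial-record frame, in storage units
NUMERIC_VARS = (
    "dm_fresh",  # g/kg fresh
    "n", "ndf", "adf", "ee", "ash",  # kg/kg DM
    "ge",  # MJ/kg DM
    "dmd", "omd", "nd", "ndfd", "adfd", "ged", "domd",  # fractions
    "de", "me",  # MJ/kg DM
    "de_ge", "me_ge",  # MJ/MJ
    "tdcp", "tdndf",  # g/100 g DM
)

ID_VARS = ("sheep_id", "trial_id", "season", "year")

# column names of the delimited-text exchange schema -> (canonical name, scale)
CSV_SCHEMA = {
    "sheep_id": ("sheep_id", None),
    "trial_id": ("trial_id", None),
    "season": ("season", None),
    "year": ("year", None),
    "dm_fresh_g_kg": ("dm_fresh", 1.0),
    "n_g_kg_dm": ("n", 1000.0),
    "ndf_g_kg_dm": ("ndf", 1000.0),
    "adf_g_kg_dm": ("adf", 1000.0),
    "ee_g_kg_dm": ("ee", 1000.0),
    "ash_g_kg_dm": ("ash", 1000.0),
    "ge_mj_kg_dm": ("ge", 1.0),
    "dmd": ("dmd", 1.0),
    "omd": ("omd", 1.0),
    "nd": ("nd", 1.0),
    "ndfd": ("ndfd", 1.0),
    "adfd": ("adfd", 1.0),
    "ged": ("ged", 1.0),
    "domd": ("domd", 1.0),
    "de_mj_kg_dm": ("de", 1.0),
    "me_mj_kg_dm": ("me", 1.0),
}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class HerbageComposition:
    """Chemical composition of the herbage on offer.

    ``dm_fresh`` is g/kg fresh weight; ``n``, ``ndf``, ``adf``, ``ee`` and
    ``ash`` are mass fractions of DM (kg/kg); ``ge`` is MJ/kg DM.  The
    fractions overlap chemically, so no closure constraint is imposed beyond
    each fraction lying in [0, 1].
    """

    dm_fresh: float
    n: float
    ndf: float
    adf: float
    ee: float
    ash: float
    ge: float


@dataclass
class DigestibilityProfile:
    """Apparent digestibility coefficients (fractions).

    ``domd`` is digestible organic matter expressed per kg DM, which can
    never exceed the organic-matter digestibility ``omd``.
    """

    dmd: float
    omd: float
    nd: float
    ndfd: float
    adfd: float
    ged: float
    domd: float


@dataclass
class EnergyProfile:
    """Energy concentrations (MJ/kg DM) and their ratios to gross energy."""

    de: float
    me: float
    de_ge: float | None = None
    me_ge: float | None = None


@dataclass
class TrialRecord:
    """One sheep x trial observation.

    ``season``/``year`` identify the trial; ``tdcp`` and ``tdndf`` are total
    digestible crude protein and NDF in g/100 g DM (concentration times
    digestibility).
    """

    sheep_id: str
    trial_id: str
    season: str
    year: int
    composition: HerbageComposition
    digestibility: DigestibilityProfile
    energy: EnergyProfile
    tdcp: float | None = None
    tdndf: float | None = None


@dataclass
class DatasetSummary:
    """Per-variable mean, sample SD, minimum and maximum of a trial dataset."""

    table: pd.DataFrame  # index: variable; columns: mean, sd, min, max

    def __getitem__(self, variable: str) -> pd.Series:
        return self.table.loc[variable]

    @property
    def variables(self) -> list[str]:
        return list(self.table.index)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="variable")

    @classmethod
    def from_tsv(cls, path) -> "DatasetSummary":
        table = pd.read_csv(path, sep="\t", index_col="variable")
        table.index.name = None
        return cls(table)


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------

def crude_protein_from_n(n: float) -> float:
    """Crude protein (kg/kg DM) from nitrogen concentration, CP = 6.25 N."""
    if np.any(np.asarray(n) < 0):
        raise DomainError("nitrogen concentration must be non-negative")
    return 6.25 * n


def domd_from_components(omd: float, ash: float) -> float:
    """Digestible OM in DM from OM digestibility and ash fraction.

    DOMD = OMD x (1 - ash): the organic matter is (1 - ash) of DM, of which
    a fraction OMD is digested.  On measured data the identity holds only
    approximately; this construction is used to build internally consistent
    synthetic records.
    """
    omd_a, ash_a = np.asarray(omd, dtype=float), np.asarray(ash, dtype=float)
    if np.any((omd_a < 0) | (omd_a > 1)):
        raise DomainError("omd must lie in [0, 1]")
    if np.any((ash_a < 0) | (ash_a > 1)):
        raise DomainError("ash must lie in [0, 1]")
    return omd * (1.0 - ash)


def derive_energy_ratios(de: float, me: float, ge: float) -> EnergyProfile:
    """Fill DE/GE and ME/GE ratios of an energy profile from gross energy."""
    if np.any(np.asarray(ge) <= 0):
        raise DomainError("gross energy must be positive")
    return EnergyProfile(de=de, me=me, de_ge=de / ge, me_ge=me / ge)


def total_digestible_cp(n: float, nd: float) -> float:
    """Total digestible crude protein, g/100 g DM: 100 x 6.25 x N x ND."""
    return 100.0 * crude_protein_from_n(n) * nd


def total_digestible_ndf(ndf: float, ndfd: float) -> float:
    """Total digestible NDF, g/100 g DM: 100 x NDF x NDFD."""
    return 100.0 * ndf * ndfd


# ---------------------------------------------------------------------------
# frames and records
# ---------------------------------------------------------------------------

def frame_from_records(records: Iterable[TrialRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        c, d, e = r.composition, r.digestibility, r.energy
        de_ge = e.de_ge if e.de_ge is not None else e.de / c.ge
        me_ge = e.me_ge if e.me_ge is not None else e.me / c.ge
        tdcp = r.tdcp if r.tdcp is not None else total_digestible_cp(c.n, d.nd)
        tdndf = r.tdndf if r.tdndf is not None else total_digestible_ndf(c.ndf, d.ndfd)
        rows.append({
            "sheep_id": r.sheep_id, "trial_id": r.trial_id,
            "season": r.season, "year": r.year,
            "dm_fresh": c.dm_fresh, "n": c.n, "ndf": c.ndf, "adf": c.adf,
            "ee": c.ee, "ash": c.ash, "ge": c.ge,
            "dmd": d.dmd, "omd": d.omd, "nd": d.nd, "ndfd": d.ndfd,
            "adfd": d.adfd, "ged": d.ged, "domd": d.domd,
            "de": e.de, "me": e.me, "de_ge": de_ge, "me_ge": me_ge,
            "tdcp": tdcp, "tdndf": tdndf,
        })
    return pd.DataFrame(rows, columns=list(ID_VARS) + list(NUMERIC_VARS))


def records_from_frame(frame: pd.DataFrame) -> list[TrialRecord]:
    records = []
    for _, row in frame.iterrows():
        records.append(TrialRecord(
            sheep_id=str(row["sheep_id"]), trial_id=str(row["trial_id"]),
            season=str(row["season"]), year=int(row["year"]),
            composition=HerbageComposition(
                dm_fresh=row["dm_fresh"], n=row["n"], ndf=row["ndf"],
                adf=row["adf"], ee=row["ee"], ash=row["ash"], ge=row["ge"]),
            digestibility=DigestibilityProfile(
                dmd=row["dmd"], omd=row["omd"], nd=row["nd"],
                ndfd=row["ndfd"], adfd=row["adfd"], ged=row["ged"],
                domd=row["domd"]),
            energy=EnergyProfile(
                de=row["de"], me=row["me"],
                de_ge=row.get("de_ge"), me_ge=row.get("me_ge")),
            tdcp=row.get("tdcp"), tdndf=row.get("tdndf"),
        ))
    return records


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return frame_from_records(records)


def write_records_csv(data, path) -> None:
    """Write trial records to the delimited-text exchange schema (CSV)."""
    frame = _as_frame(data)
    out = pd.DataFrame()
    for col, (canon, scale) in CSV_SCHEMA.items():
        if canon in frame.columns:
            out[col] = frame[canon] * scale if scale not in (None, 1.0) else frame[canon]
        else:
            out[col] = np.nan
    out.to_csv(path, index=False)


def read_records_csv(path) -> pd.DataFrame:
    """Read trial records from CSV, converting to storage units.

    Missing values come back as NaN; DE/GE, ME/GE, tdCP and tdNDF are derived
    from the stored columns.
    """
    raw = pd.read_csv(path)
    missing = [c for c in CSV_SCHEMA if c not in raw.columns]
    if missing:
        raise DomainError(f"input file lacks required columns: {missing}")
    frame = pd.DataFrame()
    for col, (canon, scale) in CSV_SCHEMA.items():
        series = raw[col]
        if scale not in (None, 1.0):
            series = series / scale
        frame[canon] = series
    frame["de_ge"] = frame["de"] / frame["ge"]
    frame["me_ge"] = frame["me"] / frame["ge"]
    frame["tdcp"] = 100.0 * 6.25 * frame["n"] * frame["nd"]
    frame["tdndf"] = 100.0 * frame["ndf"] * frame["ndfd"]
    return frame[list(ID_VARS) + list(NUMERIC_VARS)]


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summarize_dataset(records) -> DatasetSummary:
    """Per-variable mean, sample (n-1) SD, min and max over the records."""
    frame = _as_frame(records)
    if len(frame) < 2:
        raise DomainError("summary requires at least 2 records")
    stats = {}
    for var in NUMERIC_VARS:
        if var not in frame.columns:
            continue
        x = frame[var].astype(float)
        if x.notna().sum() == 0:
            continue
        stats[var] = {"mean": x.mean(), "sd": x.std(ddof=1),
                      "min": x.min(), "max": x.max()}
    return DatasetSummary(pd.DataFrame(stats).T[["mean", "sd", "min", "max"]])


def fold_range(records, variable: str) -> float:
    """Max/min ratio of a variable over a dataset (dimensionless).

    The summary statistic quoted for trial datasets ("the maximum DE was 1.9
    times the minimum").  Requires a strictly positive minimum.
    """
    if isinstance(records, DatasetSummary):
        lo, hi = records[variable]["min"], records[variable]["max"]
    else:
        frame = _as_frame(records)
        if variable not in frame.columns:
            raise DomainError(f"unknown variable {variable!r}")
        lo, hi = frame[variable].min(), frame[variable].max()
    if not lo > 0:
        raise DomainError(f"fold range of {variable!r} undefined: minimum {lo} <= 0")
    return float(hi) / float(lo)


def mean_record(summary: DatasetSummary) -> pd.DataFrame:
    """A one-row frame holding every variable at its summary mean.

    tdCP and tdNDF are derived from the mean concentrations and
    digestibilities when the summary does not carry them directly.
    """
    row: dict = {v: summary[v]["mean"] for v in summary.variables}
    row.setdefault("tdcp", 100.0 * 6.25 * row["n"] * row["nd"])
    row.setdefault("tdndf", 100.0 * row["ndf"] * row["ndfd"])
    row.update(sheep_id="mean", trial_id="mean", season="august", year=0)
    return pd.DataFrame([row])


def reference_summary() -> DatasetSummary:
    """The built-in study-scale summary (means, SDs, extremes per variable).

    Values are in storage units (fractions kg/kg DM, energies MJ/kg DM);
    ``dm_fresh`` stays in g/kg fresh.
    """
    text = (importlib.resources.files("herbenergy.data") / "table1_summary.json").read_text()
    data = json.loads(text)
    table = pd.DataFrame(data).T[["mean", "sd", "min", "max"]]
    return DatasetSummary(table)


# ---------------------------------------------------------------------------
# record validation
# ---------------------------------------------------------------------------

def _check(violations, ok: bool, message: str) -> None:
    if not ok:
        violations.append(message)


def validate_record(record: TrialRecord, tdcp_rtol: float = 0.02) -> list[str]:
    """Check every type invariant; returns one message per violation.

    An empty list means the record is internally consistent.  Reporting only:
    never raises.
    """
    v: list[str] = []
    c, d, e = record.composition, record.digestibility, record.energy
    for name in ("n", "ndf", "adf", "ee", "ash"):
        val = getattr(c, name)
        _check(v, 0 <= val <= 1, f"composition.{name}={val}: mass fraction must lie in [0, 1]")
    _check(v, c.ge > 0, f"composition.ge={c.ge}: gross energy must be positive")
    _check(v, 0 <= c.dm_fresh <= 1000,
           f"composition.dm_fresh={c.dm_fresh}: g/kg fresh must lie in [0, 1000]")
    for name in ("dmd", "omd", "nd", "ndfd", "adfd", "ged", "domd"):
        val = getattr(d, name)
        _check(v, 0 <= val <= 1, f"digestibility.{name}={val}: coefficient must lie in [0, 1]")
    _check(v, d.domd <= d.omd + 1e-12,
           f"digestibility.domd={d.domd} exceeds omd={d.omd}: DOMD cannot exceed OMD")
    _check(v, e.me > 0, f"energy.me={e.me}: ME must be positive")
    _check(v, e.me <= e.de + 1e-12,
           f"energy.me={e.me} exceeds de={e.de}: ME cannot exceed DE")
    if e.de_ge is not None and e.me_ge is not None:
        _check(v, e.me_ge <= e.de_ge + 1e-12,
               f"energy.me_ge={e.me_ge} exceeds de_ge={e.de_ge}")
        _check(v, e.de_ge <= 1 + 1e-12, f"energy.de_ge={e.de_ge} exceeds 1")
    if record.season not in SEASONS:
        v.append(f"season={record.season!r}: must be one of {SEASONS}")
    if record.tdcp is not None:
        expected = total_digestible_cp(c.n, d.nd)
        if expected > 0 and not math.isclose(record.tdcp, expected, rel_tol=tdcp_rtol):
            v.append(f"tdcp={record.tdcp} inconsistent with 100 x 6.25 x n x nd = {expected:.4f}")
    return v
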