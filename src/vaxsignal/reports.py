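"""Spontaneous-report data model, file I/O, stratification and pair counting.

One row of a reports file is one vaccine-event *mention*: a case report that
lists k suspected adverse events for one vaccine yields k rows sharing a
``report_id``.  Everything downstream (disproportionality counts, time-to-onset
samples, the evaluation universe) is defined over these mentions and the
vaccine-event pairs they induce.
"""
from __future__ import annotations

import datetime as dt
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "UNKNOWN",
    "Report",
    "PairKey",
    "StratumSpec",
    "ALL_STRATIFICATIONS",
    "GoldStandard",
    "PairCountTable",
    "ValidationSummary",
    "read_reports",
    "write_reports",
    "reports_to_frame",
    "frame_to_reports",
    "assign_stratum",
    "assign_strata_frame",
    "build_pair_counts",
    "read_gold_standard",
    "write_gold_standard",
]

UNKNOWN = "UNKNOWN"
#: tokens parsed as missing/unknown by default (configurable via ``dialect``)
DEFAULT_NA_TOKENS = ("", "NA")

#: default right-open age intervals separating paediatric, adolescent and
#: adult vaccine populations; configurable everywhere a StratumSpec is built.
DEFAULT_AGE_EDGES = (0.0, 2.0, 12.0, 18.0, 46.0, 66.0, float("inf"))

_FACTOR_ORDER = "SARY"
#: the 16 admissible stratification factor subsets ("" = unstratified)
ADMISSIBLE_FACTOR_SETS = (
    "", "S", "A", "R", "Y",
    "SA", "SR", "SY", "AR", "AY", "RY",
    "SAR", "SAY", "ARY", "SRY", "SARY",
)

REPORT_COLUMNS = (
    "report_id", "receipt_date", "vaccine", "event",
    "sex", "age_years", "region", "tto_days",
)
MANDATORY_COLUMNS = ("report_id", "receipt_date", "vaccine", "event")


class PairKey(NamedTuple):
    """A vaccine-event pair, the unit of signal detection."""

    vaccine: str
    event: str


@dataclass(frozen=True)
class Report:
    """One spontaneous vaccine-event mention.

    ``sex`` is one of ``"F"``, ``"M"`` or ``UNKNOWN``; ``age_years`` and
    ``region`` are None when unknown; ``tto_days`` (days between immunisation
    and event onset) is None when missing and otherwise a non-negative int.
    """

    report_id: str
    receipt_date: dt.date
    vaccine: str
    event: str
    sex: str = UNKNOWN
    age_years: float | None = None
    region: str | None = None
    tto_days: int | None = None

    @property
    def report_year(self) -> int:
        return self.receipt_date.year

    @property
    def pair(self) -> PairKey:
        return PairKey(self.vaccine, self.event)

    def __post_init__(self) -> None:
        if not self.vaccine or not self.event:
            raise ValueError("vaccine and event codes must be non-empty")
        if self.sex not in ("F", "M", UNKNOWN):
            raise ValueError(f"invalid sex code {self.sex!r}")
        if self.age_years is not None and self.age_years < 0:
            raise ValueError("age_years must be non-negative")
        if self.tto_days is not None and self.tto_days < 0:
            raise ValueError("tto_days must be non-negative")


def _age_bin_labels(edges: Sequence[float]) -> list[str]:
    labels = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if np.isinf(hi):
            labels.append(f"{int(lo)}+")
        else:
            labels.append(f"{int(lo)}-{int(hi) - 1}")
    return labels


@dataclass(frozen=True)
class StratumSpec:
    """A choice of stratification factors among (S)ex, (A)ge, (R)egion, (Y)ear.

    ``factors`` is a string over "SARY" (order-insensitive input, stored in
    canonical SARY order); the empty string is the unstratified analysis,
    labelled "U".  Age is binned into the right-open intervals defined by
    ``age_edges``, which must start at 0 and end at +inf.
    """

    factors: str = ""
    age_edges: tuple[float, ...] = DEFAULT_AGE_EDGES

    def __post_init__(self) -> None:
        upper = set(self.factors.upper())
        if upper - set(_FACTOR_ORDER):
            raise ValueError(f"unknown stratification factors in {self.factors!r}")
        canonical = "".join(f for f in _FACTOR_ORDER if f in upper)
        object.__setattr__(self, "factors", canonical)
        edges = tuple(float(e) for e in self.age_edges)
        if edges[0] != 0.0 or not np.isinf(edges[-1]) or list(edges) != sorted(set(edges)):
            raise ValueError("age_edges must increase from 0 to +inf")
        object.__setattr__(self, "age_edges", edges)

    @property
    def label(self) -> str:
        return self.factors if self.factors else "U"

    @property
    def age_labels(self) -> tuple[str, ...]:
        return tuple(_age_bin_labels(self.age_edges))

    def age_bin(self, age_years: float | None) -> str:
        if age_years is None or (isinstance(age_years, float) and np.isnan(age_years)):
            return "UNK"
        idx = int(np.searchsorted(self.age_edges, age_years, side="right")) - 1
        return self.age_labels[min(idx, len(self.age_labels) - 1)]


ALL_STRATIFICATIONS = tuple(StratumSpec(f) for f in ADMISSIBLE_FACTOR_SETS)


def assign_stratum(report: Report, spec: StratumSpec) -> str:
    """Stratum label of one report under ``spec`` ("ALL" when unstratified).

    Unknown values map to a dedicated "UNK" level per factor so that counts
    are conserved between stratified and unstratified analyses.
    """
    if not spec.factors:
        return "ALL"
    parts = []
    for f in spec.factors:
        if f == "S":
            parts.append(report.sex if report.sex in ("F", "M") else "UNK")
        elif f == "A":
            parts.append(spec.age_bin(report.age_years))
        elif f == "R":
            parts.append(report.region if report.region else "UNK")
        elif f == "Y":
            parts.append(str(report.report_year))
    return "|".join(parts)


def assign_strata_frame(df: pd.DataFrame, spec: StratumSpec) -> pd.Series:
    """Vectorised :func:`assign_stratum` over a reports frame."""
    if not spec.factors:
        return pd.Series("ALL", index=df.index)
    cols: list[pd.Series] = []
    for f in spec.factors:
        if f == "S":
            s = df["sex"].where(df["sex"].isin(["F", "M"]), "UNK").astype(str)
        elif f == "A":
            age = pd.to_numeric(df["age_years"], errors="coerce")
            binned = pd.cut(age, bins=list(spec.age_edges), right=False,
                            labels=list(spec.age_labels))
            s = binned.astype(object).fillna("UNK").astype(str)
        elif f == "R":
            s = df["region"].astype(object).fillna("UNK").replace("", "UNK").astype(str)
        elif f == "Y":
            s = df["report_year"].astype(int).astype(str)
        cols.append(s)
    out = cols[0]
    for c in cols[1:]:
        out = out.str.cat(c, sep="|")
    return out


# ---------------------------------------------------------------------------
# frames <-> Report lists


def reports_to_frame(reports: Iterable[Report] | pd.DataFrame) -> pd.DataFrame:
    """Canonical DataFrame view of a report collection.

    Columns: the reports-file columns plus a derived ``report_year``.
    ``age_years`` / ``tto_days`` use NaN for unknown/missing; ``sex`` keeps
    the three-level code; ``region`` uses None for unknown.
    """
    if isinstance(reports, pd.DataFrame):
        df = reports.copy()
        if "report_year" not in df.columns:
            df["report_year"] = pd.to_datetime(df["receipt_date"]).dt.year
        return df
    rows = [
        (r.report_id, r.receipt_date, r.vaccine, r.event, r.sex,
         np.nan if r.age_years is None else float(r.age_years),
         r.region,
         np.nan if r.tto_days is None else float(r.tto_days),
         r.report_year)
        for r in reports
    ]
    return pd.DataFrame(rows, columns=list(REPORT_COLUMNS) + ["report_year"])


def frame_to_reports(df: pd.DataFrame) -> list[Report]:
    out = []
    for row in df.itertuples(index=False):
        date = row.receipt_date
        if not isinstance(date, dt.date) or isinstance(date, pd.Timestamp):
            date = pd.Timestamp(date).date()
        age = getattr(row, "age_years", None)
        tto = getattr(row, "tto_days", None)
        region = getattr(row, "region", None)
        out.append(Report(
            report_id=str(row.report_id),
            receipt_date=date,
            vaccine=str(row.vaccine),
            event=str(row.event),
            sex=getattr(row, "sex", UNKNOWN) or UNKNOWN,
            age_years=None if age is None or (isinstance(age, float) and np.isnan(age)) else float(age),
            region=None if region is None or (isinstance(region, float) and np.isnan(region)) or region == "" else str(region),
            tto_days=None if tto is None or (isinstance(tto, float) and np.isnan(tto)) else int(tto),
        ))
    return out


# ---------------------------------------------------------------------------
# reports file I/O


@dataclass
class ValidationSummary:
    """Row-level accounting of a reports-file read."""

    n_rows: int = 0
    n_valid: int = 0
    reasons: Counter = field(default_factory=Counter)

    @property
    def n_rejected(self) -> int:
        return self.n_rows - self.n_valid


class ReportsFormatError(ValueError):
    """The file cannot be interpreted as a reports table at all."""


def _detect_sep(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") > header.count(",") else ","


def read_reports(path, dialect: Mapping | None = None) -> tuple[list[Report], ValidationSummary]:
    """Read a delimited reports file.

    ``dialect`` may carry ``sep`` (default: sniffed comma/tab) and
    ``na_tokens`` (default ``("", "NA")``) for UNKNOWN/MISSING coding.
    Rows whose mandatory fields (report_id, receipt_date, vaccine, event) do
    not parse, or that violate invariants (negative tto_days or age, a
    report_year column inconsistent with receipt_date), are rejected and
    tallied in the returned :class:`ValidationSummary`.
    """
    dialect = dict(dialect or {})
    sep = dialect.get("sep") or _detect_sep(path)
    na_tokens = set(dialect.get("na_tokens", DEFAULT_NA_TOKENS))

    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ReportsFormatError(f"missing mandatory columns: {missing}")

    summary = ValidationSummary(n_rows=len(df))

    def _is_na(s: pd.Series) -> pd.Series:
        return s.str.strip().isin(na_tokens)

    dates = pd.to_datetime(df["receipt_date"], format="ISO8601", errors="coerce")
    bad = pd.Series(False, index=df.index)

    for col in ("vaccine", "event", "report_id"):
        m = _is_na(df[col])
        summary.reasons[f"missing_{col}"] += int((m & ~bad).sum())
        bad |= m
    m = dates.isna()
    summary.reasons["bad_receipt_date"] += int((m & ~bad).sum())
    bad |= m

    if "age_years" in df.columns:
        age = pd.to_numeric(df["age_years"].where(~_is_na(df["age_years"])), errors="coerce")
        m = ~_is_na(df["age_years"]) & age.isna()
        summary.reasons["bad_age_years"] += int((m & ~bad).sum())
        bad |= m
        m = age < 0
        summary.reasons["negative_age_years"] += int((m & ~bad).sum())
        bad |= m
    else:
        age = pd.Series(np.nan, index=df.index)

    if "tto_days" in df.columns:
        tto = pd.to_numeric(df["tto_days"].where(~_is_na(df["tto_days"])), errors="coerce")
        m = ~_is_na(df["tto_days"]) & tto.isna()
        summary.reasons["bad_tto_days"] += int((m & ~bad).sum())
        bad |= m
        m = tto < 0
        summary.reasons["negative_tto_days"] += int((m & ~bad).sum())
        bad |= m
    else:
        tto = pd.Series(np.nan, index=df.index)

    if "report_year" in df.columns:
        year = pd.to_numeric(df["report_year"].where(~_is_na(df["report_year"])), errors="coerce")
        m = year.notna() & dates.notna() & (year != dates.dt.year)
        summary.reasons["report_year_mismatch"] += int((m & ~bad).sum())
        bad |= m

    if "sex" in df.columns:
        sex = df["sex"].str.strip().str.upper()
        sex = sex.where(sex.isin(["F", "M"]), UNKNOWN)
    else:
        sex = pd.Series(UNKNOWN, index=df.index)

    if "region" in df.columns:
        region = df["region"].where(~_is_na(df["region"]), None)
    else:
        region = pd.Series(None, index=df.index, dtype=object)

    keep = ~bad
    reports = []
    for i in df.index[keep]:
        reports.append(Report(
            report_id=df.at[i, "report_id"].strip(),
            receipt_date=dates[i].date(),
            vaccine=df.at[i, "vaccine"].strip(),
            event=df.at[i, "event"].strip(),
            sex=sex[i],
            age_years=None if np.isnan(age[i]) else float(age[i]),
            region=region[i],
            tto_days=None if np.isnan(tto[i]) else int(tto[i]),
        ))
    summary.n_valid = len(reports)
    return reports, summary


def write_reports(reports: Iterable[Report] | pd.DataFrame, path, sep: str = ",") -> None:
    """Write reports as delimited text (the format :func:`read_reports` reads)."""
    df = reports_to_frame(reports)
    out = pd.DataFrame({
        "report_id": df["report_id"],
        "receipt_date": pd.to_datetime(df["receipt_date"]).dt.strftime("%Y-%m-%d"),
        "vaccine": df["vaccine"],
        "event": df["event"],
        "sex": df["sex"].replace(UNKNOWN, ""),
        "age_years": df["age_years"],
        "region": df["region"].fillna(""),
        "tto_days": df["tto_days"].map(lambda v: "" if pd.isna(v) else str(int(v))),
    })
    out.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# pair counts


@dataclass
class PairCountTable:
    """Per-stratum vaccine-event counts with their Mantel-Haenszel margins.

    ``cells`` is indexed by (vaccine, event, stratum); the margins are the
    per-stratum row totals (vaccine), column totals (event) and grand totals
    that the stratified expected counts are built from.
    """

    spec: StratumSpec
    cells: pd.Series
    vaccine_totals: pd.Series
    event_totals: pd.Series
    stratum_totals: pd.Series

    @property
    def total(self) -> int:
        return int(self.stratum_totals.sum())

    def pair_totals(self) -> pd.Series:
        """Total N per vaccine-event pair (summed over strata)."""
        return self.cells.groupby(level=["vaccine", "event"]).sum()

    @property
    def pairs(self) -> list[PairKey]:
        return [PairKey(v, e) for v, e in self.pair_totals().index]


def build_pair_counts(reports: Iterable[Report] | pd.DataFrame,
                      spec: StratumSpec) -> PairCountTable:
    """Count report rows per (vaccine, event, stratum) and tally the margins."""
    df = reports_to_frame(reports)
    if len(df) == 0:
        raise ValueError("cannot build pair counts from an empty report list")
    stratum = assign_strata_frame(df, spec)
    work = pd.DataFrame({"vaccine": df["vaccine"], "event": df["event"],
                         "stratum": stratum})
    cells = work.groupby(["vaccine", "event", "stratum"]).size()
    vac = work.groupby(["vaccine", "stratum"]).size()
    eve = work.groupby(["event", "stratum"]).size()
    tot = work.groupby("stratum").size()
    return PairCountTable(spec=spec, cells=cells, vaccine_totals=vac,
                          event_totals=eve, stratum_totals=tot)


# ---------------------------------------------------------------------------
# gold standard


class GoldStandard:
    """Mapping from vaccine to the set of event codes deemed truly associated.

    The label set is a proxy for true signals (product-label adverse
    reactions).  ``lookup`` distinguishes three cases: labelled (True),
    reported-but-unlabelled (False) and vaccine-not-covered (None) — pairs of
    uncovered vaccines cannot be evaluated at all.
    """

    def __init__(self, mapping: Mapping[str, Iterable[str]]):
        self._map: dict[str, frozenset[str]] = {
            str(v): frozenset(map(str, events)) for v, events in mapping.items()
        }
        if not self._map:
            raise ValueError("gold standard is empty: evaluation impossible")

    @property
    def vaccines(self) -> frozenset[str]:
        return frozenset(self._map)

    def covers(self, vaccine: str) -> bool:
        return vaccine in self._map

    def events(self, vaccine: str) -> frozenset[str]:
        return self._map[vaccine]

    def lookup(self, vaccine: str, event: str) -> bool | None:
        if vaccine not in self._map:
            return None
        return event in self._map[vaccine]

    def is_labelled(self, pair: PairKey | tuple[str, str]) -> bool:
        v, e = pair
        status = self.lookup(v, e)
        if status is None:
            raise KeyError(f"vaccine {v!r} not covered by the gold standard")
        return status

    def n_labelled(self) -> int:
        return sum(len(s) for s in self._map.values())

    def __eq__(self, other) -> bool:
        return isinstance(other, GoldStandard) and self._map == other._map

    def __repr__(self) -> str:
        return f"GoldStandard({len(self._map)} vaccines, {self.n_labelled()} labelled pairs)"


def read_gold_standard(path, sep: str | None = None) -> GoldStandard:
    """Read a two-column (vaccine, event) file; duplicate rows collapse."""
    sep = sep or _detect_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ReportsFormatError("gold standard needs two columns (vaccine, event)")
    if len(df) == 0:
        raise ValueError("gold standard file has no labelled pairs")
    vcol, ecol = df.columns[:2]
    mapping: dict[str, set[str]] = {}
    for v, e in zip(df[vcol], df[ecol]):
        mapping.setdefault(v.strip(), set()).add(e.strip())
    return GoldStandard(mapping)


def write_gold_standard(gold: GoldStandard, path, sep: str = ",") -> None:
    rows = [(v, e) for v in sorted(gold.vaccines) for e in sorted(gold.events(v))]
    pd.DataFrame(rows, columns=["vaccine", "event"]).to_csv(path, sep=sep, index=False)
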