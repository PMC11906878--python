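"""Read and filter occurrence tables into the pipeline's data model.

Input files are Darwin-Core-like delimited tables, one row per georeferenced
species observation.  Parsing applies the study filters up front: only
georeferenced human observations carrying a recognised country code are kept,
and every rejected row is tallied by reason in a structured
:class:`RejectionReport` so the filtering is auditable rather than silent.
"""

from __future__ import annotations

import datetime as dt
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

from ._countries import COUNTRY_CODES, HIGH_SEAS

__all__ = [
    "OccurrenceRecord",
    "PeriodWindow",
    "RejectionReport",
    "ParseResult",
    "parse_occurrences",
    "exclude_high_seas",
    "count_records",
    "lockdown_window",
]

#: Column names accepted for each logical field (first match wins).
_COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "record_id": ("id", "occurrenceID", "gbifID", "record_id"),
    "country_code": ("countryCode", "country_code"),
    "event_date": ("eventDate", "event_date"),
    "lat": ("decimalLatitude", "lat"),
    "lon": ("decimalLongitude", "lon"),
    "basis": ("basisOfRecord", "basis"),
    "dataset_tag": ("datasetKey", "datasetTag", "dataset_tag"),
    "observer_id": ("observerId", "recordedBy", "observer_id"),
}

_REQUIRED = ("record_id", "country_code", "event_date", "lat", "lon", "basis",
             "dataset_tag")


class ConfigurationError(ValueError):
    """A required input column is missing or an option is inconsistent."""


@dataclass(frozen=True)
class OccurrenceRecord:
    """One georeferenced species observation.

    ``basis`` is collapsed to the binary the analysis needs
    (``human_observation`` vs ``other``), and ``dataset_tag`` to
    ``ebird`` vs ``other``.  ``observer_id`` is present exactly when the
    record comes from the eBird dataset.
    """

    record_id: str
    country_code: str
    event_date: dt.date
    lat: float
    lon: float
    basis: Literal["human_observation", "other"]
    dataset_tag: Literal["ebird", "other"]
    observer_id: str | None = None


@dataclass(frozen=True)
class PeriodWindow:
    """A closed within-year calendar window, e.g. the lockdown window.

    The default window runs March 15 to May 1 inclusive — 48 days in both
    2019 and 2020 — and both endpoints count ("between" read inclusively).
    """

    year: int
    start_month_day: tuple[int, int] = (3, 15)
    end_month_day: tuple[int, int] = (5, 1)

    def __post_init__(self) -> None:
        if self.start_date > self.end_date:
            raise ValueError(
                f"window start {self.start_date} is after end {self.end_date}")

    @property
    def start_date(self) -> dt.date:
        return dt.date(self.year, *self.start_month_day)

    @property
    def end_date(self) -> dt.date:
        return dt.date(self.year, *self.end_month_day)

    @property
    def n_days(self) -> int:
        return (self.end_date - self.start_date).days + 1

    def contains(self, date: dt.date) -> bool:
        """True iff ``date`` falls inside the closed window."""
        return self.start_date <= date <= self.end_date


def lockdown_window(year: int) -> PeriodWindow:
    """The March 15 – May 1 window for ``year`` (the study's focal window)."""
    return PeriodWindow(year=year)


@dataclass
class RejectionReport:
    """Counts of rows rejected during parsing, keyed by reason."""

    counts: Counter = field(default_factory=Counter)

    def add(self, reason: str) -> None:
        self.counts[reason] += 1

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)


@dataclass
class ParseResult:
    """Records retained by the parse filters plus the rejection tally."""

    records: list[OccurrenceRecord]
    rejections: RejectionReport

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _resolve_columns(columns: Sequence[str]) -> dict[str, str]:
    resolved: dict[str, str] = {}
    for logical, aliases in _COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in columns:
                resolved[logical] = alias
                break
    missing = [c for c in _REQUIRED if c not in resolved]
    if missing:
        raise ConfigurationError(
            f"occurrence file is missing required column(s): {missing}; "
            f"found columns {list(columns)}")
    return resolved


def _normalise_basis(raw: str) -> str:
    return ("human_observation"
            if str(raw).strip().upper() in {"HUMAN_OBSERVATION",
                                            "HUMANOBSERVATION"}
            else "other")


def _normalise_dataset(raw: str) -> str:
    return "ebird" if str(raw).strip().lower() == "ebird" else "other"


def parse_occurrences(
    path: str | Path,
    code_list: Iterable[str] = COUNTRY_CODES,
    dialect: Literal["tab", "csv"] = "tab",
) -> ParseResult:
    """Parse an occurrence table, applying the study's retention filters.

    Retained records are georeferenced, tagged as human observations, and
    carry a recognised country code.  Every other row is counted in the
    rejection report under the first filter it fails (missing fields,
    bad coordinates, unparsable date, unrecognised country, non-human basis).

    Parameters
    ----------
    path
        Tab-delimited (default) or comma-delimited file with a header.
    code_list
        Recognised country codes; defaults to the 249 ISO 3166-1 alpha-2
        codes plus ``XK`` and ``ZZ``.
    dialect
        ``"tab"`` or ``"csv"``.
    """
    codes = frozenset(code_list)
    sep = "\t" if dialect == "tab" else ","
    try:
        frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except OSError as exc:  # pragma: no cover - passthrough
        raise IOError(f"cannot read occurrence file {path}: {exc}") from exc
    colmap = _resolve_columns(frame.columns)

    records: list[OccurrenceRecord] = []
    report = RejectionReport()
    has_observer = "observer_id" in colmap
    cols = {k: frame[v].to_numpy() for k, v in colmap.items()}
    n = len(frame)
    for i in range(n):
        lat_raw, lon_raw = cols["lat"][i].strip(), cols["lon"][i].strip()
        if not lat_raw or not lon_raw:
            report.add("not_georeferenced")
            continue
        try:
            lat, lon = float(lat_raw), float(lon_raw)
        except ValueError:
            report.add("not_georeferenced")
            continue
        if not (-90.0 <= lat <= 90.0 and -180.0 <= lon <= 180.0):
            report.add("coordinates_out_of_range")
            continue
        basis = _normalise_basis(cols["basis"][i])
        if basis != "human_observation":
            report.add("basis_not_human_observation")
            continue
        code = cols["country_code"][i].strip().upper()
        if code not in codes:
            report.add("unrecognised_country_code")
            continue
        try:
            date = dt.date.fromisoformat(cols["event_date"][i].strip()[:10])
        except ValueError:
            report.add("unparsable_event_date")
            continue
        tag = _normalise_dataset(cols["dataset_tag"][i])
        observer = None
        if tag == "ebird" and has_observer:
            obs_raw = cols["observer_id"][i].strip()
            observer = obs_raw or None
        records.append(OccurrenceRecord(
            record_id=str(cols["record_id"][i]),
            country_code=code,
            event_date=date,
            lat=lat,
            lon=lon,
            basis=basis,
            dataset_tag=tag,
            observer_id=observer,
        ))
    return ParseResult(records=records, rejections=report)


def exclude_high_seas(
    records: Iterable[OccurrenceRecord],
) -> list[OccurrenceRecord]:
    """Drop records collected in international waters (country code ``ZZ``)."""
    return [r for r in records if r.country_code != HIGH_SEAS]


_KEY_GETTERS = {
    "country": lambda r: r.country_code,
    "observer": lambda r: r.observer_id,
    "dataset_tag": lambda r: r.dataset_tag,
}


def count_records(
    records: Iterable[OccurrenceRecord],
    window: PeriodWindow,
    keys: Sequence[str] = ("country",),
    universe: Iterable | None = None,
) -> pd.Series:
    """Count records inside the closed window, grouped by ``keys``.

    Parameters
    ----------
    records
        Occurrence records (any order; counting is order-invariant).
    window
        Closed calendar window; a record dated on either endpoint counts.
    keys
        Grouping among ``{"country", "observer", "dataset_tag"}``.
    universe
        Optional explicit key universe.  Keys absent from the data appear
        with count 0 only when a universe is supplied.

    Returns
    -------
    pandas.Series
        Non-negative integer counts indexed by the grouping key(s).
    """
    unknown = [k for k in keys if k not in _KEY_GETTERS]
    if unknown:
        raise ValueError(f"unknown grouping key(s) {unknown}; "
                         f"choose among {sorted(_KEY_GETTERS)}")
    getters = [_KEY_GETTERS[k] for k in keys]
    counter: Counter = Counter()
    for rec in records:
        if window.contains(rec.event_date):
            key = tuple(g(rec) for g in getters)
            counter[key if len(key) > 1 else key[0]] += 1
    if universe is not None:
        for key in universe:
            counter.setdefault(key, 0)
    series = pd.Series(counter, dtype="int64", name="n_records")
    series = series.sort_index()
    series.index.name = keys[0] if len(keys) == 1 else None
    if len(keys) > 1 and len(series):
        series.index.names = list(keys)
    return series
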