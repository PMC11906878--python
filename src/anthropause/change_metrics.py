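"""The percent-change-in-records statistic and its modelling transform.

For a country with ``n_t0`` records in the baseline window and ``n_t1`` in
the lockdown window,

    change_pct = (n_t1 - n_t0) / n_t0 * 100

which is bounded below by -100 (no records at all during lockdown) and
undefined when the baseline is empty.  Because equal-length windows are
compared, the statistic is identical whether computed from window totals or
from mean daily counts.  For regression modelling the response is
``log10(change_pct + 100)``, which symmetrises the heavy right skew of
percent changes; it is undefined at exactly -100, and such countries are
excluded from the model frame with a logged warning rather than patched
with an epsilon.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "ChangeRecordsResult",
    "UndefinedBaselineError",
    "TransformDomainError",
    "compute_change_records",
    "log_offset_transform",
    "change_table",
]

logger = logging.getLogger(__name__)


class UndefinedBaselineError(ValueError):
    """Raised when the baseline window holds zero records."""

    def __init__(self, country_code: str | None = None):
        self.country_code = country_code
        where = f" for {country_code}" if country_code else ""
        super().__init__(
            f"change in records is undefined{where}: no baseline records")


class TransformDomainError(ValueError):
    """Raised for the log-offset transform at change_pct = -100."""


@dataclass(frozen=True)
class ChangeRecordsResult:
    country_code: str
    n_t0: int
    n_t1: int
    change_pct: float

    @property
    def log_change(self) -> float:
        return log_offset_transform(self.change_pct)


def compute_change_records(n_t0: int, n_t1: int,
                           country_code: str | None = None) -> float:
    """Percent change in record counts between two matched windows."""
    if n_t0 <= 0:
        raise UndefinedBaselineError(country_code)
    return (n_t1 - n_t0) / n_t0 * 100.0


def log_offset_transform(change_pct: float) -> float:
    """``log10(change_pct + 100)`` — the regression response scale."""
    if change_pct <= -100.0:
        raise TransformDomainError(
            f"log-offset transform undefined at change_pct={change_pct} "
            "(no lockdown records); exclude the country from the response")
    return math.log10(change_pct + 100.0)


def change_table(counts_t0: pd.Series, counts_t1: pd.Series) -> pd.DataFrame:
    """Per-country change table from two per-country count series.

    Countries missing from either series are treated as zero-count in that
    window.  Countries with an empty baseline are excluded (logged, mirroring
    the territories the study could not compute); countries with
    ``change_pct = -100`` keep their row but get ``log_change = NaN`` with a
    warning, since the transform is undefined there.

    Returns a frame with columns
    ``country_code, n_t0, n_t1, change_pct, log_change``.
    """
    idx = counts_t0.index.union(counts_t1.index)
    t0 = counts_t0.reindex(idx, fill_value=0).astype(int)
    t1 = counts_t1.reindex(idx, fill_value=0).astype(int)
    rows = []
    skipped: list[str] = []
    for code in idx:
        if t0[code] == 0:
            skipped.append(str(code))
            continue
        change = compute_change_records(int(t0[code]), int(t1[code]), code)
        if change <= -100.0:
            logger.warning(
                "country %s has no lockdown records (change = -100%%); "
                "log_change is undefined and set to NaN", code)
            log_change = float("nan")
        else:
            log_change = log_offset_transform(change)
        rows.append((code, int(t0[code]), int(t1[code]), change, log_change))
    if skipped:
        logger.info("change in records undefined (no baseline records) "
                    "for %d unit(s): %s", len(skipped), ", ".join(skipped))
    return pd.DataFrame(
        rows, columns=["country_code", "n_t0", "n_t1",
                       "change_pct", "log_change"])
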