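"""Assemble the per-country covariate table and the regression frame.

Each country carries five covariates for the change-in-records regression:
the 0-100 government-response stringency index, the percent change in park
visitors and in time spent at home (both relative to a pre-pandemic
baseline), population size, and a four-level economic development class
(developed / emerging / developing / least developed, in that order,
"developed" being the modelling reference level).

The regression frame is the inner join of the per-country change table with
the covariate table, with incomplete rows dropped (and listed), population
log10-transformed, and a Spearman collinearity screen applied: time-at-home
is strongly rank-correlated with park visitors (the generator targets
rho = -0.74), so it is dropped from the model by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from ._countries import ECONOMIC_CLASSES

__all__ = [
    "COVARIATE_COLUMNS",
    "CONTINUOUS_COVARIATES",
    "CollinearityReport",
    "assemble_frame",
    "collinearity_screen",
]

logger = logging.getLogger(__name__)

COVARIATE_COLUMNS = (
    "country_code",
    "stringency_index",
    "change_park_visitors",
    "change_time_at_home",
    "population_size",
    "economic_class",
)

#: Continuous covariates entering the collinearity screen.
CONTINUOUS_COVARIATES = (
    "stringency_index",
    "change_park_visitors",
    "change_time_at_home",
    "log10_population_size",
)


class ConfigurationError(ValueError):
    pass


def _validate_covariates(covars: pd.DataFrame) -> None:
    missing = [c for c in COVARIATE_COLUMNS if c not in covars.columns]
    if missing:
        raise ConfigurationError(
            f"covariate table is missing column(s): {missing}")
    bad_class = set(covars["economic_class"].dropna()) - set(ECONOMIC_CLASSES)
    if bad_class:
        raise ConfigurationError(
            f"unknown economic class value(s): {sorted(bad_class)}; "
            f"expected {ECONOMIC_CLASSES}")
    si = covars["stringency_index"].dropna()
    if len(si) and ((si < 0) | (si > 100)).any():
        raise ConfigurationError("stringency_index must lie in [0, 100]")
    pop = covars["population_size"].dropna()
    if len(pop) and (pop <= 0).any():
        raise ConfigurationError("population_size must be positive")


def assemble_frame(changes: pd.DataFrame,
                   covars: pd.DataFrame) -> pd.DataFrame:
    """Inner-join change results with covariates into the model frame.

    Rows with any missing covariate (or an undefined log response) are
    dropped, and the dropped country codes are logged — in the study design
    roughly half the administrative units fall out here for lack of
    mobility or stringency data.  ``population_size`` is replaced by
    ``log10_population_size``.

    The returned frame has columns: ``country_code``, ``n_t0``, ``n_t1``,
    ``change_pct``, ``log_change``, ``stringency_index``,
    ``change_park_visitors``, ``change_time_at_home``,
    ``log10_population_size``, ``economic_class`` (ordered categorical,
    reference first).
    """
    _validate_covariates(covars)
    merged = changes.merge(covars, on="country_code", how="inner")
    if merged.empty:
        raise ConfigurationError(
            "change table and covariate table share no country codes")
    merged["log10_population_size"] = np.log10(
        merged["population_size"].astype(float))
    needed = ["log_change", "stringency_index", "change_park_visitors",
              "change_time_at_home", "log10_population_size",
              "economic_class"]
    complete = merged[needed].notna().all(axis=1)
    dropped = merged.loc[~complete, "country_code"].tolist()
    if dropped:
        logger.info("dropping %d country(ies) with incomplete covariates "
                    "or undefined response: %s",
                    len(dropped), ", ".join(map(str, dropped)))
    frame = merged.loc[complete].drop(columns=["population_size"])
    frame["economic_class"] = pd.Categorical(
        frame["economic_class"], categories=list(ECONOMIC_CLASSES),
        ordered=True)
    frame = frame.sort_values("country_code").reset_index(drop=True)
    frame.attrs["dropped_countries"] = dropped
    return frame


@dataclass
class CollinearityReport:
    """Spearman rank correlations between continuous covariate pairs."""

    threshold: float
    correlations: pd.DataFrame  # columns: var_a, var_b, rho, flagged
    dropped: list[str] = field(default_factory=list)

    @property
    def flagged_pairs(self) -> pd.DataFrame:
        return self.correlations[self.correlations["flagged"]]


def collinearity_screen(
    frame: pd.DataFrame,
    threshold: float = 0.7,
    drop: str | None = "change_time_at_home",
) -> tuple[pd.DataFrame, CollinearityReport]:
    """Screen continuous covariates for rank collinearity.

    Computes Spearman's rho for every pair of continuous covariates present
    in ``frame``; pairs with ``|rho| >= threshold`` are flagged.  If any
    flagged pair involves ``drop`` (default: time-at-home, the member the
    study design chose to sacrifice), that column is removed from the
    returned frame.  Pairs involving a constant column get ``rho = NaN``
    and are reported as undefined.

    Returns ``(screened_frame, report)``.
    """
    cols = [c for c in CONTINUOUS_COVARIATES if c in frame.columns]
    if len(frame) < 3:
        raise ValueError("need at least 3 complete rows for the screen")
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            xa = frame[a].to_numpy(dtype=float)
            xb = frame[b].to_numpy(dtype=float)
            if np.ptp(xa) == 0 or np.ptp(xb) == 0:
                rho = float("nan")  # undefined for a constant column
            else:
                rho = float(spearmanr(xa, xb).statistic)
            flagged = (not math.isnan(rho)) and abs(rho) >= threshold
            rows.append((a, b, rho, flagged))
    corr = pd.DataFrame(rows, columns=["var_a", "var_b", "rho", "flagged"])
    dropped: list[str] = []
    if drop is not None and drop in frame.columns:
        hit = corr["flagged"] & ((corr["var_a"] == drop) |
                                 (corr["var_b"] == drop))
        if hit.any():
            partners = sorted((set(corr.loc[hit, "var_a"]) |
                               set(corr.loc[hit, "var_b"])) - {drop})
            frame = frame.drop(columns=[drop])
            dropped.append(drop)
            logger.info("dropping %s (|rho| >= %.2f with %s)", drop,
                        threshold, ", ".join(partners))
    return frame, CollinearityReport(threshold=threshold,
                                     correlations=corr, dropped=dropped)
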