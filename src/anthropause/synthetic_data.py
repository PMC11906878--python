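"""Synthetic occurrence worlds with declared ground truth.

Every pipeline stage is testable without downloading anything: this module
generates Darwin-Core-like occurrence tables, observer populations and
country covariate tables whose generating parameters — per-country Poisson
rates, lockdown multipliers, observer itineraries — are emitted alongside
the data in a ground-truth ledger.

Generating model
----------------
* Yearly window counts per country are Poisson with mean
  ``lambda0 * (1 + g)**(year - 2010)`` (occurrence archives grow roughly
  exponentially), multiplied in 2020 by a per-country lockdown multiplier
  ``m_c``: a per-economic-class level (defaults: developed 1.1, emerging
  0.9, developing 0.6, least developed 0.5) with mean-corrected lognormal
  country-level heterogeneity.  Effects are multiplicative on Poisson means,
  matching the percent-change semantics of the response.
* Observers have a home country; in 2019 each travels with probability
  ``p_travel`` to a destination sampled by economic-class preference
  weights.  In 2020 travel is governed by a single borders switch — closed
  (the lockdown scenario: nobody travels) or open.  Records are allocated
  to the observers present in a country by a multinomial draw with
  per-observer Gamma activity weights, dated uniformly inside the window,
  and placed along a bounded random walk (step scale sigma, halved-scale
  sigma_lock in 2020).
* Covariates: stringency is drawn per class around class means; the
  park-visitor change is tied to the realised lockdown multiplier through a
  Gaussian copula (so mobility genuinely correlates with the effect it
  proxies); time-at-home is copula-correlated with park visitors at
  rho = -0.74; population sizes are log-uniform.

Identical (config, seed) pairs give identical outputs.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._countries import ECONOMIC_CLASSES
from .ingest import OccurrenceRecord, PeriodWindow

__all__ = [
    "CountryConfig",
    "ObserverConfig",
    "CovariateConfig",
    "SyntheticWorldConfig",
    "WorldData",
    "default_world",
    "generate_world",
    "simulate_change_frame",
    "simulate_trend_series",
    "simulate_gls_benchmark",
    "simulate_migration_cohort",
    "make_fixture",
]

KM_PER_DEG = 111.195

#: Default per-class lockdown multipliers on 2020 record rates.
DEFAULT_MULTIPLIERS: dict[str, float] = {
    "developed": 1.1,
    "emerging": 0.9,
    "developing": 0.6,
    "least_developed": 0.5,
}

#: Class means of the stringency index (0-100) during the lockdown window.
DEFAULT_STRINGENCY: dict[str, float] = {
    "developed": 55.0,
    "emerging": 70.0,
    "developing": 80.0,
    "least_developed": 75.0,
}

# ISO codes used by the default worlds, with plausible class labels.
_CODE_POOL: dict[str, list[str]] = {
    "developed": ["US", "CA", "GB", "DE", "SE", "FI", "NO", "DK", "NL", "AU",
                  "NZ", "JP", "FR", "AT", "CH", "BE", "IE", "IT", "ES", "PT"],
    "emerging": ["BR", "MX", "ZA", "TR", "TH", "MY", "AR", "CL", "CN", "RU",
                 "CO", "PE", "HU", "PL", "RO", "BG", "KZ", "PH", "ID", "IN"],
    "developing": ["KE", "GH", "NG", "EC", "BO", "PY", "HN", "NI", "PK", "LK",
                   "VN", "MA", "TN", "EG", "JO", "GT", "SV", "BZ", "NA", "BW"],
    "least_developed": ["UG", "TZ", "MZ", "MW", "ZM", "SN", "ML", "NE", "TD",
                        "ET", "MG", "KH", "LA", "NP", "BD", "HT", "RW", "BJ",
                        "TG", "GM"],
}


# ----------------------------------------------------------------------
# configuration
# ----------------------------------------------------------------------
@dataclass
class CountryConfig:
    code: str
    economic_class: str
    bbox: tuple[float, float, float, float]  # lon_min, lat_min, lon_max, lat_max
    baseline_rate: float       # expected window records in 2010
    growth: float = 0.15       # yearly multiplicative growth


@dataclass
class ObserverConfig:
    observers_per_country: int = 30
    daily_recording_prob: float = 0.4
    travel_prob: float = 0.15
    destination_class_weights: dict[str, float] = field(
        default_factory=lambda: {"developed": 0.20, "emerging": 0.20,
                                 "developing": 0.35, "least_developed": 0.25})
    movement_scale_km: float = 30.0
    lockdown_movement_scale_km: float = 15.0
    activity_shape: float = 0.8  # Gamma shape of per-observer weights


@dataclass
class CovariateConfig:
    stringency_by_class: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STRINGENCY))
    stringency_sd: float = 12.0
    park_change_copula_rho: float = 0.6
    park_change_sd: float = 18.0
    time_at_home_rho: float = -0.74
    time_at_home_mean: float = 12.0
    time_at_home_sd: float = 6.0
    population_log10_range: tuple[float, float] = (5.0, 8.5)
    missing_mobility_frac: float = 0.0


@dataclass
class SyntheticWorldConfig:
    countries: list[CountryConfig]
    observer: ObserverConfig = field(default_factory=ObserverConfig)
    covariate: CovariateConfig = field(default_factory=CovariateConfig)
    lockdown_multipliers: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MULTIPLIERS))
    multiplier_log_sd: float = 0.15
    borders: Literal["open", "closed"] = "closed"
    years: tuple[int, int] = (2010, 2023)
    high_seas_frac: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not self.countries:
            raise ValueError("config has zero countries")
        for c in self.countries:
            lo_lon, lo_lat, hi_lon, hi_lat = c.bbox
            if not (-180 <= lo_lon < hi_lon <= 180 and
                    -90 <= lo_lat < hi_lat <= 90):
                raise ValueError(f"invalid bbox for {c.code}: {c.bbox}")
            if c.economic_class not in ECONOMIC_CLASSES:
                raise ValueError(f"unknown economic class "
                                 f"{c.economic_class!r} for {c.code}")
            if c.baseline_rate <= 0:
                raise ValueError(f"non-positive baseline rate for {c.code}")
        probs = [self.observer.daily_recording_prob,
                 self.observer.travel_prob, self.high_seas_frac]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.borders not in ("open", "closed"):
            raise ValueError(f"unknown borders scenario {self.borders!r}")

    # -- YAML round trip ------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticWorldConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["countries"] = [
            CountryConfig(**{**c, "bbox": tuple(c["bbox"])})
            for c in raw["countries"]]
        raw["observer"] = ObserverConfig(**raw.get("observer", {}))
        cov = raw.get("covariate", {})
        if "population_log10_range" in cov:
            cov["population_log10_range"] = tuple(cov["population_log10_range"])
        raw["covariate"] = CovariateConfig(**cov)
        raw["years"] = tuple(raw.get("years", (2010, 2023)))
        return cls(**raw)


def default_world(n_countries: int = 20, seed: int = 0,
                  borders: Literal["open", "closed"] = "closed",
                  observers_per_country: int = 30,
                  baseline_range: tuple[float, float] = (80.0, 400.0),
                  ) -> SyntheticWorldConfig:
    """A ready-made world config with ``n_countries`` spread over classes."""
    rng = np.random.default_rng(seed)
    countries = []
    per_class = -(-n_countries // len(ECONOMIC_CLASSES))  # ceil
    k = 0
    for cls in ECONOMIC_CLASSES:
        for code in _CODE_POOL[cls][:per_class]:
            if k >= n_countries:
                break
            lon0 = float(rng.uniform(-170, 160))
            lat0 = float(rng.uniform(-55, 55))
            countries.append(CountryConfig(
                code=code, economic_class=cls,
                bbox=(lon0, lat0, lon0 + 8.0, lat0 + 6.0),
                baseline_rate=float(np.exp(rng.uniform(
                    np.log(baseline_range[0]), np.log(baseline_range[1])))),
            ))
            k += 1
    return SyntheticWorldConfig(
        countries=countries, borders=borders, seed=seed,
        observer=ObserverConfig(observers_per_country=observers_per_country))


# ----------------------------------------------------------------------
# covariate machinery (shared by the full world and the fast path)
# ----------------------------------------------------------------------
def _draw_multipliers(classes: np.ndarray, multipliers: Mapping[str, float],
                      log_sd: float, rng: np.random.Generator
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Per-country multiplier m_c and its standardised log deviation."""
    z = rng.standard_normal(classes.size)
    base = np.array([multipliers[c] for c in classes])
    # mean-corrected lognormal heterogeneity: E[m_c] = class multiplier
    m = base * np.exp(log_sd * z - 0.5 * log_sd ** 2)
    return m, z


def _draw_covariates(classes: np.ndarray, z_mult: np.ndarray,
                     cov: CovariateConfig, rng: np.random.Generator,
                     multipliers: Mapping[str, float]) -> pd.DataFrame:
    n = classes.size
    stringency = np.clip(
        np.array([cov.stringency_by_class[c] for c in classes])
        + rng.normal(0.0, cov.stringency_sd, n), 0.0, 100.0)
    # park change: class-level mean tied to the class multiplier, country
    # scatter tied to the realised multiplier through a Gaussian copula
    rho = cov.park_change_copula_rho
    z_park = rho * z_mult + np.sqrt(1 - rho ** 2) * rng.standard_normal(n)
    park = (100.0 * (np.array([multipliers[c] for c in classes]) - 1.0)
            + cov.park_change_sd * z_park)
    # time at home: copula-correlated with the *overall* park signal
    z_total = (park - park.mean()) / max(park.std(), 1e-12)
    rho_h = cov.time_at_home_rho
    z_home = rho_h * z_total + np.sqrt(1 - rho_h ** 2) * rng.standard_normal(n)
    home = cov.time_at_home_mean + cov.time_at_home_sd * z_home
    pop = 10.0 ** rng.uniform(*cov.population_log10_range, n)
    out = pd.DataFrame({
        "stringency_index": stringency,
        "change_park_visitors": park,
        "change_time_at_home": home,
        "population_size": pop,
        "economic_class": classes,
    })
    if cov.missing_mobility_frac > 0:
        mask = rng.random(n) < cov.missing_mobility_frac
        out.loc[mask, ["change_park_visitors", "change_time_at_home"]] = np.nan
        out.attrs["missing_mask"] = mask
    return out


# ----------------------------------------------------------------------
# full world generation
# ----------------------------------------------------------------------
@dataclass
class WorldData:
    """A generated world: occurrence table, covariates, ground truth."""

    occurrences: pd.DataFrame
    covariates: pd.DataFrame
    ledger: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.occurrences.to_csv(out / "occurrences.tsv", sep="\t",
                                index=False)
        self.covariates.to_csv(out / "covariates.csv", index=False)
        with open(out / "ledger.json", "w") as fh:
            json.dump(self.ledger, fh, indent=1, sort_keys=True)


def _walk(rng: np.random.Generator, bbox, n: int, scale_km: float
          ) -> np.ndarray:
    """Bounded random walk of n (lon, lat) positions inside bbox."""
    lo_lon, lo_lat, hi_lon, hi_lat = bbox
    lat_mid = 0.5 * (lo_lat + hi_lat)
    dlat = scale_km / KM_PER_DEG
    dlon = scale_km / (KM_PER_DEG *
                       max(np.cos(np.deg2rad(lat_mid)), 0.05))
    pos = np.empty((n, 2))
    pos[0] = (rng.uniform(lo_lon, hi_lon), rng.uniform(lo_lat, hi_lat))
    for i in range(1, n):
        step = rng.normal(0.0, (dlon, dlat))
        pos[i, 0] = _reflect(pos[i - 1, 0] + step[0], lo_lon, hi_lon)
        pos[i, 1] = _reflect(pos[i - 1, 1] + step[1], lo_lat, hi_lat)
    return pos


def _reflect(x: float, lo: float, hi: float) -> float:
    span = hi - lo
    if span <= 0:
        return lo
    t = (x - lo) % (2 * span)
    return lo + (t if t <= span else 2 * span - t)


def generate_world(config: SyntheticWorldConfig,
                   seed: int | None = None) -> WorldData:
    """Generate occurrences, covariates and the ground-truth ledger.

    The 2019 and 2020 lockdown-window records are eBird-tagged and carry
    observer ids generated from per-observer itineraries; records in the
    other years (the trend series) are plain human-observation records.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    y0, y1 = config.years
    classes = np.array([c.economic_class for c in config.countries])
    m_country, z_mult = _draw_multipliers(
        classes, config.lockdown_multipliers, config.multiplier_log_sd, rng)
    covars = _draw_covariates(classes, z_mult, config.covariate, rng,
                              config.lockdown_multipliers)
    covars.insert(0, "country_code", [c.code for c in config.countries])

    # --- observer itineraries for 2019/2020 ---------------------------
    obs_cfg = config.observer
    observers: list[dict] = []
    codes = [c.code for c in config.countries]
    by_class: dict[str, list[int]] = {cls: [] for cls in ECONOMIC_CLASSES}
    for idx, c in enumerate(config.countries):
        by_class[c.economic_class].append(idx)
    for idx, c in enumerate(config.countries):
        for j in range(obs_cfg.observers_per_country):
            oid = f"obs_{c.code}_{j:03d}"
            where = {2019: idx, 2020: idx}
            for year in (2019, 2020):
                closed = config.borders == "closed" and year == 2020
                if not closed and rng.random() < obs_cfg.travel_prob:
                    where[year] = _sample_destination(
                        rng, idx, by_class, obs_cfg.destination_class_weights)
            observers.append({
                "observer_id": oid, "home": idx,
                "present_2019": where[2019], "present_2020": where[2020],
                "weight": float(rng.gamma(obs_cfg.activity_shape, 1.0)),
            })

    present: dict[tuple[int, int], list[int]] = {}
    for k, o in enumerate(observers):
        present.setdefault((o["present_2019"], 2019), []).append(k)
        present.setdefault((o["present_2020"], 2020), []).append(k)

    # --- per-country record generation ---------------------------------
    rows: list[tuple] = []
    ledger_countries: dict[str, dict] = {}
    obs_records: dict[str, dict[int, dict[str, int]]] = {
        o["observer_id"]: {2019: {}, 2020: {}} for o in observers}
    rid = 0
    for idx, c in enumerate(config.countries):
        lam_years = {}
        for year in range(y0, y1 + 1):
            lam = c.baseline_rate * (1.0 + c.growth) ** (year - y0)
            if year == 2020:
                lam *= m_country[idx]
            lam_years[year] = lam
            n = int(rng.poisson(lam))
            window = PeriodWindow(year=year)
            days = window.n_days
            if year in (2019, 2020):
                who = present.get((idx, year), [])
                if who:
                    w = np.array([observers[k]["weight"] for k in who])
                    alloc = rng.multinomial(n, w / w.sum())
                else:  # no observers present: anonymous records
                    alloc = np.array([], dtype=int)
                    who = []
                used = int(alloc.sum()) if len(who) else 0
                for k, cnt in zip(who, alloc):
                    if cnt == 0:
                        continue
                    o = observers[k]
                    day_idx = np.sort(rng.integers(0, days, cnt))
                    pos = _walk(rng, c.bbox, cnt,
                                obs_cfg.lockdown_movement_scale_km
                                if year == 2020
                                else obs_cfg.movement_scale_km)
                    for d, (lon, lat) in zip(day_idx, pos):
                        date = window.start_date + dt.timedelta(int(d))
                        rows.append((f"r{rid}", c.code, date.isoformat(),
                                     f"{lat:.5f}", f"{lon:.5f}",
                                     "HUMAN_OBSERVATION", "ebird",
                                     o["observer_id"]))
                        rid += 1
                    obs_records[o["observer_id"]][year][c.code] = int(cnt)
                n_left = n - used
            else:
                n_left = n
            if n_left > 0:
                day_idx = rng.integers(0, days, n_left)
                lons = rng.uniform(c.bbox[0], c.bbox[2], n_left)
                lats = rng.uniform(c.bbox[1], c.bbox[3], n_left)
                for d, lon, lat in zip(day_idx, lons, lats):
                    date = window.start_date + dt.timedelta(int(d))
                    rows.append((f"r{rid}", c.code, date.isoformat(),
                                 f"{lat:.5f}", f"{lon:.5f}",
                                 "HUMAN_OBSERVATION", "other", ""))
                    rid += 1
        ledger_countries[c.code] = {
            "economic_class": c.economic_class,
            "baseline_rate": c.baseline_rate,
            "growth": c.growth,
            "lockdown_multiplier": float(m_country[idx]),
            "lambda_by_year": {str(y): float(v)
                               for y, v in lam_years.items()},
        }

    n_land = len(rows)
    n_zz = round(n_land * config.high_seas_frac / (1.0 - config.high_seas_frac)) \
        if config.high_seas_frac > 0 else 0
    for _ in range(n_zz):
        date = PeriodWindow(year=2019).start_date + dt.timedelta(
            int(rng.integers(0, 48)))
        rows.append((f"r{rid}", "ZZ", date.isoformat(),
                     f"{float(rng.uniform(-40, 40)):.5f}",
                     f"{float(rng.uniform(-170, 170)):.5f}",
                     "HUMAN_OBSERVATION", "other", ""))
        rid += 1

    occurrences = pd.DataFrame(rows, columns=[
        "id", "countryCode", "eventDate", "decimalLatitude",
        "decimalLongitude", "basisOfRecord", "datasetTag", "observerId"])

    ledger_observers = {}
    for o in observers:
        rec = obs_records[o["observer_id"]]
        countries_2020 = sorted(k for k, v in rec[2020].items() if v > 0)
        ledger_observers[o["observer_id"]] = {
            "home": codes[o["home"]],
            "present_2019": codes[o["present_2019"]],
            "present_2020": codes[o["present_2020"]],
            "records_2019": rec[2019],
            "records_2020": rec[2020],
            "countries_2020": countries_2020,
        }
    ledger = {
        "seed": int(config.seed if seed is None else seed),
        "borders": config.borders,
        "n_records_land": n_land,
        "n_records_high_seas": n_zz,
        "high_seas_frac": config.high_seas_frac,
        "countries": ledger_countries,
        "observers": ledger_observers,
    }
    return WorldData(occurrences=occurrences, covariates=covars,
                     ledger=ledger)


def _sample_destination(rng, home_idx, by_class, weights) -> int:
    probs, pool = [], []
    for cls, idxs in by_class.items():
        cand = [i for i in idxs if i != home_idx]
        if not cand:
            continue
        w = weights.get(cls, 0.0) / len(cand)
        pool.extend(cand)
        probs.extend([w] * len(cand))
    if not pool:
        return home_idx
    probs = np.asarray(probs)
    return int(rng.choice(pool, p=probs / probs.sum()))


# ----------------------------------------------------------------------
# fast count-level path for replicate studies
# ----------------------------------------------------------------------
DEFAULT_CLASS_COUNTS_129: dict[str, int] = {
    "developed": 36, "emerging": 30, "developing": 43, "least_developed": 20}


def simulate_change_frame(
    rng: np.random.Generator,
    class_counts: Mapping[str, int] | None = None,
    lam_range: tuple[float, float] = (200.0, 5000.0),
    growth: float = 0.15,
    multipliers: Mapping[str, float] | None = None,
    multiplier_log_sd: float = 0.15,
    covariate: CovariateConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Draw a regression-ready frame at the count level (no records).

    Per country: a 2019 window rate log-uniform in ``lam_range``,
    ``n_t0 ~ Poisson(rate)``, ``n_t1 ~ Poisson(rate * (1+g) * m_c)``, plus
    covariates from the shared copula machinery.  Defaults mirror the
    129-country study frame.  Returns ``(frame, truth)`` where the frame has
    the columns :func:`anthropause.covariates.assemble_frame` produces.
    """
    from .change_metrics import change_table
    from .covariates import assemble_frame

    class_counts = dict(class_counts or DEFAULT_CLASS_COUNTS_129)
    multipliers = dict(multipliers or DEFAULT_MULTIPLIERS)
    covariate = covariate or CovariateConfig()
    codes, classes = [], []
    for cls, n in class_counts.items():
        pool = _CODE_POOL[cls]
        for i in range(n):
            codes.append(pool[i % len(pool)] + (str(i // len(pool))
                                                if i >= len(pool) else ""))
            classes.append(cls)
    classes = np.asarray(classes)
    n = len(codes)
    m, z = _draw_multipliers(classes, multipliers, multiplier_log_sd, rng)
    lam = np.exp(rng.uniform(np.log(lam_range[0]), np.log(lam_range[1]), n))
    n_t0 = rng.poisson(lam)
    n_t1 = rng.poisson(lam * (1.0 + growth) * m)
    covars = _draw_covariates(classes, z, covariate, rng, multipliers)
    covars.insert(0, "country_code", codes)
    changes = change_table(pd.Series(n_t0, index=codes),
                           pd.Series(n_t1, index=codes))
    frame = assemble_frame(changes, covars)
    truth = {
        "multipliers": {c: float(v) for c, v in zip(codes, m)},
        "class_multipliers": multipliers,
        "growth": growth,
        "n_countries": n,
        "n_missing_mobility": int(
            covars["change_park_visitors"].isna().sum()),
        "expected_change_pct": {
            c: float(((1.0 + growth) * mi - 1.0) * 100.0)
            for c, mi in zip(codes, m)},
    }
    return frame, truth


def simulate_trend_series(
    rng: np.random.Generator,
    lam0: float = 500.0,
    growth: float = 0.15,
    years: Sequence[int] = tuple(range(2010, 2024)),
    shock_sd: float = 0.0,
    shock_year: int = 2020,
) -> tuple[np.ndarray, np.ndarray]:
    """One country's yearly window counts: Poisson around exponential growth.

    ``shock_sd`` subtracts that many focal-year residual standard
    deviations (sqrt of the Poisson mean) from the focal-year count,
    emulating a lockdown collapse in data collection.
    """
    years = np.asarray(years)
    mu = lam0 * (1.0 + growth) ** (years - years[0])
    counts = rng.poisson(mu).astype(float)
    if shock_sd:
        i = int(np.flatnonzero(years == shock_year)[0])
        counts[i] = max(0.0, counts[i] - shock_sd * np.sqrt(mu[i]))
    return years, counts


def simulate_gls_benchmark(
    rng: np.random.Generator,
    multipliers: Sequence[float] = (1.0, 2.0, 4.0, 8.0),
    n_per_group: int = 500,
    sigma: float = 1.0,
    beta: Sequence[float] | None = None,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, np.ndarray]:
    """A linear-model benchmark with known per-group variance multipliers.

    Design: intercept, two standard-normal covariates, and group dummies
    (reference group first).  Returns ``(X, y, groups, beta_true)`` with X
    a named DataFrame including the intercept column.
    """
    G = len(multipliers)
    if beta is None:
        beta = np.concatenate([[1.0, 0.5, -0.5], np.linspace(0.3, -0.3, G - 1)])
    beta = np.asarray(beta, dtype=float)
    n = G * n_per_group
    groups = np.repeat(np.arange(G), n_per_group)
    X = np.column_stack([
        np.ones(n),
        rng.standard_normal(n),
        rng.standard_normal(n),
        *[(groups == g).astype(float) for g in range(1, G)],
    ])
    names = (["intercept", "x1", "x2"] +
             [f"group[{g}]" for g in range(1, G)])
    eps = rng.standard_normal(n) * sigma * np.asarray(multipliers)[groups]
    y = X @ beta + eps
    return pd.DataFrame(X, columns=names), y, groups, beta


# ----------------------------------------------------------------------
# migration cohorts
# ----------------------------------------------------------------------
def simulate_migration_cohort(
    rng: np.random.Generator,
    n_observers: int = 1000,
    p_active: float = 0.75,
    p_travel: float = 0.3,
    p_also_home: float = 0.3,
    borders: Literal["open", "closed"] = "open",
) -> tuple[dict[str, list[OccurrenceRecord]], pd.DataFrame]:
    """Observers with known lockdown whereabouts, for the migration test.

    Each observer has an origin country (where they were selected).  In the
    lockdown window they are active with probability ``p_active``; active
    observers travel with probability ``p_travel`` (0 under closed borders)
    and record in the destination — also in the origin with probability
    ``p_also_home`` (those are 'returned' by precedence).  Returns
    ``(records_by_observer, truth)``; truth has columns ``observer_id,
    origin, status, countries``.
    """
    pool = [(code, cls) for cls in ECONOMIC_CLASSES
            for code in _CODE_POOL[cls][:5]]
    window = PeriodWindow(year=2020)
    records: dict[str, list[OccurrenceRecord]] = {}
    truth_rows = []
    rid = 0
    for i in range(n_observers):
        oid = f"mig_{i:05d}"
        origin, _ = pool[int(rng.integers(len(pool)))]
        recs: list[OccurrenceRecord] = []
        countries: list[str] = []
        if rng.random() < p_active:
            travels = (borders == "open") and (rng.random() < p_travel)
            if travels:
                dest = origin
                while dest == origin:
                    dest, _ = pool[int(rng.integers(len(pool)))]
                countries.append(dest)
                if rng.random() < p_also_home:
                    countries.append(origin)
            else:
                countries.append(origin)
        for code in countries:
            for _ in range(int(rng.integers(1, 4))):
                date = window.start_date + dt.timedelta(
                    int(rng.integers(0, window.n_days)))
                recs.append(OccurrenceRecord(
                    record_id=f"m{rid}", country_code=code, event_date=date,
                    lat=0.0, lon=0.0, basis="human_observation",
                    dataset_tag="ebird", observer_id=oid))
                rid += 1
        if not countries:
            status = "inactive"
        elif origin in countries:
            status = "returned"
        else:
            status = "migrated"
        records[oid] = recs
        truth_rows.append((oid, origin, status,
                           sorted(set(countries))))
    truth = pd.DataFrame(truth_rows,
                         columns=["observer_id", "origin", "status",
                                  "countries"])
    return records, truth


# ----------------------------------------------------------------------
# canned fixtures
# ----------------------------------------------------------------------
def make_fixture(name: str) -> dict:
    """Deterministic tiny datasets for unit tests and documentation.

    ``"minimal"``      three countries with window counts (100 -> 150),
                       (100 -> 100), (100 -> 50): changes +50 / 0 / -50.
    ``"tie-break"``    two observers with equal active days but unequal
                       record counts (A wins the tie).
    ``"antimeridian"`` an observer straddling +/-180 deg with a known
                       0.4 x 0.4 deg equatorial hull.
    """
    if name == "minimal":
        rows = []
        rid = 0
        for code, (t0, t1) in {"US": (100, 150), "DE": (100, 100),
                               "KE": (100, 50)}.items():
            for year, cnt in ((2019, t0), (2020, t1)):
                window = PeriodWindow(year=year)
                for i in range(cnt):
                    date = window.start_date + dt.timedelta(i % window.n_days)
                    rows.append((f"f{rid}", code, date.isoformat(), "1.0",
                                 "1.0", "HUMAN_OBSERVATION", "ebird",
                                 f"obs_{code}_0"))
                    rid += 1
        occ = pd.DataFrame(rows, columns=[
            "id", "countryCode", "eventDate", "decimalLatitude",
            "decimalLongitude", "basisOfRecord", "datasetTag", "observerId"])
        return {"occurrences": occ,
                "expected_change_pct": {"US": 50.0, "DE": 0.0, "KE": -50.0}}
    if name == "tie-break":
        window = PeriodWindow(year=2019)
        recs = []
        rid = 0
        # A: 5 days, 10 records; C: 5 days, 5 records; B: 3 days, 9 records
        sched = {"A": [(d, 2) for d in range(5)],
                 "C": [(d, 1) for d in range(5)],
                 "B": [(d, 3) for d in range(3)]}
        for oid, days in sched.items():
            for d, k in days:
                for _ in range(k):
                    recs.append(OccurrenceRecord(
                        record_id=f"t{rid}", country_code="US",
                        event_date=window.start_date + dt.timedelta(d),
                        lat=40.0, lon=-100.0, basis="human_observation",
                        dataset_tag="ebird", observer_id=oid))
                    rid += 1
        return {"records": recs, "window": window,
                "expected_ranking": ["A", "C", "B"]}
    if name == "antimeridian":
        pts = [(179.8, 0.0), (-179.8, 0.0), (179.8, 0.4), (-179.8, 0.4)]
        # planar oracle after unwrapping: 0.4 x 0.4 deg at the equator
        return {"points": pts,
                "oracle_area_km2": 0.4 * 0.4 * KM_PER_DEG ** 2}
    raise KeyError(f"unknown fixture {name!r}; choose among "
                   "'minimal', 'tie-break', 'antimeridian'")
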