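"""Synthetic multi-city cohorts with a known heat-mortality truth.

The generator emulates the structure the three-stage analysis assumes:
~100 European cities in four regions, daily mean temperature with a seasonal
cycle, AR(1) noise and multi-day heatwave excursions, and overdispersed
daily death counts whose log-mean carries a lagged nonlinear heat effect.
The true exposure-response is piecewise linear in the location's warm-season
temperature *percentile* — zero at and below the minimum-mortality
percentile, rising linearly so that the log relative risk at the 99th
percentile equals the region's (possibly time-trending) heat slope.  A
country's heat prevention plan (HPP) multiplies the slope by ``hpp_effect``
from January 1 of its implementation year.  Every draw is reproducible
under a fixed seed, and the known truth supports exact attribution oracles
for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import (
    REGIONS,
    SEASON_MONTHS,
    LocationSeries,
    Subperiod,
    enumerate_subperiods,
    season_mask,
)
from .hpp import catalogue_to_frame, hpp_indicator, HPPRecord
from .splines import EmpiricalPercentiles

# reference percentile for quoting heat slopes: the true log-RR at the 99th
# warm-season percentile equals the region's slope parameter
SLOPE_REF_PCT = 99.0


def _default_lag_weights(max_lag: int = 10, decay: float = 0.6) -> tuple[float, ...]:
    w = np.exp(-decay * np.arange(max_lag + 1))
    return tuple(w / w.sum())


@dataclass
class TruthParams:
    """Ground-truth data-generating parameters.

    Defaults describe the full study configuration: 102 cities in 14
    countries across four European regions, daily series 1990-2019, a
    baseline of 20 expected deaths/day, quasi-Poisson overdispersion 1.3,
    MMT at the 75th warm-season percentile, region-specific heat slopes
    (log-RR at the 99th percentile) with a mild declining decadal trend,
    geometric-decay lag weights over 0..10 days, and a 30% slope reduction
    (hpp_effect 0.7) from each country's HPP implementation year onward.
    """

    n_cities: int = 102
    n_countries: int = 14
    regions: tuple[str, ...] = REGIONS
    years: tuple[int, int] = (1990, 2019)
    baseline_rate: float = 20.0
    overdispersion: float = 1.3
    mmt_pct: float = 75.0
    heat_slope: dict[str, float] = field(
        default_factory=lambda: {"Northern": 0.25, "Eastern": 0.40, "Western": 0.30, "Southern": 0.35}
    )
    heat_trend: dict[str, float] = field(
        default_factory=lambda: {r: -0.03 for r in REGIONS}
    )  # change in slope per decade
    lag_weights: tuple[float, ...] = field(default_factory=_default_lag_weights)
    hpp_year: dict[str, int] | None = None  # country -> year; None = staggered defaults
    hpp_effect: float = 0.7
    season_amp: float = 0.15
    dow_effects: tuple[float, ...] = (1.00, 0.98, 0.97, 0.97, 0.98, 1.01, 1.02)
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.lag_weights, float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("TruthParams: lag_weights must be nonnegative and sum to 1")
        if not 0.0 < self.hpp_effect <= 1.0:
            raise ValueError("TruthParams: hpp_effect must be in (0, 1]")
        if self.overdispersion < 1.0:
            raise ValueError("TruthParams: overdispersion must be >= 1")
        if not 0.0 < self.mmt_pct < 100.0:
            raise ValueError("TruthParams: mmt_pct must be in (0, 100)")
        if self.baseline_rate <= 0:
            raise ValueError("TruthParams: baseline_rate must be > 0")
        if self.years[1] < self.years[0]:
            raise ValueError("TruthParams: invalid year range")
        if self.n_countries > self.n_cities:
            raise ValueError("TruthParams: more countries than cities")
        if len(self.dow_effects) != 7:
            raise ValueError("TruthParams: dow_effects must have 7 entries")
        for r in self.regions:
            if r not in self.heat_slope or r not in self.heat_trend:
                raise ValueError(f"TruthParams: missing heat_slope/heat_trend for region {r!r}")

    @property
    def max_lag(self) -> int:
        return len(self.lag_weights) - 1

    @property
    def ref_year(self) -> float:
        """Calendar-time reference for the slope trend (mid study period)."""
        return 0.5 * (self.years[0] + self.years[1])

    def countries(self) -> list[str]:
        return [f"C{i + 1:02d}" for i in range(self.n_countries)]

    def country_region(self) -> dict[str, str]:
        return {c: self.regions[i % len(self.regions)] for i, c in enumerate(self.countries())}

    def country_hpp_year(self) -> dict[str, int]:
        if self.hpp_year is not None:
            return dict(self.hpp_year)
        # staggered implementations across the later study period (most
        # European plans followed the 2003 heatwave)
        y0, y1 = self.years
        lo = max(y0 + 6, min(1999, y1 - 3))
        hi = min(y1 - 3, 2013)
        if hi < lo:
            hi = lo
        yrs = np.round(np.linspace(lo, hi, self.n_countries)).astype(int)
        return dict(zip(self.countries(), yrs.tolist()))

    def slope_at(self, region: str, year_frac: np.ndarray) -> np.ndarray:
        """Heat slope for a region at (fractional) calendar time, floored at 0."""
        s = self.heat_slope[region] + self.heat_trend[region] * (np.asarray(year_frac) - self.ref_year) / 10.0
        return np.maximum(s, 0.0)


@dataclass(frozen=True)
class CityClimate:
    mean: float
    amplitude: float
    noise_sd: float = 2.5
    noise_ar: float = 0.7
    heatwave_rate: float = 1.5   # expected episodes per warm season
    heatwave_amp: float = 5.0    # peak excursion, degrees C
    heatwave_days: tuple[int, int] = (3, 6)

    def __post_init__(self) -> None:
        for name in ("mean", "amplitude", "noise_sd", "heatwave_amp"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"CityClimate: {name} must be finite")
        if not 0.0 <= self.noise_ar < 1.0:
            raise ValueError("CityClimate: noise_ar must be in [0, 1)")
        if self.heatwave_rate < 0:
            raise ValueError("CityClimate: heatwave_rate must be >= 0")


#: per-region climate archetypes (mean degrees C, seasonal amplitude)
REGION_CLIMATE = {
    "Northern": (8.0, 9.0),
    "Eastern": (11.0, 10.0),
    "Western": (12.0, 7.0),
    "Southern": (17.0, 8.0),
}


# ---------------------------------------------------------------------------
# temperature
# ---------------------------------------------------------------------------

def _heatwave_episodes(
    rng: np.random.Generator,
    dates: pd.DatetimeIndex,
    climate: CityClimate,
) -> list[tuple[int, int, float]]:
    """Draw (start index, duration, peak amplitude) heatwave excursions.

    Episode counts are Poisson per warm season with the climate's rate;
    episodes start uniformly within May-September.
    """
    episodes = []
    in_season = np.flatnonzero(season_mask(dates))
    if in_season.size == 0 or climate.heatwave_rate == 0:
        return episodes
    years = dates.year.to_numpy()
    for yr in np.unique(years[in_season]):
        idx = in_season[years[in_season] == yr]
        n_ep = rng.poisson(climate.heatwave_rate)
        for _ in range(n_ep):
            start = int(rng.choice(idx))
            dur = int(rng.integers(climate.heatwave_days[0], climate.heatwave_days[1] + 1))
            amp = climate.heatwave_amp * (0.7 + 0.6 * rng.random())
            episodes.append((start, dur, amp))
    return episodes


def simulate_temperature(
    climate: CityClimate,
    years: tuple[int, int],
    rng: np.random.Generator | int,
) -> tuple[pd.DatetimeIndex, np.ndarray]:
    """Daily mean temperature: seasonal cycle + AR(1) noise + heatwaves."""
    if years[1] < years[0]:
        raise ValueError("simulate_temperature: invalid year range 'years'")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    dates = pd.date_range(f"{years[0]}-01-01", f"{years[1]}-12-31", freq="D")
    doy = dates.dayofyear.to_numpy()
    # seasonal peak in mid-July (day ~197)
    seasonal = climate.mean + climate.amplitude * np.cos(2 * np.pi * (doy - 197) / 365.25)
    n = len(dates)
    eps = rng.normal(0.0, climate.noise_sd * np.sqrt(1 - climate.noise_ar**2), n)
    noise = np.empty(n)
    acc = rng.normal(0.0, climate.noise_sd)
    for t in range(n):
        acc = climate.noise_ar * acc + eps[t]
        noise[t] = acc
    tmean = seasonal + noise
    for start, dur, amp in _heatwave_episodes(rng, dates, climate):
        end = min(start + dur, n)
        shape = np.sin(np.pi * (np.arange(end - start) + 0.5) / dur)  # half-sine bump
        tmean[start:end] += amp * shape
    return dates, tmean


# ---------------------------------------------------------------------------
# mortality
# ---------------------------------------------------------------------------

def true_log_rr_percentile(truth: TruthParams, percentile: np.ndarray) -> np.ndarray:
    """Unit-slope true curve: 0 at/below the MMT percentile, 1 at the 99th."""
    p = np.asarray(percentile, float)
    return np.maximum(p - truth.mmt_pct, 0.0) / (SLOPE_REF_PCT - truth.mmt_pct)


def _seasonal_baseline(truth: TruthParams, dates: pd.DatetimeIndex) -> np.ndarray:
    """Winter-peaking seasonal multiplier, normalised to mean 1 over May-Sep."""
    doy = dates.dayofyear.to_numpy()
    seas = np.exp(truth.season_amp * np.cos(2 * np.pi * (doy - 15) / 365.25))
    seas /= seas[season_mask(dates)].mean()
    return seas


def hpp_factor(
    truth: TruthParams, dates: pd.DatetimeIndex, country: str
) -> np.ndarray:
    """Daily multiplicative slope factor: hpp_effect from Jan 1 of the
    country's implementation year onward, 1 before."""
    year = truth.country_hpp_year().get(country)
    factor = np.ones(len(dates))
    if year is not None:
        factor[dates.year.to_numpy() >= year] = truth.hpp_effect
    return factor


def true_daily_log_rr(
    truth: TruthParams,
    dates: pd.DatetimeIndex,
    tmean: np.ndarray,
    region: str,
    country: str,
    counterfactual: bool = False,
) -> np.ndarray:
    """Lag-cumulated true log relative risk vs MMT for every day.

    Uses the day-t slope (trend and HPP factor evaluated at the outcome
    day) applied to the lag-weighted unit curve; the first max_lag days use
    the partial lag window (they are burn-in for any likelihood).
    """
    perc = EmpiricalPercentiles(tmean[season_mask(dates)]).to_percentile(tmean)
    s = true_log_rr_percentile(truth, perc)
    w = np.asarray(truth.lag_weights)
    n = len(s)
    lagsum = np.zeros(n)
    for lag, wl in enumerate(w):
        if wl == 0:
            continue
        lagsum[lag:] += wl * s[: n - lag]
        lagsum[:lag] += wl * s[0]  # burn-in: hold the first value
    yf = dates.year.to_numpy() + (dates.dayofyear.to_numpy() - 1) / 365.25
    slope = truth.slope_at(region, yf)
    factor = np.ones(n) if counterfactual else hpp_factor(truth, dates, country)
    return slope * factor * lagsum


def simulate_mortality(
    dates: pd.DatetimeIndex,
    tmean: np.ndarray,
    truth: TruthParams,
    region: str,
    country: str,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Overdispersed daily death counts under the true lagged heat model.

    Counts are gamma-Poisson (NB2) with Var = psi * mean, the standard
    generative stand-in for quasi-Poisson overdispersion.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    psi = truth.overdispersion
    if psi < 1.0:
        raise ValueError("simulate_mortality: overdispersion must be >= 1")
    seas = _seasonal_baseline(truth, dates)
    dow = np.asarray(truth.dow_effects)[dates.dayofweek.to_numpy()]
    log_rr = true_daily_log_rr(truth, dates, tmean, region, country)
    mu = truth.baseline_rate * seas * dow * np.exp(log_rr)
    if psi == 1.0:
        return rng.poisson(mu).astype(np.int64)
    lam = rng.gamma(shape=mu / (psi - 1.0), scale=psi - 1.0)
    return rng.poisson(lam).astype(np.int64)


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    cities: list[LocationSeries]
    catalogue: pd.DataFrame
    truth: TruthParams

    def city_region(self) -> dict[str, str]:
        return {c.city_id: c.region for c in self.cities}

    def city_country(self) -> dict[str, str]:
        return {c.city_id: c.country for c in self.cities}


def _synthetic_catalogue(truth: TruthParams, rng: np.random.Generator) -> pd.DataFrame:
    """Random action catalogue; classes by terciles of the maximum score."""
    hpp_years = truth.country_hpp_year()
    records = []
    for country in truth.countries():
        actions = {}
        for element in range(1, 9):
            n_act = int(rng.integers(0, 4))
            if n_act:
                actions[element] = list(rng.choice([0.5, 1.0, 1.5, 2.0], size=n_act))
        records.append(HPPRecord(country=country, implementation_year=hpp_years.get(country), actions=actions))
    max_score = max(max(r.total_score for r in records), 1.0)
    return catalogue_to_frame(records, max_score=max_score)


def build_cohort(truth: TruthParams) -> Cohort:
    """Generate the full cohort: per-city series, HPP catalogue, truth."""
    master = np.random.SeedSequence(truth.seed)
    cat_rng = np.random.default_rng(master.spawn(1)[0])
    catalogue = _synthetic_catalogue(truth, cat_rng)

    countries = truth.countries()
    country_region = truth.country_region()
    cities = []
    child_seeds = master.spawn(truth.n_cities)
    for i in range(truth.n_cities):
        country = countries[i % truth.n_countries]
        region = country_region[country]
        rng = np.random.default_rng(child_seeds[i])
        base_mean, base_amp = REGION_CLIMATE[region]
        climate = CityClimate(
            mean=base_mean + rng.normal(0.0, 1.0),
            amplitude=base_amp * (1.0 + rng.normal(0.0, 0.05)),
        )
        dates, tmean = simulate_temperature(climate, truth.years, rng)
        deaths = simulate_mortality(dates, tmean, truth, region, country, rng)
        population = int(np.round(rng.lognormal(mean=12.5, sigma=0.6)))
        cities.append(
            LocationSeries(
                city_id=f"city_{i + 1:03d}",
                country=country,
                region=region,
                dates=dates,
                tmean=tmean,
                deaths=deaths,
                population=population,
            )
        )
    return Cohort(cities=cities, catalogue=catalogue, truth=truth)


# ---------------------------------------------------------------------------
# ground-truth attribution oracle
# ---------------------------------------------------------------------------

def true_attribution(
    truth: TruthParams,
    cohort: Cohort,
    block_years: int = 3,
    threshold_pct: float = 95.0,
    indicator_rule: str = "start_year",
) -> dict:
    """Exact HAF/HAD under the known truth, factual vs counterfactual.

    Because the lag weights sum to one, the true overall cumulative log-RR
    at temperature percentile p is just slope * s(p); daily attributable
    fractions (RR-1)/RR are computed on days above the warm-season
    ``threshold_pct`` percentile and pooled over post-implementation
    subperiods exactly as the estimation pipeline does.
    """
    if cohort.truth is not truth and cohort.truth != truth:
        raise ValueError("true_attribution: truth does not match the cohort's generator")
    hpp_years = truth.country_hpp_year()
    tot = {"an_f": 0.0, "an_cf": 0.0, "deaths": 0.0, "person_years": 0.0}
    per_city = {}
    for city in cohort.cities:
        sps = enumerate_subperiods(city.dates[0].year, city.dates[-1].year, block_years)
        in_season = season_mask(city.dates)
        perc = EmpiricalPercentiles(city.tmean[in_season]).to_percentile(city.tmean)
        thr = threshold_pct
        years = city.dates.year.to_numpy()
        yf = years + (city.dates.dayofyear.to_numpy() - 1) / 365.25
        slope = truth.slope_at(city.region, yf)
        factor = hpp_factor(truth, city.dates, city.country)
        s = true_log_rr_percentile(truth, perc)
        rr_f = np.exp(slope * factor * s)
        rr_cf = np.exp(slope * s)
        city_tot = {"an_f": 0.0, "an_cf": 0.0, "deaths": 0.0, "person_years": 0.0}
        for sp in sps:
            if not hpp_indicator(hpp_years.get(city.country), sp.start_year, sp.end_year, indicator_rule):
                continue
            in_sp = in_season & (years >= sp.start_year) & (years <= sp.end_year)
            if not in_sp.any():
                continue
            hot = in_sp & (perc > thr)
            d = city.deaths[hot].astype(float)
            city_tot["an_f"] += float(np.sum(d * (rr_f[hot] - 1.0) / rr_f[hot]))
            city_tot["an_cf"] += float(np.sum(d * (rr_cf[hot] - 1.0) / rr_cf[hot]))
            city_tot["deaths"] += float(city.deaths[in_sp].sum())
            city_tot["person_years"] += city.population * len(np.unique(years[in_sp]))
        for k in tot:
            tot[k] += city_tot[k]
        per_city[city.city_id] = city_tot

    def summarise(t: dict) -> dict:
        haf_f = 100.0 * t["an_f"] / t["deaths"] if t["deaths"] else np.nan
        haf_cf = 100.0 * t["an_cf"] / t["deaths"] if t["deaths"] else np.nan
        had_f = 1e5 * t["an_f"] / t["person_years"] if t["person_years"] else np.nan
        had_cf = 1e5 * t["an_cf"] / t["person_years"] if t["person_years"] else np.nan
        change = 100.0 * (haf_f - haf_cf) / haf_cf if haf_cf else np.nan
        return {
            "haf_factual": haf_f,
            "haf_counterfactual": haf_cf,
            "haf_change": change,
            "had_factual": had_f,
            "had_counterfactual": had_cf,
            "had_difference": had_f - had_cf,
            "deaths_avoided": t["an_cf"] - t["an_f"],
        }

    out = summarise(tot)
    out["per_city"] = {cid: summarise(t) for cid, t in per_city.items()}
    return out
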