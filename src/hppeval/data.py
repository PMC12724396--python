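"""Core data containers: location series, subperiods, cohort I/O."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

REGIONS = ("Northern", "Eastern", "Western", "Southern")

#: warm-season months (May-September), the window in which heat prevention
#: plans are active and the analysis is run
SEASON_MONTHS = (5, 6, 7, 8, 9)

#: first year of the subperiod grid; 3-year blocks are aligned to this
#: anchor regardless of when an individual city's series starts
SUBPERIOD_ANCHOR = 1990


@dataclass
class LocationSeries:
    """One city's daily all-cause mortality and mean temperature."""

    city_id: str
    country: str
    region: str
    dates: pd.DatetimeIndex
    tmean: np.ndarray
    deaths: np.ndarray
    population: int

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"LocationSeries: region {self.region!r} not one of {REGIONS}")
        self.dates = pd.DatetimeIndex(self.dates)
        self.tmean = np.asarray(self.tmean, float)
        self.deaths = np.asarray(self.deaths)
        n = len(self.dates)
        if self.tmean.shape != (n,) or self.deaths.shape != (n,):
            raise ValueError("LocationSeries: dates/tmean/deaths lengths differ")
        diffs = np.diff(self.dates.to_numpy())
        if n > 1 and not (diffs == np.timedelta64(1, "D")).all():
            raise ValueError("LocationSeries: dates must be strictly increasing at daily resolution")
        if not np.all(np.isfinite(self.tmean)):
            raise ValueError("LocationSeries: tmean must be finite")
        if np.any(self.deaths < 0) or not np.issubdtype(self.deaths.dtype, np.integer):
            raise ValueError("LocationSeries: deaths must be nonnegative integers")
        if self.population <= 0:
            raise ValueError("LocationSeries: population must be positive")

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"date": self.dates, "tmean": self.tmean, "deaths": self.deaths})


@dataclass(frozen=True)
class Subperiod:
    """A 3-year block of the analysis grid (e.g. 1990-1992)."""

    index: int
    start_year: int
    end_year: int

    @property
    def mid_time(self) -> float:
        """Numeric time for the middle of the subperiod (stage-2 Time)."""
        return 0.5 * (self.start_year + self.end_year)

    @property
    def label(self) -> str:
        return f"{self.start_year}-{self.end_year}"


def enumerate_subperiods(
    first_year: int,
    last_year: int,
    block_years: int = 3,
    anchor: int = SUBPERIOD_ANCHOR,
) -> list[Subperiod]:
    """All anchor-aligned blocks overlapping [first_year, last_year]."""
    if last_year < first_year:
        raise ValueError("enumerate_subperiods: empty year range")
    k0 = (first_year - anchor) // block_years
    k1 = (last_year - anchor) // block_years
    out = []
    for k in range(k0, k1 + 1):
        start = anchor + k * block_years
        out.append(Subperiod(index=k, start_year=start, end_year=start + block_years - 1))
    return out


def season_mask(dates: pd.DatetimeIndex, months: tuple[int, ...] = SEASON_MONTHS) -> np.ndarray:
    return np.isin(np.asarray(dates.month), months)


# ---------------------------------------------------------------------------
# cohort I/O: one CSV per city + metadata CSV
# ---------------------------------------------------------------------------

def write_cohort(cities: list[LocationSeries], outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = []
    for city in sorted(cities, key=lambda c: c.city_id):
        df = city.frame()
        df["date"] = df["date"].dt.strftime("%Y-%m-%d")
        df.to_csv(outdir / f"{city.city_id}.csv", index=False, float_format="%.4f")
        meta.append(
            {
                "city_id": city.city_id,
                "country": city.country,
                "region": city.region,
                "population": city.population,
                "series_start": city.dates[0].strftime("%Y-%m-%d"),
                "series_end": city.dates[-1].strftime("%Y-%m-%d"),
            }
        )
    pd.DataFrame(meta).to_csv(outdir / "metadata.csv", index=False)


def read_cohort(indir: str | Path) -> list[LocationSeries]:
    indir = Path(indir)
    meta = pd.read_csv(indir / "metadata.csv")
    cities = []
    for _, row in meta.iterrows():
        df = pd.read_csv(indir / f"{row['city_id']}.csv", parse_dates=["date"])
        cities.append(
            LocationSeries(
                city_id=row["city_id"],
                country=row["country"],
                region=row["region"],
                dates=pd.DatetimeIndex(df["date"]),
                tmean=df["tmean"].to_numpy(float),
                deaths=df["deaths"].to_numpy(np.int64),
                population=int(row["population"]),
            )
        )
    return cities
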