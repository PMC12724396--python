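"""Stage 1: location x subperiod quasi-Poisson DLNM fits.

Each city's warm-season (May-September) daily series is split into 3-year
subperiods aligned to the 1990 grid.  Within each subperiod a quasi-Poisson
regression of daily deaths controls for seasonality (natural cubic spline
with 4 df for day of season, interacted with a year indicator) and the
weekly cycle (day-of-week dummies), with the temperature cross-basis
carrying the lagged nonlinear heat effect.  The fitted cross-basis is
reduced to the overall cumulative exposure-response curve, recentered at
the fit's own minimum-mortality temperature.

Exposure enters the cross-basis on the location's full-period warm-season
percentile scale (spline knots at the 50th and 90th percentile), so the
reduced coefficient vectors of all cities live on one common basis and can
be pooled directly in stage 2.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data import SEASON_MONTHS, LocationSeries, Subperiod, enumerate_subperiods, season_mask
from .splines import (
    EmpiricalPercentiles,
    LagBasisSpec,
    ReducedCurve,
    VarBasisSpec,
    cross_basis,
    default_lag_spec,
    find_mmt,
    natural_spline_basis,
    reduce_to_overall,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Stage1Config:
    block_years: int = 3
    season_months: tuple[int, ...] = SEASON_MONTHS
    knot_percentiles: tuple[float, float] = (50.0, 90.0)
    max_lag: int = 10
    n_lag_knots: int = 2
    season_df: int = 4
    min_days: int = 270                      # drop thinner blocks (~60% of 2 seasons)
    allow_partial_blocks: bool = True
    mmt_search: tuple[float, float] = (1.0, 99.0)  # percentile bounds
    mmt_grid_step: float = 0.05                    # percentile units
    exclude_2003: bool = False
    exclude_2003_months: tuple[int, ...] = (6, 7, 8)  # "summer of 2003" read as JJA


@dataclass
class SubperiodFit:
    """Reduced overall-cumulative curve for one city x subperiod."""

    city_id: str
    subperiod: Subperiod
    curve: ReducedCurve
    dispersion: float
    n_days: int
    converged: bool

    def to_dict(self) -> dict:
        return {
            "city_id": self.city_id,
            "subperiod": {
                "index": self.subperiod.index,
                "start_year": self.subperiod.start_year,
                "end_year": self.subperiod.end_year,
            },
            "curve": self.curve.to_dict(),
            "dispersion": float(self.dispersion),
            "n_days": int(self.n_days),
            "converged": bool(self.converged),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SubperiodFit":
        return cls(
            city_id=d["city_id"],
            subperiod=Subperiod(**d["subperiod"]),
            curve=ReducedCurve.from_dict(d["curve"]),
            dispersion=float(d["dispersion"]),
            n_days=int(d["n_days"]),
            converged=bool(d["converged"]),
        )


def write_fits(fits: list["SubperiodFit"], path) -> None:
    with open(path, "w") as fh:
        for f in fits:
            fh.write(json.dumps(f.to_dict()) + "\n")


def read_fits(path) -> list["SubperiodFit"]:
    with open(path) as fh:
        return [SubperiodFit.from_dict(json.loads(line)) for line in fh if line.strip()]


# ---------------------------------------------------------------------------
# subperiod splitting
# ---------------------------------------------------------------------------

def split_subperiods(
    series: LocationSeries, config: Stage1Config = Stage1Config()
) -> list[tuple[Subperiod, np.ndarray]]:
    """(Subperiod, row indices of analyzed in-season days) for each block.

    Blocks are aligned to 1990 + 3k regardless of the city's start year;
    under ``allow_partial_blocks`` a partially covered block is kept (it is
    still subject to the min_days guard at fit time).  The lag window is
    NOT restricted here: the cross-basis is built on the full daily series,
    so early-May outcome days keep their late-April exposure history.
    """
    y0, y1 = series.dates[0].year, series.dates[-1].year
    in_season = season_mask(series.dates, config.season_months)
    years = series.dates.year.to_numpy()
    out = []
    for sp in enumerate_subperiods(y0, y1, config.block_years):
        covered = np.unique(years[(years >= sp.start_year) & (years <= sp.end_year)])
        if covered.size == 0:
            continue
        if not config.allow_partial_blocks and covered.size < config.block_years:
            continue
        rows = np.flatnonzero(in_season & (years >= sp.start_year) & (years <= sp.end_year))
        if rows.size:
            out.append((sp, rows))
    return out


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

def _day_of_season(dates: pd.DatetimeIndex) -> np.ndarray:
    """Days since April 30 of the same year (May 1 -> 1, Sep 30 -> 153)."""
    apr30 = pd.to_datetime({"year": dates.year, "month": 4, "day": 30})
    return (dates - pd.DatetimeIndex(apr30)).days.to_numpy()


def build_design(
    dates: pd.DatetimeIndex,
    cb_rows: np.ndarray,
    season_df: int = 4,
) -> tuple[np.ndarray, list[str]]:
    """Stage-1 design: intercept, per-year seasonal spline, day-of-week
    dummies (reference Monday), then the cross-basis columns.

    The seasonal control is a natural cubic spline with ``season_df``
    degrees of freedom in day of season, fitted separately for each year of
    the block (the year-indicator interaction).
    """
    n = len(dates)
    dos = _day_of_season(dates).astype(float)
    qs = np.quantile(dos, np.linspace(0, 1, season_df + 1))
    ns = natural_spline_basis(dos, qs[1:-1], (qs[0], qs[-1]), intercept=False)
    cols = [np.ones((n, 1))]
    names = ["intercept"]
    years = dates.year.to_numpy()
    for yr in np.unique(years):
        mask = (years == yr).astype(float)[:, None]
        cols.append(ns * mask)
        names += [f"ns{j + 1}:y{yr}" for j in range(ns.shape[1])]
    dow = dates.dayofweek.to_numpy()
    for d in range(1, 7):
        cols.append((dow == d).astype(float)[:, None])
        names.append(f"dow{d}")
    cols.append(cb_rows)
    names += [f"cb{j + 1}" for j in range(cb_rows.shape[1])]
    return np.column_stack(cols), names


def _drop_aliased(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[int]]:
    """Remove numerically aliased columns via pivoted QR; returns kept indices."""
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    keep = sorted(piv[diag > tol])
    if len(keep) < X.shape[1]:
        dropped = [names[i] for i in range(X.shape[1]) if i not in keep]
        log.info("dropping aliased design columns: %s", dropped)
    return X[:, keep], keep


# ---------------------------------------------------------------------------
# quasi-Poisson fit
# ---------------------------------------------------------------------------

def fit_quasipoisson(
    y: np.ndarray, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Quasi-Poisson GLM: Poisson IRLS point estimates, Pearson dispersion.

    Returns (coef, vcov, dispersion, converged); vcov is the Poisson-MLE
    covariance scaled by the Pearson chi2 / (n - p) dispersion estimate.
    """
    y = np.asarray(y)
    if np.any(y < 0):
        raise ValueError("fit_quasipoisson: counts must be nonnegative")
    if not y.any():
        raise ValueError("fit_quasipoisson: all-zero outcome")
    model = sm.GLM(y, X, family=sm.families.Poisson())
    try:
        res = model.fit(scale="X2", maxiter=100, tol=1e-8)
    except Exception as exc:  # pragma: no cover - rare numerical failure
        log.warning("GLM fit failed: %s", exc)
        p = X.shape[1]
        return np.full(p, np.nan), np.full((p, p), np.nan), np.nan, False
    converged = bool(getattr(res, "converged", True)) and bool(np.all(np.isfinite(res.params)))
    return res.params, res.cov_params(), float(res.scale), converged


# ---------------------------------------------------------------------------
# per-city pipeline
# ---------------------------------------------------------------------------

@dataclass
class PreparedCity:
    series: LocationSeries
    percentiles: EmpiricalPercentiles
    var_spec: VarBasisSpec
    lag_spec: LagBasisSpec
    perc: np.ndarray          # tmean expressed as warm-season percentile
    cb: np.ndarray            # cross-basis over the full daily series
    complete: np.ndarray      # rows with a full lag window
    table: dict = field(default_factory=dict)


def prepare_city(series: LocationSeries, config: Stage1Config = Stage1Config()) -> PreparedCity:
    in_season = season_mask(series.dates, config.season_months)
    ep = EmpiricalPercentiles(series.tmean[in_season])
    perc = ep.to_percentile(series.tmean)
    var_spec = VarBasisSpec(internal_knots=config.knot_percentiles, boundary=(0.0, 100.0))
    lag_spec = default_lag_spec(config.max_lag, config.n_lag_knots)
    cb, complete = cross_basis(perc, var_spec, lag_spec)
    return PreparedCity(
        series=series, percentiles=ep, var_spec=var_spec, lag_spec=lag_spec,
        perc=perc, cb=cb, complete=complete, table=ep.table(),
    )


def fit_city_subperiod(
    prep: PreparedCity, sp: Subperiod, rows: np.ndarray, config: Stage1Config = Stage1Config()
) -> SubperiodFit | None:
    rows = rows[prep.complete[rows]]
    if config.exclude_2003:
        dts = prep.series.dates[rows]
        drop = (np.asarray(dts.year) == 2003) & np.isin(np.asarray(dts.month), config.exclude_2003_months)
        rows = rows[~drop]
    if rows.size < config.min_days:
        log.info("%s %s: only %d analyzed days, skipping", prep.series.city_id, sp.label, rows.size)
        return None
    dates = prep.series.dates[rows]
    y = prep.series.deaths[rows]
    X, names = build_design(dates, prep.cb[rows], season_df=config.season_df)
    ncb = prep.cb.shape[1]
    Xk, keep = _drop_aliased(X, names)
    cb_positions = list(range(X.shape[1] - ncb, X.shape[1]))
    if not set(cb_positions) <= set(keep):
        log.warning("%s %s: aliased cross-basis columns, fit flagged", prep.series.city_id, sp.label)
        return None
    try:
        coef, vcov, phi, converged = fit_quasipoisson(y, Xk)
    except ValueError as exc:
        log.warning("%s %s: %s", prep.series.city_id, sp.label, exc)
        return None
    if not converged:
        return None
    idx = [keep.index(i) for i in cb_positions]
    cb_coef = coef[idx]
    cb_vcov = vcov[np.ix_(idx, idx)]
    curve = reduce_to_overall(
        cb_coef, cb_vcov, prep.var_spec, prep.lag_spec, center=0.0, percentiles=prep.table
    )
    mmt_x, _ = find_mmt(curve, config.mmt_search, config.mmt_grid_step)
    curve = curve.recentered(mmt_x)
    curve.mmt_x = mmt_x
    curve.mmt = float(prep.percentiles.to_celsius(mmt_x))
    return SubperiodFit(
        city_id=prep.series.city_id,
        subperiod=sp,
        curve=curve,
        dispersion=phi,
        n_days=int(rows.size),
        converged=converged,
    )


def first_stage(
    cities: list[LocationSeries], config: Stage1Config = Stage1Config()
) -> list[SubperiodFit]:
    """Fit every city x subperiod; failures are logged and skipped."""
    fits: list[SubperiodFit] = []
    n_failed = 0
    for series in cities:
        prep = prepare_city(series, config)
        for sp, rows in split_subperiods(series, config):
            fit = fit_city_subperiod(prep, sp, rows, config)
            if fit is None:
                n_failed += 1
            else:
                fits.append(fit)
    if n_failed:
        log.info("first_stage: %d city-subperiod blocks excluded", n_failed)
    return fits
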