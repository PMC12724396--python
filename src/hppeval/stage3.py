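"""Stage 3: heat-attributable mortality under factual vs counterfactual HPP.

BLUP curves from the stage-2 model are evaluated, per city x subperiod, on
days hotter than the 95th percentile of the location's full-period
warm-season temperature distribution.  The daily attributable fraction is
(RR-1)/RR against each curve's own minimum-mortality temperature, floored
at zero; attributable numbers (AN) sum into the heat-attributable fraction
of warm-season deaths (HAF, %) and annual attributable death rates per
100 000 inhabitants (HAD, 2015 populations).  The protective effect of heat
prevention plans is the contrast between the factual scenario (HPP
indicator as observed) and the counterfactual (indicator forced to 0) over
post-implementation subperiods, with 95% empirical confidence intervals
from Monte-Carlo samples of the meta-regression coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import LocationSeries, season_mask
from .splines import ReducedCurve, bspline_basis
from .stage1 import Stage1Config, SubperiodFit, split_subperiods
from .stage2 import K, LikelihoodContext, MetaDataset, MetaModel

SCOPES = ("overall", "region", "country", "hppclass", "location")


@dataclass(frozen=True)
class AttributionConfig:
    threshold_pct: float = 95.0
    n_samples: int = 1000
    mmt_search: tuple[float, float] = (1.0, 99.0)
    mmt_grid_step: float = 0.1            # percentile units
    floor_negative_af: bool = True
    share_mmt: bool = False               # counterfactual reuses the factual MMT
    sample_random_effects: bool = False   # also perturb BLUP random effects
    unweighted_region_mean: bool = False  # report region HAF change as mean of countries


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def attributable_numbers(
    tmean: np.ndarray,
    deaths: np.ndarray,
    curve: ReducedCurve,
    threshold_pct: float = 95.0,
    floor_negative_af: bool = True,
) -> tuple[np.ndarray, float, float]:
    """Daily AN, HAF (%) and total deaths for one series slice.

    ``tmean`` is in degrees Celsius and is mapped onto the curve's
    percentile scale through its location percentile table; the curve must
    already be centered at its MMT.
    """
    if not curve.percentiles:
        raise ValueError("attributable_numbers: curve lacks a percentile table")
    pcts = np.array(sorted(curve.percentiles))
    temps = np.array([curve.percentiles[p] for p in pcts])
    if temps[0] == temps[-1]:
        raise ValueError("attributable_numbers: degenerate (constant) temperature distribution")
    perc = np.interp(np.asarray(tmean, float), temps, pcts)
    deaths = np.asarray(deaths, float)
    an = np.zeros_like(deaths)
    hot = perc > threshold_pct
    if hot.any():
        rr = np.exp(curve.log_rr(perc[hot]))
        af = 1.0 - 1.0 / rr
        if floor_negative_af:
            af = np.maximum(af, 0.0)
        an[hot] = deaths[hot] * af
    total = float(deaths.sum())
    haf = 100.0 * an.sum() / total if total > 0 else 0.0
    return an, haf, total


def had_rate(an_total: float, population: int, n_years: float) -> float:
    """Annual attributable deaths per 100 000 inhabitants."""
    if population <= 0:
        raise ValueError("had_rate: population must be positive")
    if n_years <= 0:
        raise ValueError("had_rate: n_years must be positive")
    return an_total / n_years / population * 1e5


# ---------------------------------------------------------------------------
# unit preparation
# ---------------------------------------------------------------------------

@dataclass
class UnitData:
    """Everything needed to recompute one unit's AN for any coefficients."""

    city_id: str
    subperiod: int
    country: str
    region: str
    hppclass: int
    hpp_obs: int
    time: float
    Bq: np.ndarray            # (nq, 4) basis rows of qualifying (hot) days
    deaths_q: np.ndarray      # (nq,)
    total_deaths: float       # all warm-season deaths in the slice
    n_years: int
    population: int
    Xf_fact: np.ndarray       # (4, p)
    Xf_cf: np.ndarray         # (4, p)
    re: np.ndarray            # (4,) b0 + time*b1 random-effect contribution

    @property
    def post(self) -> bool:
        return self.hpp_obs == 1

    @property
    def person_years(self) -> float:
        return float(self.population) * self.n_years


@dataclass
class AttributionProblem:
    units: list[UnitData]
    model: MetaModel
    grid: np.ndarray           # (ngrid,) percentile grid for MMT search
    G: np.ndarray              # (ngrid, 4) basis on the grid
    config: AttributionConfig
    re_point: dict[str, np.ndarray] = field(default_factory=dict)  # city -> (8,)
    re_cov: dict[str, np.ndarray] = field(default_factory=dict)    # city -> (8,8)


def build_attribution_problem(
    cities: list[LocationSeries],
    fits: list[SubperiodFit],
    model: MetaModel,
    dataset: MetaDataset,
    stage1_config: Stage1Config = Stage1Config(),
    config: AttributionConfig = AttributionConfig(),
) -> AttributionProblem:
    """Assemble per-unit day-level inputs and scenario design rows."""
    from .splines import EmpiricalPercentiles

    ctx = LikelihoodContext(dataset, model.design)
    re = ctx.blups(model.beta, model.psi)
    re_cov = ctx.blup_cov(model.psi) if config.sample_random_effects else {}

    fit_index = {(f.city_id, f.subperiod.index): f for f in fits}
    var_spec = fits[0].curve.var_spec
    lo, hi = config.mmt_search
    grid = np.arange(lo, hi + 0.5 * config.mmt_grid_step, config.mmt_grid_step)
    G = bspline_basis(grid, var_spec)

    city_by_id = {c.city_id: c for c in cities}
    units: list[UnitData] = []
    for row in dataset.covariates.itertuples():
        key = (row.city_id, row.subperiod)
        if key not in fit_index:
            continue
        series = city_by_id[row.city_id]
        sp = fit_index[key].subperiod
        in_season = season_mask(series.dates, stage1_config.season_months)
        years = series.dates.year.to_numpy()
        in_sp = in_season & (years >= sp.start_year) & (years <= sp.end_year)
        ep = EmpiricalPercentiles(series.tmean[in_season])
        perc = ep.to_percentile(series.tmean)
        hot = in_sp & (perc > config.threshold_pct)
        Bq = bspline_basis(perc[hot], var_spec)
        x_f = model.design.row(row.hpp, row.region, row.time, int(row.hppclass))
        x_c = model.design.row(0.0, row.region, row.time, int(row.hppclass))
        b = re[row.city_id]
        units.append(
            UnitData(
                city_id=row.city_id,
                subperiod=row.subperiod,
                country=row.country if hasattr(row, "country") else row.city_id,
                region=row.region,
                hppclass=int(row.hppclass),
                hpp_obs=int(row.hpp),
                time=float(row.time),
                Bq=Bq,
                deaths_q=series.deaths[hot].astype(float),
                total_deaths=float(series.deaths[in_sp].sum()),
                n_years=int(np.unique(years[in_sp]).size),
                population=series.population,
                Xf_fact=np.kron(x_f, np.eye(K)),
                Xf_cf=np.kron(x_c, np.eye(K)),
                re=b[:K] + float(row.time) * b[K:],
            )
        )
    return AttributionProblem(
        units=units, model=model, grid=grid, G=G, config=config,
        re_point=dict(re), re_cov=re_cov,
    )


# ---------------------------------------------------------------------------
# AN computation for a coefficient draw
# ---------------------------------------------------------------------------

def _unit_coefs(problem: AttributionProblem, beta: np.ndarray, which: str,
                re_draw: dict[str, np.ndarray] | None = None) -> np.ndarray:
    """(U, 4) scenario curve coefficients for one beta draw."""
    out = np.empty((len(problem.units), K))
    for u, unit in enumerate(problem.units):
        Xf = unit.Xf_fact if which == "factual" else unit.Xf_cf
        re = unit.re
        if re_draw is not None:
            b = re_draw[unit.city_id]
            re = b[:K] + unit.time * b[K:]
        out[u] = Xf @ beta + re
    return out


def _an_per_unit(problem: AttributionProblem, coefs: np.ndarray,
                 mmt_override: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """AN per unit for given (U,4) coefficients; returns (an, mmt_values).

    The curve minimum over the search grid recenters each curve at its own
    MMT; ``mmt_override`` (grid values per unit) shares the factual MMT with
    the counterfactual when configured.
    """
    vals = problem.G @ coefs.T                     # (ngrid, U)
    if mmt_override is None:
        imin = np.argmin(vals, axis=0)
    else:
        imin = mmt_override
    base = vals[imin, np.arange(vals.shape[1])]
    an = np.empty(len(problem.units))
    for u, unit in enumerate(problem.units):
        if unit.Bq.shape[0] == 0:
            an[u] = 0.0
            continue
        logrr = unit.Bq @ coefs[u] - base[u]
        af = 1.0 - np.exp(-logrr)
        if problem.config.floor_negative_af:
            af = np.maximum(af, 0.0)
        an[u] = float(unit.deaths_q @ af)
    return an, imin


def scenario_an(problem: AttributionProblem, beta: np.ndarray,
                re_draw: dict[str, np.ndarray] | None = None) -> tuple[np.ndarray, np.ndarray]:
    """(AN_factual, AN_counterfactual) per unit for one coefficient draw."""
    cf_coefs = _unit_coefs(problem, beta, "counterfactual", re_draw)
    f_coefs = _unit_coefs(problem, beta, "factual", re_draw)
    an_f, imin_f = _an_per_unit(problem, f_coefs)
    an_cf, _ = _an_per_unit(
        problem, cf_coefs, mmt_override=imin_f if problem.config.share_mmt else None
    )
    return an_f, an_cf


def scenario_curves(problem: AttributionProblem) -> list[dict]:
    """Point-estimate factual/counterfactual curves per unit (diagnostics)."""
    beta = problem.model.beta
    out = []
    for which in ("factual", "counterfactual"):
        coefs = _unit_coefs(problem, beta, which)
        vals = problem.G @ coefs.T
        imin = np.argmin(vals, axis=0)
        for u, unit in enumerate(problem.units):
            out.append(
                {
                    "city_id": unit.city_id,
                    "subperiod": unit.subperiod,
                    "scenario": which,
                    "post_implementation": unit.post,
                    "coef": coefs[u].tolist(),
                    "mmt_percentile": float(problem.grid[imin[u]]),
                }
            )
    return out


# ---------------------------------------------------------------------------
# aggregation and contrasts
# ---------------------------------------------------------------------------

def _scope_groups(problem: AttributionProblem, post_only: bool) -> list[tuple[str, str, np.ndarray]]:
    """(scope_type, scope_label, unit index array) for every reporting scope."""
    units = problem.units
    sel = np.array([(u.post or not post_only) for u in units])
    idx_all = np.flatnonzero(sel)
    groups: list[tuple[str, str, np.ndarray]] = [("overall", "overall", idx_all)]
    for attr, scope in (("region", "region"), ("country", "country"), ("hppclass", "hppclass"),
                        ("city_id", "location")):
        labels = sorted({str(getattr(u, attr)) for u in units})
        for lab in labels:
            idx = np.array(
                [i for i in idx_all if str(getattr(units[i], attr)) == lab], dtype=int
            )
            if idx.size:
                groups.append((scope, lab, idx))
    return groups


def _summaries(problem: AttributionProblem, an_f: np.ndarray, an_cf: np.ndarray,
               groups: list[tuple[str, str, np.ndarray]]) -> np.ndarray:
    """Per-group summary vector for one draw.

    Columns: haf_f, haf_cf, haf_change, had_f, had_cf, had_diff, deaths_avoided.
    """
    deaths = np.array([u.total_deaths for u in problem.units])
    py = np.array([u.person_years for u in problem.units])
    out = np.full((len(groups), 7), np.nan)
    for gi, (_, _, idx) in enumerate(groups):
        d = deaths[idx].sum()
        p = py[idx].sum()
        af, acf = an_f[idx].sum(), an_cf[idx].sum()
        haf_f = 100.0 * af / d if d > 0 else np.nan
        haf_cf = 100.0 * acf / d if d > 0 else np.nan
        change = 100.0 * (haf_f - haf_cf) / haf_cf if haf_cf and haf_cf > 0 else np.nan
        had_f = 1e5 * af / p if p > 0 else np.nan
        had_cf = 1e5 * acf / p if p > 0 else np.nan
        out[gi] = (haf_f, haf_cf, change, had_f, had_cf, had_f - had_cf, acf - af)
    return out


_COLS = ("haf_factual", "haf_counterfactual", "haf_change",
         "had_factual", "had_counterfactual", "had_difference", "deaths_avoided")


def monte_carlo_ci(
    problem: AttributionProblem,
    seed: int | np.random.Generator = 0,
    n_samples: int | None = None,
) -> dict:
    """Point estimates and 95% empirical CIs for every scope.

    Samples the fixed-effect coefficients from MVN(beta, vcov_beta)
    (optionally also the city random effects from their conditional
    covariance), recomputes both scenarios' AN per sample, and takes the
    empirical 2.5th/97.5th percentiles of each aggregated quantity.
    """
    import warnings

    cfg = problem.config
    n_samples = cfg.n_samples if n_samples is None else n_samples
    if n_samples < 100:
        warnings.warn(f"monte_carlo_ci: only {n_samples} samples; CIs will be unstable")
    model = problem.model
    vc = 0.5 * (model.vcov_beta + model.vcov_beta.T)
    evals, evecs = np.linalg.eigh(vc)
    if evals.min() < -1e-8 * max(1.0, np.abs(vc).max()):
        raise ValueError("monte_carlo_ci: vcov_beta is not positive semi-definite")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # exact PSD square root (no jitter): degenerate directions stay exact
    L = evecs * np.sqrt(np.clip(evals, 0.0, None))

    groups = _scope_groups(problem, post_only=True)
    an_f0, an_cf0 = scenario_an(problem, model.beta)
    point = _summaries(problem, an_f0, an_cf0, groups)

    re_chol = {}
    if cfg.sample_random_effects:
        for city, C in problem.re_cov.items():
            re_chol[city] = np.linalg.cholesky(C + 1e-10 * np.eye(C.shape[0]))

    draws = np.empty((n_samples, len(groups), 7))
    an_samples_f = np.empty((n_samples, len(problem.units)))
    an_samples_cf = np.empty((n_samples, len(problem.units)))
    for s in range(n_samples):
        beta = model.beta + L @ rng.standard_normal(model.beta.shape[0])
        re_draw = None
        if cfg.sample_random_effects:
            re_draw = {
                city: problem.re_point[city] + Lc @ rng.standard_normal(Lc.shape[0])
                for city, Lc in re_chol.items()
            }
        an_f, an_cf = scenario_an(problem, beta, re_draw)
        an_samples_f[s], an_samples_cf[s] = an_f, an_cf
        draws[s] = _summaries(problem, an_f, an_cf, groups)

    with np.errstate(invalid="ignore"):
        lo = np.nanpercentile(draws, 2.5, axis=0)
        hi = np.nanpercentile(draws, 97.5, axis=0)

    rows = []
    for gi, (scope_type, label, idx) in enumerate(groups):
        row = {"scope_type": scope_type, "scope": label, "n_units": int(idx.size)}
        for ci, col in enumerate(_COLS):
            row[col] = point[gi, ci]
            row[f"{col}_lo"] = lo[gi, ci]
            row[f"{col}_hi"] = hi[gi, ci]
        rows.append(row)
    table = pd.DataFrame(rows)

    if cfg.unweighted_region_mean:
        table = _add_unweighted_means(problem, table, draws, point, groups)

    return {
        "table": table,
        "groups": [(t, l) for t, l, _ in groups],
        "an_factual": an_samples_f,
        "an_counterfactual": an_samples_cf,
        "point_an": (an_f0, an_cf0),
    }


def _add_unweighted_means(problem, table, draws, point, groups) -> pd.DataFrame:
    """Append region rows formed as unweighted means of country HAF changes."""
    country_region = {u.country: u.region for u in problem.units}
    gidx = {(t, l): i for i, (t, l, _) in enumerate(groups)}
    extra = []
    for region in sorted({u.region for u in problem.units if u.post}):
        members = [gidx[("country", c)] for c, r in country_region.items()
                   if r == region and ("country", c) in gidx]
        if not members:
            continue
        row = {"scope_type": "region_unweighted", "scope": region, "n_units": len(members)}
        for ci, col in enumerate(_COLS):
            vals = point[members, ci]
            dvals = np.nanmean(draws[:, members, ci], axis=1)
            row[col] = float(np.nanmean(vals))
            row[f"{col}_lo"] = float(np.nanpercentile(dvals, 2.5))
            row[f"{col}_hi"] = float(np.nanpercentile(dvals, 97.5))
        extra.append(row)
    return pd.concat([table, pd.DataFrame(extra)], ignore_index=True)


def haf_trajectories(problem: AttributionProblem) -> pd.DataFrame:
    """Overall HAF per subperiod under both scenarios (point estimates)."""
    beta = problem.model.beta
    an_f, an_cf = scenario_an(problem, beta)
    deaths = np.array([u.total_deaths for u in problem.units])
    sps = sorted({u.subperiod for u in problem.units})
    rows = []
    for sp in sps:
        idx = np.array([i for i, u in enumerate(problem.units) if u.subperiod == sp])
        d = deaths[idx].sum()
        rows.append(
            {
                "subperiod": sp,
                "haf_factual": 100.0 * an_f[idx].sum() / d if d else np.nan,
                "haf_counterfactual": 100.0 * an_cf[idx].sum() / d if d else np.nan,
                "n_post_units": int(sum(problem.units[i].post for i in idx)),
            }
        )
    return pd.DataFrame(rows)
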