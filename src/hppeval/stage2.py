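"""Stage 2: multilevel longitudinal multivariate meta-regression.

Pools the 4-dimensional reduced curve coefficients across city x subperiod
units.  For unit j of city i with outcome theta_ij (known within-unit
covariance S_ij) the model is

    theta_ij = (x_ij (x) I4) beta + b0_i + t_ij * b1_i + e_ij

with fixed-effect covariates x_ij (HPP indicator, Region, Time and their
interactions), city-level random intercepts b0_i and slopes b1_i in Time
(each 4-dimensional with diagonal covariance - 8 variance parameters), and
e_ij ~ N(0, S_ij).  Estimation is maximum likelihood: beta is profiled out
by GLS and the 8 log-variances are optimized by quasi-Newton with
multi-start.  Nested model variants are compared by likelihood ratio tests,
and city-specific curves are recovered as empirical-Bayes BLUPs, which can
be predicted under factual (HPP as observed) or counterfactual (HPP forced
to 0) scenarios by toggling only the fixed-effect HPP term.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

K = 4  # outcome dimension: reduced-curve spline coefficients

#: fixed-effect structures of the registered model variants; any other
#: combination of the known terms can be passed as an explicit tuple
MODEL_TERMS: dict[int, tuple[str, ...]] = {
    3: ("1", "hpp", "region", "time", "region:time"),
    4: ("1", "hpp", "region", "time", "region:time", "hpp:region"),
    5: ("1", "region", "time", "region:time", "hpp:class"),
}

KNOWN_TERMS = ("1", "hpp", "region", "time", "region:time", "hpp:region", "hpp:class")


# ---------------------------------------------------------------------------
# dataset
# ---------------------------------------------------------------------------

@dataclass
class MetaDataset:
    """Units (city x subperiod) with outcomes, covariances and covariates.

    ``covariates`` must contain columns: city_id, subperiod, hpp (0/1),
    region, time (already centered), hppclass (1/2/3).
    """

    theta: np.ndarray          # (U, 4)
    S: np.ndarray              # (U, 4, 4)
    covariates: pd.DataFrame
    time_center: float = 0.0

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, float)
        self.S = np.asarray(self.S, float)
        U = self.theta.shape[0]
        if self.theta.shape != (U, K) or self.S.shape != (U, K, K):
            raise ValueError("MetaDataset: theta must be (U,4) and S (U,4,4)")
        if len(self.covariates) != U:
            raise ValueError("MetaDataset: covariates length mismatch")
        for col in ("city_id", "subperiod", "hpp", "region", "time", "hppclass"):
            if col not in self.covariates.columns:
                raise ValueError(f"MetaDataset: covariates missing column {col!r}")
        if self.covariates[["hpp", "region", "time", "hppclass"]].isna().any().any():
            raise ValueError("MetaDataset: covariates must be complete")
        for u in range(U):
            Su = self.S[u]
            if not np.allclose(Su, Su.T, atol=1e-8):
                raise ValueError(f"MetaDataset: S[{u}] not symmetric")
            if np.linalg.eigvalsh(0.5 * (Su + Su.T)).min() < -1e-8 * max(1.0, np.abs(Su).max()):
                raise ValueError(f"MetaDataset: S[{u}] not positive semi-definite")

    @property
    def n_units(self) -> int:
        return self.theta.shape[0]

    @property
    def cities(self) -> list[str]:
        return sorted(self.covariates["city_id"].unique())

    def unit_keys(self) -> tuple:
        return tuple(zip(self.covariates["city_id"], self.covariates["subperiod"]))


def assemble_meta_dataset(
    fits: list,
    catalogue: pd.DataFrame,
    city_meta: dict[str, tuple[str, str]],
    indicator_rule: str = "start_year",
    time_center: float | None = None,
) -> MetaDataset:
    """Build the stage-2 dataset from stage-1 fits and the HPP catalogue.

    ``city_meta`` maps city_id -> (country, region).  Time is the subperiod
    midpoint year centered at the grand mean (or at ``time_center``).
    """
    from .hpp import hpp_indicator

    cat = catalogue.set_index("country")
    rows, thetas, Ss = [], [], []
    for f in fits:
        if not f.converged:
            continue
        country, region = city_meta[f.city_id]
        if country not in cat.index:
            raise ValueError(f"assemble_meta_dataset: country {country!r} missing from catalogue")
        hpp_year = cat.loc[country, "hpp_year"]
        hpp_year = None if pd.isna(hpp_year) else int(hpp_year)
        sp = f.subperiod
        rows.append(
            {
                "city_id": f.city_id,
                "subperiod": sp.index,
                "country": country,
                "region": region,
                "hpp": hpp_indicator(hpp_year, sp.start_year, sp.end_year, indicator_rule),
                "time": sp.mid_time,
                "hppclass": int(cat.loc[country, "hpp_class"]),
            }
        )
        thetas.append(f.curve.coef)
        Ss.append(f.curve.vcov)
    cov = pd.DataFrame(rows)
    center = float(cov["time"].mean()) if time_center is None else float(time_center)
    cov["time"] = cov["time"] - center
    return MetaDataset(theta=np.array(thetas), S=np.array(Ss), covariates=cov, time_center=center)


# ---------------------------------------------------------------------------
# fixed-effect design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixedDesign:
    terms: tuple[str, ...]
    region_levels: tuple[str, ...]
    class_levels: tuple[int, ...] = (1, 2, 3)

    def __post_init__(self) -> None:
        for t in self.terms:
            if t not in KNOWN_TERMS:
                raise ValueError(f"FixedDesign: unknown term {t!r}")

    @property
    def names(self) -> list[str]:
        out = []
        for t in self.terms:
            if t == "1":
                out.append("intercept")
            elif t in ("hpp", "time"):
                out.append(t)
            elif t == "region":
                out += [f"region[{r}]" for r in self.region_levels[1:]]
            elif t == "region:time":
                out += [f"region[{r}]:time" for r in self.region_levels[1:]]
            elif t == "hpp:region":
                out += [f"hpp:region[{r}]" for r in self.region_levels[1:]]
            elif t == "hpp:class":
                out += [f"hpp:class[{c}]" for c in self.class_levels]
        return out

    @property
    def q(self) -> int:
        return len(self.names)

    def row(self, hpp: float, region: str, time: float, hppclass: int | None = None) -> np.ndarray:
        if region not in self.region_levels:
            raise ValueError(f"FixedDesign: unseen region level {region!r}")
        need_class = "hpp:class" in self.terms
        if need_class and hppclass not in self.class_levels:
            raise ValueError(f"FixedDesign: unseen HPP class {hppclass!r}")
        out = []
        for t in self.terms:
            if t == "1":
                out.append(1.0)
            elif t == "hpp":
                out.append(float(hpp))
            elif t == "time":
                out.append(float(time))
            elif t == "region":
                out += [float(region == r) for r in self.region_levels[1:]]
            elif t == "region:time":
                out += [float(region == r) * time for r in self.region_levels[1:]]
            elif t == "hpp:region":
                out += [float(hpp) * float(region == r) for r in self.region_levels[1:]]
            elif t == "hpp:class":
                out += [float(hpp) * float(hppclass == c) for c in self.class_levels]
        return np.array(out)

    def matrix(self, cov: pd.DataFrame) -> np.ndarray:
        return np.vstack(
            [
                self.row(r.hpp, r.region, r.time, int(r.hppclass))
                for r in cov.itertuples()
            ]
        )


def resolve_terms(spec: int | tuple[str, ...] | list[str]) -> tuple[str, ...]:
    if isinstance(spec, int):
        if spec not in MODEL_TERMS:
            raise ValueError(
                f"model {spec} has no registered form; pass an explicit term tuple instead"
            )
        return MODEL_TERMS[spec]
    return tuple(spec)


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------

@dataclass
class _CityGroup:
    """Cities sharing a subperiod count, batched for dense linear algebra."""

    n: int                 # subperiods per city in this group
    city_ids: list[str]
    y: np.ndarray          # (k, 4n)
    X: np.ndarray          # (k, 4n, p) fixed design, p = 4q
    S: np.ndarray          # (k, 4n, 4n) blockdiag within-unit covariances
    J: np.ndarray          # (k, n, n) all-ones (intercept RE pattern)
    TT: np.ndarray         # (k, n, n) outer(t, t) (time RE pattern)
    t: np.ndarray          # (k, n) times


class LikelihoodContext:
    """Precomputed per-city blocks for fast repeated likelihood evaluation."""

    def __init__(self, dataset: MetaDataset, design: FixedDesign):
        self.dataset = dataset
        self.design = design
        Xrows = design.matrix(dataset.covariates)  # (U, q)
        p = K * design.q
        groups: dict[int, list] = {}
        cov = dataset.covariates
        for city, idx in cov.groupby("city_id", sort=True).indices.items():
            idx = np.sort(idx)
            n = len(idx)
            y = dataset.theta[idx].ravel()
            X = np.vstack([np.kron(Xrows[u], np.eye(K)) for u in idx])  # (4n, p)
            S = np.zeros((K * n, K * n))
            for a, u in enumerate(idx):
                S[K * a : K * a + K, K * a : K * a + K] = dataset.S[u]
            t = cov["time"].to_numpy()[idx]
            groups.setdefault(n, []).append((city, y, X, S, t))
        self.groups: list[_CityGroup] = []
        for n, items in sorted(groups.items()):
            ids = [it[0] for it in items]
            y = np.stack([it[1] for it in items])
            X = np.stack([it[2] for it in items])
            S = np.stack([it[3] for it in items])
            t = np.stack([it[4] for it in items])
            TT = np.einsum("ka,kb->kab", t, t)
            J = np.ones((len(items), n, n))
            self.groups.append(_CityGroup(n=n, city_ids=ids, y=y, X=X, S=S, J=J, TT=TT, t=t))
        self.p = p
        self.n_cities = sum(len(g.city_ids) for g in self.groups)
        self.n_obs = K * dataset.n_units

    @staticmethod
    def _kron_diag(A: np.ndarray, d: np.ndarray) -> np.ndarray:
        """Batched kron(A, diag(d)): (k,n,n) x (4,) -> (k,4n,4n)."""
        k, n, _ = A.shape
        out = np.zeros((k, n, K, n, K))
        for i in range(K):
            out[:, :, i, :, i] = A * d[i]
        return out.reshape(k, n * K, n * K)

    def _marginal_cov(self, g: _CityGroup, psi: np.ndarray) -> np.ndarray:
        return g.S + self._kron_diag(g.J, psi[:K]) + self._kron_diag(g.TT, psi[K:])

    def profiled(self, psi: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
        """GLS beta given psi, its covariance, and the ML log-likelihood."""
        psi = np.asarray(psi, float)
        A = np.zeros((self.p, self.p))
        b = np.zeros(self.p)
        yVy = 0.0
        logdet = 0.0
        for g in self.groups:
            V = self._marginal_cov(g, psi)
            sign, ld = np.linalg.slogdet(V)
            if np.any(sign <= 0):
                return np.full(self.p, np.nan), np.full((self.p, self.p), np.nan), -np.inf
            logdet += float(ld.sum())
            rhs = np.concatenate([g.X, g.y[:, :, None]], axis=2)
            sol = np.linalg.solve(V, rhs)
            VX, Vy = sol[:, :, :-1], sol[:, :, -1]
            A += np.einsum("kij,kil->jl", g.X, VX)
            b += np.einsum("kij,ki->j", g.X, Vy)
            yVy += float(np.einsum("ki,ki->", g.y, Vy))
        try:
            beta = np.linalg.solve(A, b)
            vcov_beta = np.linalg.inv(A)
        except np.linalg.LinAlgError:
            return np.full(self.p, np.nan), np.full((self.p, self.p), np.nan), -np.inf
        quad = yVy - 2.0 * beta @ b + beta @ A @ beta
        ll = -0.5 * (self.n_obs * np.log(2.0 * np.pi) + logdet + quad)
        return beta, vcov_beta, float(ll)

    def profiled_grad(self, psi: np.ndarray) -> tuple[float, np.ndarray]:
        """Profile log-likelihood and its gradient w.r.t. psi.

        By the envelope theorem the gradient of the beta-profiled likelihood
        equals the partial derivative at the GLS beta:
        d ll / d psi_k = 0.5 * (w' P_k w - tr(V^-1 P_k)) summed over cities,
        with w = V^-1 r and P_k the random-effect design pattern.
        """
        psi = np.asarray(psi, float)
        beta, _, ll = self.profiled(psi)
        if not np.isfinite(ll):
            return -np.inf, np.zeros(2 * K)
        grad = np.zeros(2 * K)
        for g in self.groups:
            V = self._marginal_cov(g, psi)
            Vinv = np.linalg.inv(V)
            r = g.y - np.einsum("kij,j->ki", g.X, beta)
            w = np.einsum("kij,kj->ki", Vinv, r)
            k_c, n = len(g.city_ids), g.n
            w3 = w.reshape(k_c, n, K)
            G = Vinv.reshape(k_c, n, K, n, K)
            for i in range(K):
                wi = w3[:, :, i]                      # (k, n)
                Gi = G[:, :, i, :, i]                 # (k, n, n)
                # intercept pattern J (all-ones)
                grad[i] += 0.5 * float(
                    np.sum(wi.sum(axis=1) ** 2) - Gi.sum()
                )
                # time pattern t t'
                tw = np.einsum("ka,ka->k", g.t, wi)
                trt = np.einsum("ka,kab,kb->k", g.t, Gi, g.t)
                grad[K + i] += 0.5 * float(np.sum(tw**2) - trt.sum())
        return ll, grad

    def loglik(self, beta: np.ndarray, psi: np.ndarray) -> float:
        """Marginal Gaussian log-likelihood at given (beta, psi)."""
        psi = np.asarray(psi, float)
        if np.any(psi < 0):
            raise ValueError("marginal_loglik: psi must be nonnegative")
        beta = np.asarray(beta, float)
        total = 0.0
        for g in self.groups:
            V = self._marginal_cov(g, psi)
            sign, ld = np.linalg.slogdet(V)
            if np.any(sign <= 0):
                bad = g.city_ids[int(np.argmax(sign <= 0))]
                raise np.linalg.LinAlgError(f"singular marginal covariance for city {bad}")
            r = g.y - np.einsum("kij,j->ki", g.X, beta)
            Vr = np.linalg.solve(V, r[:, :, None])[:, :, 0]
            total += -0.5 * float(
                K * g.n * len(g.city_ids) * np.log(2.0 * np.pi)
                + ld.sum()
                + np.einsum("ki,ki->", r, Vr)
            )
        return total

    def blups(self, beta: np.ndarray, psi: np.ndarray) -> dict[str, np.ndarray]:
        """Empirical-Bayes city random effects b_hat = Psi Z' V^-1 (y - X beta).

        Returns city_id -> (8,) vector: 4 intercept deviations then 4 time
        slopes.
        """
        out: dict[str, np.ndarray] = {}
        psi = np.asarray(psi, float)
        for g in self.groups:
            V = self._marginal_cov(g, psi)
            r = g.y - np.einsum("kij,j->ki", g.X, beta)
            Vr = np.linalg.solve(V, r[:, :, None])[:, :, 0]
            k, n = len(g.city_ids), g.n
            Z = np.zeros((k, K * n, 2 * K))
            for a in range(n):
                Z[:, K * a : K * a + K, :K] = np.eye(K)
                Z[:, K * a : K * a + K, K:] = np.eye(K)[None] * g.t[:, a, None, None]
            bhat = np.einsum("kip,ki->kp", Z, Vr) * psi
            for j, city in enumerate(g.city_ids):
                out[city] = bhat[j]
        return out

    def blup_cov(self, psi: np.ndarray) -> dict[str, np.ndarray]:
        """Conditional covariance of the city random effects,
        Psi - Psi Z' V^-1 Z Psi (fixed effects treated as known)."""
        out: dict[str, np.ndarray] = {}
        psi = np.asarray(psi, float)
        Psi = np.diag(psi)
        for g in self.groups:
            V = self._marginal_cov(g, psi)
            k, n = len(g.city_ids), g.n
            Z = np.zeros((k, K * n, 2 * K))
            for a in range(n):
                Z[:, K * a : K * a + K, :K] = np.eye(K)
                Z[:, K * a : K * a + K, K:] = np.eye(K)[None] * g.t[:, a, None, None]
            VZ = np.linalg.solve(V, Z)
            ZVZ = np.einsum("kip,kiq->kpq", Z, VZ)
            for j, city in enumerate(g.city_ids):
                C = Psi - Psi @ ZVZ[j] @ Psi
                out[city] = 0.5 * (C + C.T)
        return out


def marginal_loglik(
    beta: np.ndarray, psi: np.ndarray, dataset: MetaDataset, terms: int | tuple = 3
) -> float:
    """Marginal log-likelihood of the multilevel multivariate model."""
    design = FixedDesign(resolve_terms(terms), tuple(sorted(dataset.covariates["region"].unique())))
    return LikelihoodContext(dataset, design).loglik(beta, psi)


# ---------------------------------------------------------------------------
# fitted model
# ---------------------------------------------------------------------------

@dataclass
class MetaModel:
    spec: str
    terms: tuple[str, ...]
    design: FixedDesign
    beta: np.ndarray           # (4q,)
    vcov_beta: np.ndarray      # (4q, 4q)
    psi: np.ndarray            # (8,) intercept then time variances
    loglik: float
    converged: bool
    n_units: int
    n_cities: int
    unit_keys: tuple = ()
    time_center: float = 0.0

    def coef_table(self) -> pd.DataFrame:
        names = [f"{t}.b{j + 1}" for t in self.design.names for j in range(K)]
        se = np.sqrt(np.maximum(np.diag(self.vcov_beta), 0.0))
        return pd.DataFrame({"term": names, "estimate": self.beta, "se": se})

    def to_dict(self) -> dict:
        return {
            "spec": self.spec,
            "terms": list(self.terms),
            "region_levels": list(self.design.region_levels),
            "class_levels": list(self.design.class_levels),
            "beta": self.beta.tolist(),
            "vcov_beta": self.vcov_beta.ravel().tolist(),
            "psi": self.psi.tolist(),
            "loglik": self.loglik,
            "converged": self.converged,
            "n_units": self.n_units,
            "n_cities": self.n_cities,
            "time_center": self.time_center,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MetaModel":
        design = FixedDesign(tuple(d["terms"]), tuple(d["region_levels"]), tuple(d["class_levels"]))
        p = len(d["beta"])
        return cls(
            spec=d["spec"], terms=tuple(d["terms"]), design=design,
            beta=np.array(d["beta"]), vcov_beta=np.array(d["vcov_beta"]).reshape(p, p),
            psi=np.array(d["psi"]), loglik=float(d["loglik"]), converged=bool(d["converged"]),
            n_units=int(d["n_units"]), n_cities=int(d["n_cities"]),
            time_center=float(d.get("time_center", 0.0)),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "MetaModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_meta(
    dataset: MetaDataset,
    spec: int | tuple[str, ...] | list[str] = 3,
    n_starts: int = 3,
    tol: float = 1e-7,
    max_iter: int = 200,
) -> MetaModel:
    """Maximum-likelihood fit: GLS-profiled beta, quasi-Newton on log psi.

    Multi-start on the log-variance scale; the best log-likelihood wins
    (ties broken by the smaller parameter norm).  Variances estimated on
    the boundary come back numerically zero (~1e-7 of the outcome scale).
    """
    if len(dataset.cities) < 2:
        raise ValueError("fit_meta: need at least 2 cities")
    terms = resolve_terms(spec)
    design = FixedDesign(terms, tuple(sorted(dataset.covariates["region"].unique())))
    ctx = LikelihoodContext(dataset, design)

    scale = max(float(np.var(dataset.theta, axis=0).mean()), 1e-8)
    LO, HI = np.log(scale) - 16.0, np.log(scale) + 5.0

    BAD = 1e30  # sentinel for failed likelihood evaluations

    def neg(eta: np.ndarray) -> tuple[float, np.ndarray]:
        psi = np.exp(eta)
        ll, dpsi = ctx.profiled_grad(psi)
        if not np.isfinite(ll):
            return BAD, np.zeros_like(eta)
        return -ll, -dpsi * psi  # chain rule onto the log-variance scale

    # moment start: between-city residual variance net of mean within-unit S
    resid = dataset.theta - dataset.theta.mean(axis=0)
    between = np.maximum(np.var(resid, axis=0) - np.diag(dataset.S.mean(axis=0)), scale * 1e-3)
    starts = [
        np.log(np.concatenate([between, between * 0.1])),
        np.full(2 * K, np.log(scale * 0.5)),
        np.full(2 * K, LO + 2.0),
    ][: max(n_starts, 1)]
    for extra in range(len(starts), n_starts):
        rng = np.random.default_rng(extra)
        starts.append(np.log(scale) + rng.uniform(-6, 1, size=2 * K))

    best = None
    any_ok = False
    for eta0 in starts:
        res = optimize.minimize(
            neg, np.clip(eta0, LO, HI), method="L-BFGS-B", jac=True,
            bounds=[(LO, HI)] * (2 * K),
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-8},
        )
        ok = np.isfinite(res.fun) and res.fun < BAD / 10
        any_ok = any_ok or (ok and res.success)
        if ok and (
            best is None
            or res.fun < best.fun - 1e-10
            or (abs(res.fun - best.fun) <= 1e-10 and np.linalg.norm(res.x) < np.linalg.norm(best.x))
        ):
            best = res
    if best is None:
        raise RuntimeError("fit_meta: likelihood evaluation failed from every start")
    psi = np.exp(best.x)
    psi[psi < scale * 1e-10] = 0.0
    beta, vcov_beta, ll = ctx.profiled(psi)
    return MetaModel(
        spec=str(spec), terms=terms, design=design, beta=beta, vcov_beta=vcov_beta,
        psi=psi, loglik=ll, converged=bool(any_ok), n_units=dataset.n_units,
        n_cities=len(dataset.cities), unit_keys=dataset.unit_keys(),
        time_center=dataset.time_center,
    )


def lrt(full: MetaModel, reduced: MetaModel) -> tuple[float, int, float]:
    """Likelihood ratio test of nested ML fits on identical units."""
    if full.unit_keys and reduced.unit_keys and full.unit_keys != reduced.unit_keys:
        raise ValueError("lrt: models fitted on different unit sets")
    if not set(reduced.terms) < set(full.terms):
        raise ValueError("lrt: reduced model terms are not a strict subset of the full model")
    df = len(full.beta) - len(reduced.beta)
    stat = max(2.0 * (full.loglik - reduced.loglik), 0.0)
    if df == 0:
        return stat, 0, 1.0
    return stat, df, float(stats.chi2.sf(stat, df))


def predict_fixed(
    model: MetaModel,
    region: str,
    time: float,
    hpp: float,
    hppclass: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-effect curve coefficients X beta with delta-method covariance.

    ``time`` is on the centered scale used in fitting.
    """
    x = model.design.row(hpp, region, time, hppclass)
    Xf = np.kron(x, np.eye(K))
    return Xf @ model.beta, Xf @ model.vcov_beta @ Xf.T


def blup(
    model: MetaModel,
    dataset: MetaDataset,
    hpp_override: float | None = None,
) -> dict[tuple[str, int], tuple[np.ndarray, np.ndarray]]:
    """Per-unit BLUP curves under an HPP scenario.

    Returns (city_id, subperiod) -> (coef, covariance).  Random effects are
    estimated once from the observed data and held fixed; only the
    fixed-effect HPP term changes between scenarios (``hpp_override=None``
    keeps the observed indicator; 0 gives the counterfactual).
    """
    ctx = LikelihoodContext(dataset, model.design)
    re = ctx.blups(model.beta, model.psi)
    out = {}
    cov = dataset.covariates
    for row in cov.itertuples():
        if row.city_id not in re:
            raise ValueError(f"blup: city {row.city_id} absent from the fitted dataset")
        hpp = row.hpp if hpp_override is None else hpp_override
        x = model.design.row(hpp, row.region, row.time, int(row.hppclass))
        Xf = np.kron(x, np.eye(K))
        b = re[row.city_id]
        coef = Xf @ model.beta + b[:K] + row.time * b[K:]
        vc = Xf @ model.vcov_beta @ Xf.T
        out[(row.city_id, row.subperiod)] = (coef, vc)
    return out
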