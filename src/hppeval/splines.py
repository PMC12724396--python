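"""Spline bases and the DLNM cross-basis.

Exposure-response is modelled with a quadratic B-spline (two internal knots
at the 50th and 90th percentile of the location's full-period warm-season
temperature distribution); the lag structure over 0..10 days with a natural
cubic spline with intercept and two internal knots equally spaced on the
log-lag scale.  Their tensor product is the cross-basis; collapsing the lag
dimension yields the overall cumulative exposure-response curve, expressed
as relative risk against the minimum-mortality temperature (MMT).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline


# ---------------------------------------------------------------------------
# basis specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VarBasisSpec:
    """Quadratic B-spline basis for the exposure dimension.

    ``internal_knots`` are on whatever scale the exposure is expressed on
    (degrees Celsius or empirical percentile).  The basis has
    ``len(internal_knots) + degree`` columns once the first column of the
    full family is dropped (no intercept); with the default two knots and
    degree 2 that is 4 columns.  Values outside the boundary knots are
    evaluated by clamping to the boundary (constant extrapolation), which
    keeps record temperatures from being wildly quadratically extrapolated.
    """

    internal_knots: tuple[float, ...]
    boundary: tuple[float, float]
    degree: int = 2

    def __post_init__(self) -> None:
        knots = np.asarray(self.internal_knots, dtype=float)
        lo, hi = self.boundary
        if not np.all(np.isfinite(knots)) or not np.isfinite([lo, hi]).all():
            raise ValueError("VarBasisSpec: knots must be finite")
        if np.any(np.diff(knots) <= 0):
            raise ValueError("VarBasisSpec: internal_knots must be strictly increasing")
        if not (lo < knots[0] and knots[-1] < hi):
            raise ValueError("VarBasisSpec: boundary must strictly enclose internal_knots")

    @property
    def dimension(self) -> int:
        return len(self.internal_knots) + self.degree


@dataclass(frozen=True)
class LagBasisSpec:
    """Natural cubic spline (with intercept) over the lag dimension.

    Knots sit strictly inside (0, max_lag); the natural constraint makes the
    basis linear beyond the boundary knots, which for the default
    ``max_lag=10`` and two log-spaced internal knots gives a 4-column basis.
    """

    max_lag: int = 10
    internal_knots: tuple[float, ...] = ()
    boundary: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.max_lag < 1:
            raise ValueError("LagBasisSpec: max_lag must be >= 1")
        knots = np.asarray(self.internal_knots, dtype=float)
        if knots.size and (np.any(np.diff(knots) <= 0) or knots[0] <= 0 or knots[-1] >= self.max_lag):
            raise ValueError("LagBasisSpec: internal_knots must be strictly increasing in (0, max_lag)")
        if self.boundary is None:
            object.__setattr__(self, "boundary", (0.0, float(self.max_lag)))

    @property
    def dimension(self) -> int:
        # intercept + linear + one column per internal knot under the
        # natural (second-derivative-zero) constraint
        return len(self.internal_knots) + 2


def log_lag_knots(max_lag: int = 10, n_knots: int = 2) -> np.ndarray:
    """Knot positions equally spaced on the log scale over the lag window.

    Lag 0 cannot be log-transformed, so the log grid runs over
    [log(1), log(max_lag)] and the knots are the ``n_knots`` interior
    equal divisions of that interval (the ``logknots`` convention).
    """
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    if n_knots >= max_lag:
        raise ValueError("n_knots must be < max_lag")
    grid = np.linspace(np.log(1.0), np.log(max_lag), n_knots + 2)
    return np.exp(grid[1:-1])


# ---------------------------------------------------------------------------
# basis evaluation
# ---------------------------------------------------------------------------

def bspline_basis(x: np.ndarray, spec: VarBasisSpec, intercept: bool = False) -> np.ndarray:
    """Evaluate the quadratic B-spline family at ``x`` (Cox-de Boor).

    Out-of-boundary values are clamped to the boundary knots.  With
    ``intercept=False`` (the default) the first column of the full family is
    dropped, leaving ``spec.dimension`` columns.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("bspline_basis: x must be finite")
    lo, hi = spec.boundary
    xc = np.clip(x, lo, hi)
    deg = spec.degree
    t = np.concatenate([[lo] * (deg + 1), spec.internal_knots, [hi] * (deg + 1)])
    out = BSpline.design_matrix(xc.ravel(), t, deg).toarray()
    if not intercept:
        out = out[:, 1:]
    return out


def natural_spline_basis(
    x: np.ndarray,
    internal_knots: np.ndarray,
    boundary: tuple[float, float],
    intercept: bool = True,
) -> np.ndarray:
    """Natural cubic spline basis (truncated-power construction).

    Linear beyond the boundary knots with zero second derivative there.
    Dimension is ``len(internal_knots) + 2`` with intercept, one fewer
    without.
    """
    x = np.asarray(x, dtype=float)
    knots = np.concatenate([[boundary[0]], np.asarray(internal_knots, float), [boundary[1]]])
    if np.any(np.diff(knots) <= 0):
        raise ValueError("natural_spline_basis: knots must be strictly increasing")
    K = len(knots)

    def d(k: int) -> np.ndarray:
        num = np.maximum(x - knots[k], 0.0) ** 3 - np.maximum(x - knots[K - 1], 0.0) ** 3
        return num / (knots[K - 1] - knots[k])

    cols = [np.ones_like(x), x]
    dlast = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - dlast)
    out = np.column_stack(cols)
    if not intercept:
        out = out[:, 1:]
    return out


def natural_lag_basis(lags: np.ndarray, spec: LagBasisSpec) -> np.ndarray:
    """Lag basis evaluated at (possibly non-integer) lags, with intercept."""
    return natural_spline_basis(
        np.asarray(lags, float), np.asarray(spec.internal_knots, float), spec.boundary, intercept=True
    )


def default_lag_spec(max_lag: int = 10, n_knots: int = 2) -> LagBasisSpec:
    return LagBasisSpec(max_lag=max_lag, internal_knots=tuple(log_lag_knots(max_lag, n_knots)))


# ---------------------------------------------------------------------------
# cross-basis
# ---------------------------------------------------------------------------

def cross_basis(
    x: np.ndarray, var_spec: VarBasisSpec, lag_spec: LagBasisSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Tensor-product cross-basis of a daily exposure series.

    Column (j, k), stored at index ``j * lag_dim + k``, holds
    sum_{l=0..L} B_var,j(x[t-l]) * B_lag,k(l).  Returns the (n, vdim*ldim)
    matrix and a boolean mask flagging rows with a complete lag window
    (the first ``max_lag`` rows are incomplete).
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    L = lag_spec.max_lag
    if n <= L:
        raise ValueError(f"cross_basis: series length {n} must exceed max_lag {L}")
    Bvar = bspline_basis(x, var_spec)                      # (n, vdim)
    Blag = natural_lag_basis(np.arange(L + 1), lag_spec)   # (L+1, ldim)
    vdim, ldim = Bvar.shape[1], Blag.shape[1]
    out = np.zeros((n, vdim * ldim))
    for lag in range(L + 1):
        contrib = Bvar[: n - lag] if lag else Bvar
        # outer product over basis dims, accumulated into lagged rows
        out[lag:] += np.einsum("nj,k->njk", contrib, Blag[lag]).reshape(n - lag, -1)
    complete = np.zeros(n, dtype=bool)
    complete[L:] = True
    return out, complete


# ---------------------------------------------------------------------------
# reduction to the overall cumulative curve
# ---------------------------------------------------------------------------

@dataclass
class ReducedCurve:
    """Overall cumulative exposure-response curve for one city x subperiod.

    ``coef``/``vcov`` live on the exposure basis defined by ``var_spec``
    (here: the location's warm-season percentile scale, so coefficient
    vectors are directly comparable across cities).  Predicted log-RR is
    centered so that it is zero at ``center`` (the MMT once assigned).
    ``percentiles`` maps percentile -> degrees Celsius for the location's
    full-period warm-season distribution, used to express the curve and its
    MMT on the absolute temperature scale.
    """

    coef: np.ndarray
    vcov: np.ndarray
    var_spec: VarBasisSpec
    center: float
    mmt: float | None = None          # degrees Celsius
    mmt_x: float | None = None        # on the basis (percentile) scale
    percentiles: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, float).ravel()
        self.vcov = np.asarray(self.vcov, float)
        d = self.var_spec.dimension
        if self.coef.shape != (d,) or self.vcov.shape != (d, d):
            raise ValueError("ReducedCurve: coef/vcov dimension mismatch with var_spec")
        if not np.allclose(self.vcov, self.vcov.T, atol=1e-8):
            raise ValueError("ReducedCurve: vcov must be symmetric")
        if np.linalg.eigvalsh(0.5 * (self.vcov + self.vcov.T)).min() < -1e-10 * max(
            1.0, np.abs(self.vcov).max()
        ):
            raise ValueError("ReducedCurve: vcov must be positive semi-definite")

    def basis(self, x: np.ndarray) -> np.ndarray:
        """Centered basis rows B(x) - B(center)."""
        x = np.atleast_1d(np.asarray(x, float))
        B = bspline_basis(x, self.var_spec)
        B0 = bspline_basis(np.array([self.center]), self.var_spec)
        return B - B0

    def log_rr(self, x: np.ndarray) -> np.ndarray:
        return self.basis(x) @ self.coef

    def log_rr_se(self, x: np.ndarray) -> np.ndarray:
        B = self.basis(x)
        return np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", B, self.vcov, B), 0.0))

    def recentered(self, center: float) -> "ReducedCurve":
        return ReducedCurve(
            coef=self.coef.copy(), vcov=self.vcov.copy(), var_spec=self.var_spec,
            center=float(center), mmt=self.mmt, mmt_x=self.mmt_x,
            percentiles=dict(self.percentiles),
        )

    def with_coef(self, coef: np.ndarray, vcov: np.ndarray | None = None) -> "ReducedCurve":
        return ReducedCurve(
            coef=np.asarray(coef, float),
            vcov=self.vcov if vcov is None else np.asarray(vcov, float),
            var_spec=self.var_spec, center=self.center, mmt=self.mmt,
            mmt_x=self.mmt_x, percentiles=dict(self.percentiles),
        )

    def to_dict(self) -> dict:
        return {
            "coef": self.coef.tolist(),
            "vcov": self.vcov.ravel().tolist(),
            "internal_knots": list(self.var_spec.internal_knots),
            "boundary": list(self.var_spec.boundary),
            "degree": self.var_spec.degree,
            "center": self.center,
            "mmt": self.mmt,
            "mmt_x": self.mmt_x,
            "percentiles": {str(k): v for k, v in self.percentiles.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReducedCurve":
        dim = len(d["coef"])
        return cls(
            coef=np.array(d["coef"], float),
            vcov=np.array(d["vcov"], float).reshape(dim, dim),
            var_spec=VarBasisSpec(
                internal_knots=tuple(d["internal_knots"]),
                boundary=tuple(d["boundary"]),
                degree=int(d["degree"]),
            ),
            center=float(d["center"]),
            mmt=d.get("mmt"),
            mmt_x=d.get("mmt_x"),
            percentiles={float(k): v for k, v in d.get("percentiles", {}).items()},
        )


def reduce_to_overall(
    full_coef: np.ndarray,
    full_vcov: np.ndarray,
    var_spec: VarBasisSpec,
    lag_spec: LagBasisSpec,
    center: float,
    percentiles: dict[float, float] | None = None,
) -> ReducedCurve:
    """Collapse the lag dimension of a fitted cross-basis.

    The reduced coefficients are (I_v (x) u^T) c where u is the vector of
    column sums of the lag basis over integer lags 0..max_lag; the covariance
    transforms by the same linear map on both sides.
    """
    full_coef = np.asarray(full_coef, float).ravel()
    full_vcov = np.asarray(full_vcov, float)
    vdim, ldim = var_spec.dimension, lag_spec.dimension
    if full_coef.shape != (vdim * ldim,) or full_vcov.shape != (vdim * ldim, vdim * ldim):
        raise ValueError("reduce_to_overall: coefficient dimensions do not match basis specs")
    u = natural_lag_basis(np.arange(lag_spec.max_lag + 1), lag_spec).sum(axis=0)  # (ldim,)
    M = np.kron(np.eye(vdim), u)                                                  # (vdim, vdim*ldim)
    coef = M @ full_coef
    vcov = M @ full_vcov @ M.T
    vcov = 0.5 * (vcov + vcov.T)
    return ReducedCurve(
        coef=coef, vcov=vcov, var_spec=var_spec, center=float(center),
        percentiles=percentiles or {},
    )


class EmpiricalPercentiles:
    """Monotone empirical percentile transform for one location.

    Built from the full-period warm-season temperatures; maps temperature to
    percentile (0..100) and back by linear interpolation between order
    statistics.  Used to express every location's exposure on a common
    percentile scale so spline coefficients can be pooled across climates.
    """

    def __init__(self, values: np.ndarray):
        values = np.sort(np.asarray(values, float))
        values = values[np.isfinite(values)]
        if values.size < 2 or values[0] == values[-1]:
            raise ValueError("EmpiricalPercentiles: need at least two distinct finite values")
        self._values = values
        n = values.size
        self._pp = 100.0 * (np.arange(1, n + 1) - 0.5) / n  # plotting positions

    def to_percentile(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        return np.interp(x, self._values, self._pp, left=0.0, right=100.0)

    def to_celsius(self, p: np.ndarray) -> np.ndarray:
        p = np.asarray(p, float)
        return np.interp(p, self._pp, self._values)

    def table(self, percentiles: np.ndarray | None = None) -> dict[float, float]:
        if percentiles is None:
            percentiles = np.concatenate([[0.0], np.arange(1.0, 100.0), [100.0]])
        return {float(p): float(v) for p, v in zip(percentiles, self.to_celsius(percentiles))}


def find_mmt(
    curve: ReducedCurve,
    search_range: tuple[float, float],
    grid_step: float = 0.05,
) -> tuple[float, float]:
    """Minimum of the overall cumulative curve on a fine grid.

    Returns (x at minimum, log-RR value there) on the curve's own exposure
    scale; ties break deterministically to the lowest x.
    """
    lo, hi = search_range
    if not lo < hi:
        raise ValueError("find_mmt: empty search range")
    grid = np.arange(lo, hi + 0.5 * grid_step, grid_step)
    if grid.size == 0:
        raise ValueError("find_mmt: empty grid")
    vals = curve.log_rr(grid)
    i = int(np.argmin(vals))  # argmin takes the first (lowest-x) minimum
    return float(grid[i]), float(vals[i])
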