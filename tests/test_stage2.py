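"""Meta-regression likelihood, fit, LRT, predictions and BLUPs.

The marginal likelihood is checked against a dense multivariate-normal
oracle assembled independently (explicit loops, scipy logpdf), and the
variance estimation against a closed-form 1-D random-effects ML oracle.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hppeval.stage2 import (
    FixedDesign,
    LikelihoodContext,
    MetaDataset,
    MODEL_TERMS,
    blup,
    fit_meta,
    lrt,
    marginal_loglik,
    predict_fixed,
    resolve_terms,
)

K = 4
REGIONS = ("Eastern", "Northern", "Southern", "Western")


def make_covariates(n_cities, n_sub, seed=0, hpp_switch=None):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_cities):
        sw = rng.integers(1, n_sub) if hpp_switch is None else hpp_switch
        for s in range(n_sub):
            rows.append(
                {
                    "city_id": f"c{i:03d}",
                    "subperiod": s,
                    "region": REGIONS[i % 4],
                    "hpp": int(s >= sw),
                    "time": 3.0 * (s - (n_sub - 1) / 2.0),
                    "hppclass": 1 + i % 3,
                }
            )
    return pd.DataFrame(rows)


def simulate_dataset(cov, beta, psi, S_scale=0.02, seed=0, terms=3):
    rng = np.random.default_rng(seed)
    design = FixedDesign(resolve_terms(terms), REGIONS)
    X = design.matrix(cov)
    U = len(cov)
    S = np.empty((U, K, K))
    theta = np.empty((U, K))
    re = {}
    for city in cov["city_id"].unique():
        re[city] = (
            rng.normal(0, np.sqrt(psi[:K])),
            rng.normal(0, np.sqrt(psi[K:])),
        )
    for u in range(U):
        A = rng.normal(size=(K, K)) * np.sqrt(S_scale / K)
        S[u] = A @ A.T + S_scale * np.eye(K)
        b0, b1 = re[cov["city_id"].iloc[u]]
        mean = np.kron(X[u], np.eye(K)) @ beta + b0 + cov["time"].iloc[u] * b1
        theta[u] = rng.multivariate_normal(mean, S[u])
    return MetaDataset(theta=theta, S=S, covariates=cov)


def dense_oracle_loglik(beta, psi, dataset, terms=3):
    """Independent dense construction of the marginal normal density."""
    design = FixedDesign(resolve_terms(terms), tuple(sorted(dataset.covariates["region"].unique())))
    X = design.matrix(dataset.covariates)
    total = 0.0
    for city, idx in dataset.covariates.groupby("city_id").indices.items():
        idx = np.sort(idx)
        n = len(idx)
        y = np.concatenate([dataset.theta[u] for u in idx])
        mean = np.concatenate([np.kron(X[u], np.eye(K)) @ beta for u in idx])
        V = np.zeros((K * n, K * n))
        t = dataset.covariates["time"].to_numpy()[idx]
        for a in range(n):
            V[K * a : K * a + K, K * a : K * a + K] += dataset.S[idx[a]]
            for b in range(n):
                for i in range(K):
                    V[K * a + i, K * b + i] += psi[i] + t[a] * t[b] * psi[K + i]
        total += stats.multivariate_normal.logpdf(y, mean=mean, cov=V)
    return total


class TestMarginalLoglik:
    def test_matches_dense_mvn_oracle(self, rng):
        cov = make_covariates(5, 3, seed=2)
        design = FixedDesign(MODEL_TERMS[3], REGIONS)
        beta = rng.normal(0, 0.1, K * design.q)
        psi = np.abs(rng.normal(0, 0.05, 2 * K))
        ds = simulate_dataset(cov, beta, psi, seed=3)
        ours = marginal_loglik(beta, psi, ds, 3)
        oracle = dense_oracle_loglik(beta, psi, ds, 3)
        assert np.isclose(ours, oracle, atol=1e-8)

    def test_psi_zero_single_unit_closed_form(self, rng):
        cov = make_covariates(4, 1, seed=0, hpp_switch=1)
        design = FixedDesign(MODEL_TERMS[3], REGIONS)
        beta = rng.normal(0, 0.1, K * design.q)
        ds = simulate_dataset(cov, beta, np.zeros(2 * K), seed=1)
        ours = marginal_loglik(beta, np.zeros(2 * K), ds, 3)
        X = design.matrix(cov)
        expected = sum(
            stats.multivariate_normal.logpdf(
                ds.theta[u], mean=np.kron(X[u], np.eye(K)) @ beta, cov=ds.S[u]
            )
            for u in range(4)
        )
        assert np.isclose(ours, expected, atol=1e-10)

    def test_duplicating_units_doubles_loglik(self, rng):
        cov = make_covariates(4, 2, seed=4)
        design = FixedDesign(MODEL_TERMS[3], REGIONS)
        beta = rng.normal(0, 0.1, K * design.q)
        psi = np.full(2 * K, 0.01)
        ds = simulate_dataset(cov, beta, psi, seed=5)
        # duplicate every city under new ids
        cov2 = pd.concat(
            [ds.covariates, ds.covariates.assign(city_id=ds.covariates["city_id"] + "_dup")],
            ignore_index=True,
        )
        ds2 = MetaDataset(
            theta=np.vstack([ds.theta, ds.theta]),
            S=np.vstack([ds.S, ds.S]),
            covariates=cov2,
        )
        assert np.isclose(
            marginal_loglik(beta, psi, ds2, 3), 2 * marginal_loglik(beta, psi, ds, 3), atol=1e-8
        )

    def test_negative_psi_rejected(self, rng):
        cov = make_covariates(2, 2)
        ds = simulate_dataset(cov, np.zeros(K * 9), np.zeros(2 * K), seed=0)
        with pytest.raises(ValueError):
            marginal_loglik(np.zeros(K * 9), -np.ones(2 * K), ds, 3)


def grid_search_1d_ml(y, s2, grid):
    """1-D random-effects meta-analysis ML oracle by profile grid search.

    For each candidate tau2: mu = weighted mean with weights 1/(s2+tau2);
    loglik = sum log N(y; mu, s2+tau2).  Returns (tau2_hat, mu_hat).
    """
    y = np.asarray(y)
    best = (None, None, -np.inf)
    for tau2 in grid:
        v = np.broadcast_to(np.asarray(s2 + tau2, float), y.shape)
        mu = np.sum(y / v) / np.sum(1.0 / v)
        ll = np.sum(stats.norm.logpdf(y, mu, np.sqrt(v)))
        if ll > best[2]:
            best = (tau2, mu, ll)
    return best


class TestOneDimensionalSpecialCase:
    def test_matches_grid_search_ml(self):
        # each of the 4 outcome coordinates carries the same scalar problem
        # (diagonal S, intercept-only fixed effects, one unit per city, all
        # times zero) so the multivariate ML must match the 1-D oracle
        rng = np.random.default_rng(8)
        n = 40
        s2 = 0.04
        tau2_true = 0.09
        yv = rng.normal(0.3, np.sqrt(tau2_true + s2), n)
        rows = [
            {"city_id": f"c{i:02d}", "subperiod": 0, "region": "Western",
             "hpp": 0, "time": 0.0, "hppclass": 1}
            for i in range(n)
        ]
        cov = pd.DataFrame(rows)
        theta = np.tile(yv[:, None], (1, K))
        S = np.tile((s2 * np.eye(K))[None], (n, 1, 1))
        ds = MetaDataset(theta=theta, S=S, covariates=cov)
        model = fit_meta(ds, ("1",))
        tau2_hat, mu_hat, _ = grid_search_1d_ml(yv, s2, np.arange(0.0, 0.5, 1e-5))
        assert np.allclose(model.psi[:K], tau2_hat, atol=1e-4)
        assert np.allclose(model.beta, mu_hat, atol=1e-5)


class TestFitMeta:
    def test_recovery_of_known_structure(self):
        rng = np.random.default_rng(10)
        cov = make_covariates(100, 8, seed=10)
        design = FixedDesign(MODEL_TERMS[3], REGIONS)
        beta_true = rng.normal(0, 0.08, K * design.q)
        psi_true = np.concatenate([np.full(K, 0.01), np.full(K, 0.0005)])
        ds = simulate_dataset(cov, beta_true, psi_true, seed=11)
        model = fit_meta(ds, 3)
        assert model.converged
        se = np.sqrt(np.diag(model.vcov_beta))
        assert np.all(np.abs(model.beta - beta_true) < 3.5 * se)
        assert np.all(np.abs(model.psi / psi_true - 1.0) < 0.5)

    def test_boundary_psi_zero(self):
        # when the claimed within-unit covariance dominates the observed
        # scatter, the variance MLE sits on the zero boundary and beta
        # collapses to fixed-effects GLS
        cov = make_covariates(30, 4, seed=12)
        design = FixedDesign(MODEL_TERMS[3], REGIONS)
        beta_true = np.zeros(K * design.q)
        ds = simulate_dataset(cov, beta_true, np.zeros(2 * K), seed=13)
        ds = MetaDataset(theta=ds.theta, S=ds.S * 3.0, covariates=ds.covariates)
        model = fit_meta(ds, 3)
        assert np.all(model.psi <= 1e-4)
        ctx = LikelihoodContext(ds, model.design)
        beta_gls, _, ll0 = ctx.profiled(np.zeros(2 * K))
        assert np.allclose(model.beta, beta_gls, atol=1e-6)
        assert np.isclose(model.loglik, ll0, atol=1e-5)

    def test_time_shift_moves_only_intercept_block(self):
        # at fixed psi with no time random effect, adding a constant to
        # Time is an exact reparameterization: GLS HPP/region/slope blocks
        # are unchanged and only intercept-type blocks absorb the shift
        cov = make_covariates(25, 5, seed=14)
        design = FixedDesign(MODEL_TERMS[3], REGIONS)
        rng = np.random.default_rng(14)
        beta_true = rng.normal(0, 0.05, K * design.q)
        psi0 = np.concatenate([np.full(K, 0.003), np.zeros(K)])
        ds = simulate_dataset(cov, beta_true, psi0, seed=15)
        cov_shift = ds.covariates.copy()
        cov_shift["time"] = cov_shift["time"] + 5.0
        ds2 = MetaDataset(theta=ds.theta, S=ds.S, covariates=cov_shift)
        b1, _, ll1 = LikelihoodContext(ds, design).profiled(psi0)
        b2, _, ll2 = LikelihoodContext(ds2, design).profiled(psi0)
        names = design.names
        for term in ("hpp", "time"):
            blk = slice(K * names.index(term), K * names.index(term) + K)
            assert np.allclose(b1[blk], b2[blk], atol=1e-7)
        assert np.isclose(ll1, ll2, atol=1e-6)

    def test_fewer_than_two_cities_rejected(self):
        cov = make_covariates(1, 3)
        ds = simulate_dataset(cov, np.zeros(K * 9), np.zeros(2 * K), seed=0)
        with pytest.raises(ValueError):
            fit_meta(ds, 3)


class TestLRT:
    def test_identical_models_statistic_zero(self):
        cov = make_covariates(10, 4, seed=20)
        ds = simulate_dataset(cov, np.zeros(K * 9), np.full(2 * K, 0.005), seed=21)
        m = fit_meta(ds, 3)
        m2 = fit_meta(ds, tuple(t for t in m.terms if t != "hpp"))
        # reduced vs itself -> would not be strictly nested; compare full/full
        stat, df, p = lrt(m, m2)
        assert df == K  # one 4-dim coefficient block
        assert stat >= 0
        with pytest.raises(ValueError):
            lrt(m, m)  # not strictly nested

    def test_non_nested_rejected(self):
        cov = make_covariates(10, 4, seed=22)
        ds = simulate_dataset(cov, np.zeros(K * 9), np.full(2 * K, 0.005), seed=23)
        m4 = fit_meta(ds, ("1", "hpp"))
        m5 = fit_meta(ds, ("1", "region"))
        with pytest.raises(ValueError):
            lrt(m4, m5)


@pytest.fixture(scope="module")
def fitted():
    cov = make_covariates(30, 5, seed=30)
    rng = np.random.default_rng(30)
    design = FixedDesign(MODEL_TERMS[3], REGIONS)
    beta_true = rng.normal(0, 0.06, K * design.q)
    psi_true = np.concatenate([np.full(K, 0.008), np.full(K, 0.0004)])
    ds = simulate_dataset(cov, beta_true, psi_true, seed=31)
    return ds, fit_meta(ds, 3)


class TestPredictAndBlup:

    def test_hpp_toggle_shifts_by_hpp_block(self, fitted):
        ds, model = fitted
        c0, _ = predict_fixed(model, "Western", 1.0, 0.0)
        c1, _ = predict_fixed(model, "Western", 1.0, 1.0)
        names = model.design.names
        blockidx = names.index("hpp")
        assert np.allclose(c1 - c0, model.beta[K * blockidx : K * blockidx + K], atol=1e-12)

    def test_reference_region_center_time_is_intercept(self, fitted):
        ds, model = fitted
        ref = model.design.region_levels[0]
        c, _ = predict_fixed(model, ref, 0.0, 0.0)
        assert np.allclose(c, model.beta[:K], atol=1e-12)

    def test_unseen_level_rejected(self, fitted):
        ds, model = fitted
        with pytest.raises(ValueError):
            predict_fixed(model, "Atlantis", 0.0, 0.0)

    def test_delta_covariance_matches_sampling(self, fitted):
        ds, model = fitted
        x = model.design.row(1.0, "Western", 2.0, 1)
        Xf = np.kron(x, np.eye(K))
        _, cov_pred = predict_fixed(model, "Western", 2.0, 1.0, 1)
        rng = np.random.default_rng(99)
        draws = rng.multivariate_normal(model.beta, model.vcov_beta, size=200_000) @ Xf.T
        emp = np.cov(draws.T)
        scale = np.sqrt(np.outer(np.diag(cov_pred), np.diag(cov_pred)))
        assert np.all(np.abs(emp - cov_pred) / scale < 0.02)

    def test_psi_zero_blup_equals_fixed_prediction(self):
        cov = make_covariates(6, 3, seed=40)
        rng = np.random.default_rng(40)
        design = FixedDesign(MODEL_TERMS[3], REGIONS)
        beta_true = rng.normal(0, 0.05, K * design.q)
        ds = simulate_dataset(cov, beta_true, np.zeros(2 * K), seed=41)
        model = fit_meta(ds, 3)
        model.psi = np.zeros(2 * K)
        preds = blup(model, ds)
        for row in ds.covariates.itertuples():
            coef, _ = preds[(row.city_id, row.subperiod)]
            fixed, _ = predict_fixed(model, row.region, row.time, row.hpp, int(row.hppclass))
            assert np.allclose(coef, fixed, atol=0.0)

    def test_tiny_within_variance_blup_approaches_theta(self):
        cov = make_covariates(6, 1, seed=42, hpp_switch=1)
        rng = np.random.default_rng(42)
        design = FixedDesign(MODEL_TERMS[3], REGIONS)
        beta_true = rng.normal(0, 0.05, K * design.q)
        ds = simulate_dataset(cov, beta_true, np.full(2 * K, 0.01), seed=43)
        ds.S[:] = np.eye(K)[None] * 1e-10
        model = fit_meta(ds, ("1",))
        preds = blup(model, ds)
        for u, row in enumerate(ds.covariates.itertuples()):
            coef, _ = preds[(row.city_id, row.subperiod)]
            assert np.allclose(coef, ds.theta[u], atol=1e-6)

    def test_factual_minus_counterfactual_is_hpp_block(self, fitted):
        ds, model = fitted
        fact = blup(model, ds)
        cf = blup(model, ds, hpp_override=0.0)
        names = model.design.names
        hpp_block = model.beta[K * names.index("hpp") : K * names.index("hpp") + K]
        for row in ds.covariates.itertuples():
            d = fact[(row.city_id, row.subperiod)][0] - cf[(row.city_id, row.subperiod)][0]
            expected = hpp_block * row.hpp
            assert np.allclose(d, expected, atol=1e-12)

    def test_shrinkage_ordering_diagonal_case(self):
        # one unit per city, diagonal S, time 0: each BLUP coordinate lies
        # between the unit estimate and the fixed-effect prediction
        cov = make_covariates(20, 1, seed=44, hpp_switch=1)
        rng = np.random.default_rng(44)
        theta = rng.normal(0.2, 0.15, size=(20, K))
        S = np.tile((0.02 * np.eye(K))[None], (20, 1, 1))
        ds = MetaDataset(theta=theta, S=S, covariates=cov)
        model = fit_meta(ds, ("1",))
        preds = blup(model, ds)
        fixed = model.beta[:K]
        for u, row in enumerate(ds.covariates.itertuples()):
            coef, _ = preds[(row.city_id, row.subperiod)]
            lo = np.minimum(theta[u], fixed) - 1e-10
            hi = np.maximum(theta[u], fixed) + 1e-10
            assert np.all(coef >= lo) and np.all(coef <= hi)
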