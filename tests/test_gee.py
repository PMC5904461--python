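"""Spatial GEEs: working correlation structures, GLS oracle, QIC."""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg
from scipy.spatial.distance import pdist, squareform

import latreg as lr
from latreg.autocorr import lag1_moran
from latreg.gee import _make_blocks, fit_power_base
from .conftest import gaussian_griddata, grid_coords


def _design(data, names):
    cols = [np.ones(data.n)] + [data.covariates[c].to_numpy() for c in names]
    return np.column_stack(cols)


class TestIndependence:
    @pytest.mark.parametrize("family", ["gaussian", "binomial", "poisson"])
    def test_equals_glm(self, family):
        rng = np.random.default_rng(8)
        coords = grid_coords(10)
        x1, x2 = rng.standard_normal((2, 100))
        eta = 0.3 + 0.8 * x1 - 0.5 * x2
        if family == "gaussian":
            y = eta + rng.standard_normal(100)
        elif family == "poisson":
            y = rng.poisson(np.exp(eta)).astype(float)
        else:
            y = rng.binomial(1, 1 / (1 + np.exp(-eta))).astype(float)
        data = lr.GridData(coords, y, pd.DataFrame({"x1": x1, "x2": x2}),
                           response_name="y")
        glm = lr.fit_glm(data, "y ~ x1 + x2", family)
        gee = lr.fit_gee(data, "y ~ x1 + x2", family, corstr="independence")
        np.testing.assert_allclose(gee.beta, glm.beta, atol=1e-8)
        np.testing.assert_allclose(gee.se, glm.se, atol=1e-8)

    def test_sandwich_matches_robust_oracle(self):
        """Independence sandwich equals the textbook heteroscedasticity-
        robust covariance (X'X)^-1 X'diag(e^2)X (X'X)^-1 on gaussian data
        with heteroscedastic errors."""
        rng = np.random.default_rng(2)
        coords = grid_coords(10)
        x = rng.standard_normal(100)
        y = 1.0 + 2.0 * x + np.abs(x) * rng.standard_normal(100)
        data = lr.GridData(coords, y, pd.DataFrame({"x": x}),
                           response_name="y")
        gee = lr.fit_gee(data, "y ~ x", "gaussian", corstr="independence")
        X = _design(data, ["x"])
        e = y - X @ gee.beta
        XtXi = linalg.inv(X.T @ X)
        oracle = XtXi @ (X.T * e**2) @ X @ XtXi
        np.testing.assert_allclose(gee.cov_robust, oracle, atol=1e-10)


class TestFixed:
    def test_forced_identity_correlation_equals_glm(self, musdata):
        f = "musculus ~ pollution + exposure"
        glm = lr.fit_glm(musdata, f, "poisson")
        gee = lr.fit_gee(musdata, f, "poisson", corstr="fixed",
                         working_R=np.eye(musdata.n))
        np.testing.assert_allclose(gee.beta, glm.beta, atol=1e-8)

    def test_known_R_reproduces_gls(self):
        """Gaussian GEE with a frozen working correlation equals the
        closed-form GLS estimate (X'V^-1 X)^-1 X'V^-1 y."""
        rng = np.random.default_rng(4)
        coords = grid_coords(10)
        D = squareform(pdist(coords))
        R = 0.6**D
        L = linalg.cholesky(R, lower=True)
        x = rng.standard_normal(100)
        y = 1.0 - 2.0 * x + L @ rng.standard_normal(100)
        data = lr.GridData(coords, y, pd.DataFrame({"x": x}),
                           response_name="y")
        gee = lr.fit_gee(data, "y ~ x", "gaussian", corstr="fixed",
                         working_R=R)
        X = _design(data, ["x"])
        Ri = linalg.inv(R)
        beta_gls = linalg.solve(X.T @ Ri @ X, X.T @ Ri @ y)
        np.testing.assert_allclose(gee.beta, beta_gls, atol=1e-8)

    def test_power_base_recovered_from_exact_correlogram(self):
        from latreg.autocorr import ACProfile

        d = np.arange(10.0)
        prof = ACProfile(bin_centers=d + 0.5, moran_i=0.55**d, lim1=0.0,
                        lim2=1.0, dmax=10)
        assert fit_power_base(prof) == pytest.approx(0.55, abs=1e-4)

    def test_normalized_residuals_whiten_true_correlation(self):
        """With the TRUE simulation correlation as working R, normalised
        Pearson residuals have lag-1 Moran's I centred at the white-noise
        null (checked over seeded replicates within 3 SE)."""
        coords = grid_coords(10)
        D = squareform(pdist(coords))
        R = 0.5**D
        L = linalg.cholesky(R, lower=True)
        vals = []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(100)
            y = 1.0 + x + L @ rng.standard_normal(100)
            data = lr.GridData(coords, y, pd.DataFrame({"x": x}),
                               response_name="y")
            gee = lr.fit_gee(data, "y ~ x", "gaussian", corstr="fixed",
                             working_R=R)
            vals.append(lag1_moran(coords, gee.resid_normalized))
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - (-1 / 99)) < 3 * se

    def test_large_n_guard(self):
        side = 150  # 22500 cells > fixed-structure limit
        coords = grid_coords(side)
        rng = np.random.default_rng(0)
        data = lr.GridData(coords, rng.standard_normal(side**2),
                           pd.DataFrame({"x": rng.standard_normal(side**2)}),
                           response_name="y")
        with pytest.raises(ValueError, match="clustered"):
            lr.fit_gee(data, "y ~ x", "gaussian", corstr="fixed")


class TestClustered:
    def test_blocks_tile_the_grid(self):
        coords = grid_coords(7)  # 7 not divisible by 3: partial tiles
        blocks = _make_blocks(coords, 3)
        sizes = sorted(len(b) for b in blocks)
        assert sum(sizes) == 49
        assert max(sizes) == 9 and min(sizes) >= 1
        flat = np.sort(np.concatenate(blocks))
        np.testing.assert_array_equal(flat, np.arange(49))

    @pytest.mark.parametrize("corstr", ["exchangeable", "quadratic"])
    def test_recovers_within_block_correlation(self, corstr):
        """Strongly correlated block noise yields clearly positive
        moment-estimated within-block parameters."""
        rng = np.random.default_rng(9)
        coords = grid_coords(12)
        D = squareform(pdist(coords))
        R = 0.7**D
        L = linalg.cholesky(R, lower=True)
        x = rng.standard_normal(144)
        y = 1.0 + x + 2.0 * (L @ rng.standard_normal(144))
        data = lr.GridData(coords, y, pd.DataFrame({"x": x}),
                           response_name="y")
        gee = lr.fit_gee(data, "y ~ x", "gaussian", corstr=corstr, cluster=3)
        corr = gee.meta["correlation"]
        assert gee.converged
        alphas = np.array(list(corr.alphas.values()))
        assert np.all(alphas > 0.1)
        if corstr == "quadratic":
            # one parameter per distinct within-tile distance
            dists = sorted(corr.alphas)
            assert dists[0] == pytest.approx(1.0)
            assert len(dists) == 5  # 1, sqrt2, 2, sqrt5, 2*sqrt2 in a 3x3 tile

    def test_bad_cluster_size_rejected(self, musdata):
        with pytest.raises(ValueError, match="cluster"):
            lr.fit_gee(musdata, "musculus ~ pollution", "poisson",
                       corstr="exchangeable", cluster=5)


class TestQIC:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_definitional_formula(self, seed):
        """QIC recomputed from its definition -2Q + 2 tr(Omega^-1 V_r) by an
        independent code path."""
        ds = lr.make_musdata_like(lr.SimConfig(seed=seed, grid_side=12))
        f = "musculus ~ pollution + exposure"
        gee = lr.fit_gee(ds.data, f, "poisson", corstr="fixed")
        glm = lr.fit_glm(ds.data, f, "poisson")
        y = ds.data.response
        mu = gee.fitted
        q = float(np.sum(y * np.log(mu) - mu))  # poisson quasi-loglik, phi=1
        trace = float(np.trace(linalg.solve(glm.cov_naive, gee.cov_robust)))
        assert gee.ic["qic"] == pytest.approx(-2 * q + 2 * trace, abs=1e-8)

    def test_penalty_is_2k_when_sandwich_equals_naive(self, musdata):
        f = "musculus ~ pollution + exposure"
        gee = lr.fit_gee(musdata, f, "poisson", corstr="fixed")
        glm = lr.fit_glm(musdata, f, "poisson")
        gee.cov_robust = glm.cov_naive.copy()
        qic = lr.qic_calc(gee, glm)
        q = gee.family.quasi_loglik(musdata.response, gee.fitted, 1.0)
        assert qic == pytest.approx(-2 * q + 2 * 3, abs=1e-8)

    def test_stable_under_translation(self, musdata):
        f = "musculus ~ pollution + exposure"
        a = lr.fit_gee(musdata, f, "poisson", corstr="fixed")
        moved = lr.GridData(musdata.coords + [7, 13], musdata.response,
                            musdata.covariates, response_name="musculus")
        b = lr.fit_gee(moved, f, "poisson", corstr="fixed")
        assert a.ic["qic"] == pytest.approx(b.ic["qic"], rel=1e-8)


class TestPredictAndSummary:
    def test_predict_round_trip_and_errors(self, musdata):
        f = "musculus ~ pollution + exposure"
        gee = lr.fit_gee(musdata, f, "poisson", corstr="fixed")
        np.testing.assert_allclose(lr.predict_gee(gee, musdata), gee.fitted,
                                   atol=1e-12)
        inter = lr.fit_gee(musdata, "musculus ~ 1", "poisson",
                           corstr="independence")
        assert np.ptp(lr.predict_gee(inter, musdata)) < 1e-12
        broken = lr.GridData(musdata.coords, musdata.response,
                             musdata.covariates[["pollution"]],
                             response_name="musculus")
        with pytest.raises(KeyError):
            lr.predict_gee(gee, broken)

    def test_summary_reports_structure_parameters(self, musdata):
        f = "musculus ~ pollution + exposure"
        gee = lr.fit_gee(musdata, f, "poisson", corstr="fixed")
        text = lr.summary_gee(gee, print_autocor_pars=True)
        for token in ("QIC", "pollution", "fixed", "a ="):
            assert token in text
        ex = lr.fit_gee(musdata, f, "poisson", corstr="exchangeable")
        assert "Within-block" in lr.summary_gee(ex, print_autocor_pars=True)
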