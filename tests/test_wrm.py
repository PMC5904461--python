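"""Wavelet-revised models and scale-specific multiresolution regression."""

import numpy as np
import pandas as pd
import pytest

import latreg as lr
from latreg.autocorr import lag1_moran
from latreg.grid import PadSpec
from latreg.wavelets import WaveletSpec, extract_component, filter_highpass
from .conftest import grid_coords


class TestGaussianClosedForm:
    def test_equals_ols_on_filtered_variables(self, gauss_data):
        """Gaussian WRM slopes are the OLS slopes of the high-pass-filtered
        response on the high-pass-filtered covariates."""
        fit = lr.fit_wrm(gauss_data, "y ~ x1 + x2", "gaussian", level=1,
                         moran=None)
        coords = gauss_data.coords
        yf = filter_highpass(gauss_data.response, coords, level=1)
        x1f = filter_highpass(gauss_data.covariates["x1"].to_numpy(), coords, 1)
        x2f = filter_highpass(gauss_data.covariates["x2"].to_numpy(), coords, 1)
        Xf = np.column_stack([np.ones(gauss_data.n), x1f, x2f])
        beta_ols, *_ = np.linalg.lstsq(Xf, yf, rcond=None)
        np.testing.assert_allclose(fit.beta[1:], beta_ols[1:], atol=1e-10)

    def test_response_shift_moves_only_intercept(self, gauss_data):
        base = lr.fit_wrm(gauss_data, "y ~ x1 + x2", "gaussian", moran=None)
        shifted = lr.GridData(
            gauss_data.coords, gauss_data.response + 37.0,
            gauss_data.covariates, response_name="y",
        )
        other = lr.fit_wrm(shifted, "y ~ x1 + x2", "gaussian", moran=None)
        np.testing.assert_allclose(base.beta[1:], other.beta[1:], atol=1e-8)
        assert other.beta[0] - base.beta[0] == pytest.approx(37.0, abs=1e-6)


class TestWmrrIdentity:
    @pytest.mark.parametrize("family", ["gaussian", "poisson"])
    def test_wrm_level1_equals_wmrr_scale1_detail(self, family, musdata):
        data = musdata
        if family == "gaussian":
            data = lr.GridData(data.coords, np.log1p(data.response),
                               data.covariates, response_name="musculus")
        f = "musculus ~ pollution + exposure"
        wrm = lr.fit_wrm(data, f, family, level=1, moran=None)
        wmrr = lr.scale_wmrr(data, f, family, scale=1, detail=True)
        np.testing.assert_allclose(wrm.beta, wmrr.beta, atol=1e-8)
        np.testing.assert_allclose(wrm.fitted, wmrr.fitted, atol=1e-8)

    def test_wmrr_recovers_scale_specific_signal(self):
        """Response built purely from the level-2 detail of x: the scale-2
        regression recovers the generating slope, the scale-3 one does not."""
        rng = np.random.default_rng(5)
        coords = grid_coords(16)
        x = rng.standard_normal(256)
        x_d2 = extract_component(x, coords, scale=2, detail=True)
        y = 3.0 * x_d2 + 0.05 * rng.standard_normal(256)
        data = lr.GridData(coords, y, pd.DataFrame({"x": x}),
                           response_name="y")
        fit2 = lr.scale_wmrr(data, "y ~ x", "gaussian", scale=2)
        fit3 = lr.scale_wmrr(data, "y ~ x", "gaussian", scale=3)
        assert fit2.beta[1] == pytest.approx(3.0, abs=0.1)
        assert abs(fit3.beta[1]) < 0.5

    def test_full_depth_smooth_regression_degenerate(self):
        # on a fully observed dyadic square the level-J haar smooth of every
        # variable is the constant grand-mean field: collinear with the
        # intercept
        rng = np.random.default_rng(1)
        coords = grid_coords(16)
        data = lr.GridData(coords, rng.standard_normal(256),
                           pd.DataFrame({"x1": rng.standard_normal(256)}),
                           response_name="y")
        with pytest.raises(ValueError, match="collinear|rank"):
            lr.scale_wmrr(data, "y ~ x1", "gaussian", scale=4, detail=False)


class TestAutocorrelationReduction:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_wrm_residual_ac_below_glm(self, seed):
        """The motivating pattern: on confounded Poisson lattices the WRM's
        level-1 residual Moran's I magnitude is below the GLM's."""
        ds = lr.make_musdata_like(lr.SimConfig(seed=seed))
        f = "musculus ~ pollution + exposure"
        glm = lr.fit_glm(ds.data, f, "poisson")
        wrm = lr.fit_wrm(ds.data, f, "poisson", level=1, moran=None)
        i_glm = lag1_moran(ds.data.coords, glm.resid_pearson)
        i_wrm = lag1_moran(ds.data.coords, wrm.resid_pearson)
        assert abs(i_wrm) < abs(i_glm)

    def test_white_noise_wrm_matches_glm_slopes(self):
        """No spatial structure: filtering removes (almost) nothing that
        matters, so WRM and GLM slope estimates agree on average."""
        diffs = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            coords = grid_coords(12)
            x = rng.standard_normal(144)
            y = rng.poisson(np.exp(0.3 + 0.4 * x)).astype(float)
            data = lr.GridData(coords, y, pd.DataFrame({"x": x}),
                               response_name="y")
            glm = lr.fit_glm(data, "y ~ x", "poisson")
            wrm = lr.fit_wrm(data, "y ~ x", "poisson", moran=None)
            diffs.append(wrm.beta[1] - glm.beta[1])
        diffs = np.asarray(diffs)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) < max(3 * se, 0.02)


class TestPredictAndSummary:
    def test_predict_on_training_matches_fitted(self, musdata):
        fit = lr.fit_wrm(musdata, "musculus ~ pollution + exposure",
                         "poisson", moran=None)
        np.testing.assert_allclose(lr.predict_wrm(fit, musdata), fit.fitted,
                                   atol=1e-12)

    def test_intercept_only_predicts_constant(self, musdata):
        fit = lr.fit_wrm(musdata, "musculus ~ 1", "poisson", moran=None)
        pred = lr.predict_wrm(fit, musdata)
        assert np.ptp(pred) < 1e-12

    def test_prediction_ignores_coordinates(self, musdata):
        fit = lr.fit_wrm(musdata, "musculus ~ pollution + exposure",
                         "poisson", moran=None)
        moved = lr.GridData(musdata.coords + [50, -3], musdata.response,
                            musdata.covariates, response_name="musculus")
        np.testing.assert_allclose(lr.predict_wrm(fit, moved),
                                   lr.predict_wrm(fit, musdata), atol=0)

    def test_missing_column_raises(self, musdata):
        fit = lr.fit_wrm(musdata, "musculus ~ pollution + exposure",
                         "poisson", moran=None)
        broken = lr.GridData(musdata.coords, musdata.response,
                             musdata.covariates[["pollution"]],
                             response_name="musculus")
        with pytest.raises(KeyError):
            lr.predict_wrm(fit, broken)

    def test_summary_formats(self, musdata):
        f = "musculus ~ pollution + exposure"
        full = lr.fit_wrm(musdata, f, "poisson", level=1,
                          spec=WaveletSpec("d4", "dwt"),
                          pad=PadSpec("mean", 1.1))
        text = lr.summary_wrm(full)
        for token in ("pollution", "exposure", "AIC", "AICc", "d4",
                      "padzone = 1.1", "Moran"):
            assert token in text
        inter = lr.fit_wrm(musdata, "musculus ~ 1", "poisson", moran=None)
        assert "(Intercept)" in lr.summary_wrm(inter)
        bad = lr.fit_wrm(musdata, f, "poisson", moran=None)
        bad.converged = False
        assert "did not converge" in lr.summary_wrm(bad)

    def test_level_below_one_rejected(self, musdata):
        with pytest.raises(ValueError):
            lr.fit_wrm(musdata, "musculus ~ pollution", "poisson", level=0)
        with pytest.raises(ValueError):
            lr.scale_wmrr(musdata, "musculus ~ pollution", "poisson", scale=0)
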