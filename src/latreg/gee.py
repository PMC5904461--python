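"""Generalised estimating equations for two-dimensional lattice data.

The variance of the response is replaced by a working variance-covariance
matrix ``V = phi * A^{1/2} R A^{1/2}`` that encodes spatial dependence.
Four working correlation structures are supported:

* ``independence`` — R is the identity: identical to the GLM.
* ``fixed`` — an isotropic power function ``R_ij = a^{d_ij}`` whose base is
  adapted once to the residual Moran's I correlogram of the GLM and then
  frozen during the Fisher-scoring iteration.
* ``exchangeable`` / ``quadratic`` — the grid is tiled into
  ``cluster x cluster`` blocks and V is block diagonal; within-block
  correlation parameters are moment-estimated, either all equal
  (exchangeable) or equal at equal within-block distance (quadratic).

GEE fits report normalised Pearson residuals ``r* = L^{-1} r`` (L the
Cholesky factor of the working correlation), used to check how far the
autocorrelation was removed, and a QIC score in place of AIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import pdist, squareform

from .autocorr import acfft
from .families import get_family
from .formula import parse_formula
from .glm import (
    DEFAULT_MORAN,
    ModelFit,
    fit_glm,
    pearson_residuals,
    qic_calc,
)

_MAX_FIXED_N = 20_000


@dataclass
class CorrelationModel:
    """Fitted working correlation structure of a spatial GEE."""

    corstr: str
    a: float | None = None
    cluster: int | None = None
    alphas: dict = field(default_factory=dict)
    blocks: list | None = None  # list of observation-index arrays
    R_blocks: list | None = None  # working correlation per block


def fit_power_base(ac_profile, dmax: int | None = None) -> float:
    """Least-squares fit of rho(d) = a^d to a Moran's I correlogram.

    Bin-centre distances 1..dmax are used as the distance grid.  The base is
    constrained to [0, 0.99]; if the fit fails the lag-1 autocorrelation
    (clamped to the same range) is used instead.
    """
    vals = np.asarray(ac_profile.moran_i, dtype=float)
    if dmax is not None:
        vals = vals[:dmax]
    h = ac_profile.lim2 - ac_profile.lim1
    # bins are labelled by their left edge: on a lattice the left edge is
    # the dominant (and smallest) distance inside each unit-width bin
    d = ac_profile.lim1 + h * np.arange(vals.size, dtype=float)
    ok = np.isfinite(vals) & (d > 0)
    d, vals = d[ok], vals[ok]
    fallback = float(np.clip(vals[0] if vals.size else 0.0, 0.0, 0.99))
    if vals.size < 2:
        return fallback
    try:
        res = minimize_scalar(
            lambda a: float(np.sum((vals - a**d) ** 2)),
            bounds=(0.0, 0.99),
            method="bounded",
        )
        if not res.success:
            return fallback
        a = float(res.x)
    except Exception:
        return fallback
    if not (0.0 <= a < 1.0):
        warnings.warn("power base outside [0, 1); clamped to [0, 0.99]")
        a = float(np.clip(a, 0.0, 0.99))
    return a


def _ensure_pd(R: np.ndarray) -> np.ndarray:
    """Cholesky-test a correlation matrix, ridging it if needed."""
    ridge = 0.0
    for _ in range(40):
        try:
            linalg.cholesky(R + ridge * np.eye(R.shape[0]), lower=True)
            break
        except linalg.LinAlgError:
            ridge = max(ridge * 10.0, 1e-10)
    else:
        raise ValueError("working correlation cannot be made positive definite")
    if ridge > 0.0:
        warnings.warn("working correlation ridged to positive definiteness")
        R = (R + ridge * np.eye(R.shape[0])) / (1.0 + ridge)
    return R


def _make_blocks(coords: np.ndarray, cluster: int) -> list[np.ndarray]:
    """Axis-aligned cluster x cluster tiles anchored at the grid origin.

    Observations falling in partially observed tiles simply form smaller
    blocks.
    """
    mins = coords.min(axis=0)
    tiles = (coords - mins) // cluster
    keys = tiles[:, 0] * (tiles[:, 1].max() + 1) + tiles[:, 1]
    blocks = []
    for key in np.unique(keys):
        blocks.append(np.flatnonzero(keys == key))
    return blocks


def _block_distance_classes(coords: np.ndarray, blocks) -> list[np.ndarray]:
    """Pairwise within-block distances, rounded for use as class keys."""
    out = []
    for idx in blocks:
        if idx.size > 1:
            out.append(np.round(squareform(pdist(coords[idx])), 9))
        else:
            out.append(np.zeros((1, 1)))
    return out


def _scoring_step(X, y, family, mu, R_blocks, blocks, phi):
    """One Fisher-scoring update; returns (delta_beta, Omega=D'V^-1 D, u)."""
    gprime = family.d_link(mu)
    a_sd = np.sqrt(family.variance(mu))
    D = X / gprime[:, None]  # diag(dmu/deta) X for canonical setups
    r = y - mu
    p = X.shape[1]
    omega = np.zeros((p, p))
    u = np.zeros(p)
    for idx, R in zip(blocks, R_blocks):
        Db = D[idx]
        sd = a_sd[idx]
        Vb = (sd[:, None] * R * sd[None, :]) * phi
        c, low = linalg.cho_factor(Vb, lower=True)
        ViD = linalg.cho_solve((c, low), Db)
        omega += Db.T @ ViD
        u += ViD.T @ r[idx]
    delta = linalg.solve(omega, u, assume_a="sym")
    return delta, omega, u


def _sandwich(X, y, family, mu, R_blocks, blocks, phi, omega, groups):
    """Robust covariance Omega^{-1} M Omega^{-1}.

    The score splits over observations as ``g = sum_i d_i u_i`` with
    ``u = V^{-1}(y - mu)``; the meat M sums outer products of the score
    pieces pooled over ``groups``.  Groups are single observations under
    independence, the correlation blocks for clustered structures, and
    cluster-size tiles for the dense fixed structure (where the whole-sample
    score is exactly zero at the solution, so pooling everything would give
    a degenerate, identically zero sandwich).
    """
    gprime = family.d_link(mu)
    a_sd = np.sqrt(family.variance(mu))
    D = X / gprime[:, None]
    r = y - mu
    p = X.shape[1]
    u = np.empty_like(r)
    for idx, R in zip(blocks, R_blocks):
        sd = a_sd[idx]
        Vb = (sd[:, None] * R * sd[None, :]) * phi
        c, low = linalg.cho_factor(Vb, lower=True)
        u[idx] = linalg.cho_solve((c, low), r[idx])
    scores = D * u[:, None]
    meat = np.zeros((p, p))
    for idx in groups:
        g = scores[idx].sum(axis=0)
        meat += np.outer(g, g)
    bread = linalg.inv(omega)
    return bread @ meat @ bread


def _normalized_residuals(r_pearson, R_blocks, blocks):
    out = np.empty_like(r_pearson)
    for idx, R in zip(blocks, R_blocks):
        L = linalg.cholesky(R, lower=True)
        out[idx] = linalg.solve_triangular(L, r_pearson[idx], lower=True)
    return out


def fit_gee(
    data,
    formula,
    family,
    corstr: str = "fixed",
    cluster: int = 3,
    scale_fix: bool = False,
    moran: dict | None = None,
    working_R: np.ndarray | None = None,
    tol: float = 1e-6,
    maxit: int = 50,
) -> ModelFit:
    """Fit a spatial GEE; see the module docstring for the structures.

    ``working_R`` freezes an explicit correlation matrix (implies the fixed
    algorithm without the correlogram-adaptation step) — mainly useful for
    validation against closed-form GLS.
    """
    if isinstance(formula, str):
        formula = parse_formula(formula)
    family = get_family(family)
    if moran is None:
        moran = dict(DEFAULT_MORAN)
    if corstr not in ("independence", "fixed", "exchangeable", "quadratic"):
        raise ValueError(f"unknown corstr {corstr!r}")
    if cluster not in (2, 3, 4):
        raise ValueError("cluster size must be 2, 3 or 4")

    y = data.variable(formula.response)
    coords = data.coords
    n = y.size

    glm_fit = fit_glm(data, formula, family)
    ac_glm = acfft(coords, glm_fit.resid_pearson, **moran)

    X, names = formula.design_matrix(data)
    p = X.shape[1]

    corr = CorrelationModel(corstr=corstr)
    if corstr == "independence":
        beta = glm_fit.beta
        mu = glm_fit.fitted
        blocks = [np.array([i]) for i in range(n)]
        R_blocks = [np.eye(1) for _ in range(n)]
        sandwich_groups = blocks
        phi = 1.0 if scale_fix else glm_fit.dispersion
        if family.name == "gaussian":
            phi = glm_fit.dispersion
        cov_naive = glm_fit.cov_naive
        omega = linalg.inv(cov_naive)
        converged, it = glm_fit.converged, glm_fit.n_iter
    else:
        if corstr == "fixed":
            if n > _MAX_FIXED_N:
                raise ValueError(
                    f"corstr='fixed' needs an {n}x{n} correlation matrix; "
                    "use a clustered structure ('exchangeable' or "
                    "'quadratic') for data sets this large"
                )
            D = squareform(pdist(coords))
            if working_R is not None:
                R = _ensure_pd(np.asarray(working_R, dtype=float))
                corr.a = None
            else:
                a = fit_power_base(ac_glm)
                corr.a = a
                R = _ensure_pd(a**D)
            blocks = [np.arange(n)]
            R_blocks = [R]
            alpha_update = None
        else:
            blocks = _make_blocks(coords, cluster)
            dists = _block_distance_classes(coords, blocks)
            corr.cluster = cluster

            if corstr == "exchangeable":
                def alpha_update(r_pe, phi):
                    num, cnt = 0.0, 0
                    for idx, Db in zip(blocks, dists):
                        m = idx.size
                        if m < 2:
                            continue
                        rb = r_pe[idx]
                        iu = np.triu_indices(m, k=1)
                        num += float(np.sum(rb[iu[0]] * rb[iu[1]]))
                        cnt += iu[0].size
                    alpha = num / (cnt * phi) if cnt else 0.0
                    alpha = float(np.clip(alpha, -0.3, 0.99))
                    Rb = []
                    for idx, Db in zip(blocks, dists):
                        m = idx.size
                        R = np.full((m, m), alpha)
                        np.fill_diagonal(R, 1.0)
                        Rb.append(_ensure_pd(R))
                    return {"alpha": alpha}, Rb
            else:  # quadratic
                all_d = np.unique(
                    np.concatenate([Db[np.triu_indices(Db.shape[0], 1)]
                                    for Db in dists if Db.shape[0] > 1])
                )

                def alpha_update(r_pe, phi):
                    sums = {d: 0.0 for d in all_d}
                    cnts = {d: 0 for d in all_d}
                    for idx, Db in zip(blocks, dists):
                        m = idx.size
                        if m < 2:
                            continue
                        rb = r_pe[idx]
                        iu = np.triu_indices(m, k=1)
                        for i, j in zip(*iu):
                            d = Db[i, j]
                            sums[d] += rb[i] * rb[j]
                            cnts[d] += 1
                    alphas = {
                        d: float(np.clip(sums[d] / (cnts[d] * phi), -0.3, 0.99))
                        for d in all_d if cnts[d]
                    }
                    Rb = []
                    for idx, Db in zip(blocks, dists):
                        m = idx.size
                        R = np.eye(m)
                        for i in range(m):
                            for j in range(i + 1, m):
                                R[i, j] = R[j, i] = alphas.get(Db[i, j], 0.0)
                        Rb.append(_ensure_pd(R))
                    return alphas, Rb
            R_blocks = [np.eye(idx.size) for idx in blocks]

        beta = glm_fit.beta.copy()
        mu = glm_fit.fitted.copy()
        phi = 1.0
        converged = False
        it = 0
        for it in range(1, maxit + 1):
            r_pe = (y - mu) / np.sqrt(family.variance(mu))
            if scale_fix and family.name != "gaussian":
                phi = 1.0
            else:
                phi = float(np.sum(r_pe**2) / max(n - p, 1))
            if corstr in ("exchangeable", "quadratic"):
                pars, R_blocks = alpha_update(r_pe, phi)
                corr.alphas = pars
            delta, omega, _ = _scoring_step(
                X, y, family, mu, R_blocks, blocks, phi
            )
            beta = beta + delta
            mu = family.clip_mean(family.inverse_link(X @ beta))
            rel = np.max(np.abs(delta)) / max(1.0, np.max(np.abs(beta)))
            if rel < tol:
                converged = True
                break
        if not converged:
            warnings.warn(f"GEE scoring did not converge in {it} iterations")
        r_pe = (y - mu) / np.sqrt(family.variance(mu))
        if scale_fix and family.name != "gaussian":
            phi = 1.0
        else:
            phi = float(np.sum(r_pe**2) / max(n - p, 1))
        _, omega, _ = _scoring_step(X, y, family, mu, R_blocks, blocks, phi)
        cov_naive = linalg.inv(omega)
        sandwich_groups = (
            _make_blocks(coords, cluster) if corstr == "fixed" else blocks
        )

    cov_robust = _sandwich(
        X, y, family, mu, R_blocks, blocks, phi, omega, sandwich_groups
    )
    corr.blocks = blocks
    corr.R_blocks = R_blocks

    r_pe = (y - mu) / np.sqrt(family.variance(mu))
    r_norm = _normalized_residuals(r_pe, R_blocks, blocks)
    ac_model = acfft(coords, r_norm, **moran)

    fit = ModelFit(
        kind="gee",
        formula=formula,
        family=family,
        terms=names,
        beta=beta,
        se=np.sqrt(np.diag(cov_naive)),
        cov_naive=cov_naive,
        cov_robust=cov_robust,
        fitted=mu,
        resid_raw=y - mu,
        resid_pearson=pearson_residuals(y, mu, family, phi),
        resid_normalized=r_norm,
        dispersion=phi,
        ic={},
        converged=converged,
        n_iter=it,
        n=n,
        ac_glm=ac_glm,
        ac_model=ac_model,
        meta={
            "corstr": corstr,
            "cluster": cluster,
            "scale_fix": scale_fix,
            "scale_estimated": not scale_fix,
            "moran": moran,
            "correlation": corr,
        },
    )
    fit.ic = {"qic": qic_calc(fit, glm_fit), **{
        k: v for k, v in glm_fit.ic.items() if k == "loglik"
    }}
    return fit


def predict_gee(fit: ModelFit, newdata) -> np.ndarray:
    """Mean predictions g^{-1}(X_new beta)."""
    try:
        X, _ = fit.formula.design_matrix(newdata)
    except KeyError as e:
        raise KeyError(f"newdata is missing model column: {e}") from None
    return fit.family.inverse_link(X @ fit.beta)


def summary_gee(fit: ModelFit, print_autocor_pars: bool = False) -> str:
    """Formatted report: coefficients, QIC, working-correlation parameters."""
    corr: CorrelationModel = fit.meta["correlation"]
    lines = [
        f"Spatial GEE, family = {fit.family.name}, corstr = {corr.corstr}",
        f"Formula: {fit.formula}",
        "",
        fit.coef_table().to_string(float_format=lambda v: f"{v: .6g}"),
        "",
        f"QIC: {fit.ic['qic']:.4f}   dispersion: {fit.dispersion:.4f}",
    ]
    if print_autocor_pars:
        if corr.corstr == "fixed" and corr.a is not None:
            lines.append(f"Autocorrelation parameter: a = {corr.a:.4f} "
                         f"(R_ij = a^d_ij)")
        elif corr.alphas:
            pretty = ", ".join(
                f"{k}: {v:.4f}" if isinstance(k, str) else f"d={k:g}: {v:.4f}"
                for k, v in corr.alphas.items()
            )
            lines.append(f"Within-block correlations ({corr.corstr}, "
                         f"cluster={corr.cluster}): {pretty}")
    if not fit.converged:
        lines.append("WARNING: algorithm did not converge")
    if fit.ac_glm is not None and fit.ac_model is not None:
        m = min(5, fit.ac_glm.dmax)
        glm_i = ", ".join(f"{v:.3f}" for v in fit.ac_glm.moran_i[:m])
        mod_i = ", ".join(f"{v:.3f}" for v in fit.ac_model.moran_i[:m])
        lines += ["", "Residual Moran's I (GLM vs GEE), first bins:",
                  f"  GLM: {glm_i}", f"  GEE: {mod_i}"]
    return "\n".join(lines)
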