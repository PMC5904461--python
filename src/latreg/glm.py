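"""GLM fitting by IRLS, plus the information criteria shared by all models.

The IRLS driver accepts an optional per-iteration filter applied to the
working response and to the non-constant design columns; the plain GLM uses
no filter, the wavelet-revised model plugs in a high-pass wavelet filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.stats import norm

from .autocorr import ACProfile, acfft
from .families import Family, get_family
from .formula import Formula, parse_formula

DEFAULT_MORAN = {"lim1": 0.0, "lim2": 1.0, "dmax": 10}


class NonConvergenceWarning(UserWarning):
    pass


@dataclass
class ModelFit:
    """A fitted lattice regression (GLM / WRM / WMRR / GEE).

    Holds coefficients with their covariance, fitted means on the original
    scale, raw / Pearson (and for GEEs correlation-normalised) residuals,
    the dispersion, information criteria, and the residual Moran's I
    profiles of the comparison GLM and of the model itself.
    """

    kind: str
    formula: Formula
    family: Family
    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    cov_naive: np.ndarray
    fitted: np.ndarray
    resid_raw: np.ndarray
    resid_pearson: np.ndarray
    dispersion: float
    ic: dict
    converged: bool
    n_iter: int
    n: int
    resid_normalized: np.ndarray | None = None
    cov_robust: np.ndarray | None = None
    ac_glm: ACProfile | None = None
    ac_model: ACProfile | None = None
    meta: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return self.beta.size

    def coef_table(self) -> "np.ndarray":
        import pandas as pd

        z = np.divide(self.beta, self.se, out=np.full_like(self.beta, np.nan),
                      where=self.se > 0)
        p = 2.0 * norm.sf(np.abs(z))
        return pd.DataFrame(
            {"estimate": self.beta, "std_error": self.se, "z": z, "p_value": p},
            index=self.terms,
        )

    def criterion(self, use_aicc: bool = False) -> float:
        if self.kind == "gee":
            return float(self.ic["qic"])
        return float(self.ic["aicc" if use_aicc else "aic"])


def _check_rank(X: np.ndarray, names: list[str], what: str = "design") -> None:
    if X.shape[0] < X.shape[1]:
        raise ValueError(f"{what} matrix has more columns than rows")
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    if rank < X.shape[1]:
        bad = [names[j] for j in piv[rank:]]
        raise ValueError(
            f"rank-deficient {what} matrix; collinear column(s): {bad}"
        )


def irls(
    X: np.ndarray,
    y: np.ndarray,
    family: Family,
    filter_fn=None,
    constant_cols=None,
    tol: float = 1e-8,
    maxit: int = 100,
    beta_start: np.ndarray | None = None,
):
    """Iteratively reweighted least squares with an optional spatial filter.

    At each iteration the working response ``z = eta + (y - mu) g'(mu)`` and
    weights ``W = 1 / (V(mu) g'(mu)^2)`` are formed; when ``filter_fn`` is
    given it is applied to ``z`` and to every non-constant design column
    before the weighted solve (the constant column is left untouched so the
    intercept stays identifiable).  Returns the solution together with the
    (possibly filtered) design and weights of the final iteration, from
    which naive standard errors are built.
    """
    n, p = X.shape
    if constant_cols is None:
        constant_cols = [np.ptp(X[:, j]) == 0 for j in range(p)]
    if filter_fn is not None:
        Xf = X.copy()
        for j in range(p):
            if not constant_cols[j]:
                Xf[:, j] = filter_fn(X[:, j])
    else:
        Xf = X

    if beta_start is not None:
        beta = np.asarray(beta_start, dtype=float).copy()
        mu = family.clip_mean(family.inverse_link(X @ beta))
    else:
        beta = np.zeros(p)
        mu = family.clip_mean(family.initialize(y))
    eta = family.link(mu)

    converged = False
    it = 0
    for it in range(1, maxit + 1):
        gprime = family.d_link(mu)
        V = family.variance(mu)
        w = 1.0 / (V * gprime**2)
        z = eta + (y - mu) * gprime
        zf = filter_fn(z) if filter_fn is not None else z
        sw = np.sqrt(w)
        if not (np.all(np.isfinite(sw)) and np.all(np.isfinite(zf))):
            warnings.warn("IRLS diverged (non-finite working quantities)",
                          NonConvergenceWarning)
            break
        new_beta, *_ = np.linalg.lstsq(Xf * sw[:, None], zf * sw, rcond=None)
        if family.name != "gaussian":
            # exp/logit links: halve steps that push eta out of range
            step = new_beta - beta
            for _ in range(20):
                eta_try = X @ (beta + step)
                if (np.max(np.abs(eta_try)) < 30.0
                        or np.max(np.abs(eta_try)) <= np.max(np.abs(X @ beta))):
                    break
                step = step / 2.0
            new_beta = beta + step
        delta = np.max(np.abs(new_beta - beta)) / max(
            1.0, np.max(np.abs(new_beta))
        )
        beta = new_beta
        eta = X @ beta
        mu = family.clip_mean(family.inverse_link(eta))
        if delta < tol:
            converged = True
            break

    if family.name in ("binomial", "poisson") and np.max(np.abs(X @ beta)) > 30.0:
        converged = False  # separation / divergence: estimates unbounded
    if not converged:
        warnings.warn(
            f"IRLS did not converge in {it} iterations",
            NonConvergenceWarning,
        )
    gprime = family.d_link(mu)
    w = 1.0 / (family.variance(mu) * gprime**2)
    z = family.link(mu) + (y - mu) * gprime
    zf = filter_fn(z) if filter_fn is not None else z
    return beta, mu, w, Xf, zf, converged, it


def pearson_residuals(y, mu, family: Family, phi: float | None = None):
    r = (y - mu) / np.sqrt(family.variance(mu))
    # skip the gaussian scale standardisation when the fit is (numerically)
    # saturated: dividing round-off residuals by a round-off scale would
    # manufacture spurious O(1) residuals
    degenerate = phi is None or phi <= 1e-14 * (1.0 + float(np.mean(y**2)))
    if family.name == "gaussian" and not degenerate:
        r = r / np.sqrt(phi)
    return r


def aic_calc(formula, family, data, mu, strict: bool = True) -> dict:
    """Log-likelihood, AIC and AICc for fitted means ``mu``.

    k counts the regression coefficients, plus one for the gaussian error
    variance.  ``AICc = AIC + 2k(k+1)/(n-k-1)``.
    """
    if isinstance(formula, str):
        formula = parse_formula(formula)
    family = get_family(family)
    y = data.variable(formula.response)
    mu = np.asarray(mu, dtype=float)
    _, names = formula.design_matrix(data)
    k = len(names) + (1 if family.name == "gaussian" else 0)
    n = y.size
    ll = family.loglik(y, mu)
    aic = -2.0 * ll + 2.0 * k
    if n - k - 1 <= 0:
        if strict:
            raise ValueError("AICc undefined: n - k - 1 <= 0")
        warnings.warn("AICc undefined (n - k - 1 <= 0); reported as NaN")
        aicc = np.nan
    else:
        aicc = aic + 2.0 * k * (k + 1) / (n - k - 1)
    return {"loglik": ll, "aic": aic, "aicc": aicc}


def fit_glm(
    data,
    formula,
    family,
    tol: float = 1e-8,
    maxit: int = 100,
    moran: dict | None = None,
) -> ModelFit:
    """Fit a GLM by IRLS (the non-spatial baseline for every other model)."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    family = get_family(family)
    y = data.variable(formula.response)
    X, names = formula.design_matrix(data)
    _check_rank(X, names)

    beta, mu, w, Xf, _zf, converged, it = irls(X, y, family, tol=tol, maxit=maxit)

    n, k = X.shape
    r_pe = (y - mu) / np.sqrt(family.variance(mu))
    phi = float(np.sum(r_pe**2) / max(n - k, 1))
    # SEs use the family convention: estimated scale for gaussian, unit
    # dispersion for binomial/poisson
    se_phi = phi if family.name == "gaussian" else 1.0
    XtWX = (Xf * w[:, None]).T @ Xf
    cov = linalg.inv(XtWX) * se_phi
    ic = aic_calc(formula, family, data, mu, strict=False)

    fit = ModelFit(
        kind="glm",
        formula=formula,
        family=family,
        terms=names,
        beta=beta,
        se=np.sqrt(np.diag(cov)),
        cov_naive=cov,
        fitted=mu,
        resid_raw=y - mu,
        resid_pearson=pearson_residuals(y, mu, family, phi),
        dispersion=phi,
        ic=ic,
        converged=converged,
        n_iter=it,
        n=n,
        meta={"tol": tol, "maxit": maxit},
    )
    if moran is not None:
        fit.ac_model = acfft(data.coords, fit.resid_pearson, **moran)
        fit.ac_glm = fit.ac_model
    return fit


def predict_glm(fit: ModelFit, newdata) -> np.ndarray:
    """Mean predictions g^{-1}(X_new beta) — coordinates play no role."""
    try:
        X, _ = fit.formula.design_matrix(newdata)
    except KeyError as e:
        raise KeyError(f"newdata is missing model column: {e}") from None
    return fit.family.inverse_link(X @ fit.beta)


def qic_calc(fit: ModelFit, independence_fit: ModelFit) -> float:
    """Quasi-likelihood information criterion (Pan's trace form).

    ``QIC = -2 Q(mu_hat; I) + 2 trace(Omega_I^{-1} V_r)`` where Q is the
    independence quasi-likelihood at the model's fitted means, Omega_I the
    model-based covariance of the coefficients from the independence fit,
    and V_r the robust sandwich covariance of the model.
    """
    y = independence_fit.resid_raw + independence_fit.fitted
    # Q is evaluated at unit dispersion: a model-specific estimated scale
    # would cancel the fit term (-2Q == n-k for every gaussian model) and
    # void the criterion for model comparison
    q = fit.family.quasi_loglik(y, fit.fitted, phi=1.0)
    omega_i = independence_fit.cov_naive
    v_r = fit.cov_robust if fit.cov_robust is not None else fit.cov_naive
    if not np.all(np.isfinite(omega_i)):
        raise ValueError("singular model-based covariance")
    try:
        trace = float(np.trace(linalg.solve(omega_i, v_r, assume_a="sym")))
    except linalg.LinAlgError:
        raise ValueError("singular model-based covariance") from None
    return -2.0 * q + 2.0 * trace
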