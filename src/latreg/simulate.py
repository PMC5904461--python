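"""Seeded synthetic lattice data with known ground truth.

Three generators emulate the statistical shape of the kinds of data the
toolkit targets (they are not numerical reproductions of any real survey):

* ``make_musdata_like`` — Poisson counts of a species on a grid, driven by
  two spatially autocorrelated covariates (``pollution``, ``exposure``)
  plus a smooth latent confounder that shares low-frequency structure with
  the covariates: the classic setting in which a GLM picks up biased slopes
  and spatially aware models should not.
* ``make_carlinadata_like`` — the same model on an exactly square, fully
  observed grid with covariates ``aridity`` and ``land_use``, convenient
  for clean dyadic wavelet behaviour.
* ``make_hook_like`` — clustered presence/absence actuals with a
  probability prediction field that can be displaced by whole cells, for
  exercising spatial vs classical accuracy measures.

Spatial structure comes from Gaussian-kernel smoothing of white noise
(periodic boundaries); ``ac_range`` is the kernel scale in cells and
controls the autocorrelation range.  Every generator is a pure function of
its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .grid import GridData


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic generators.

    grid_side : side of the square lattice (cells).
    betas : ground-truth (intercept, slope1, slope2) on the link scale.
    family : response family (poisson counts by default).
    ac_range : Gaussian smoothing scale (cells) of covariate/confounder
        fields; 0 gives white noise.
    confounder_strength : link-scale standard deviation of the smooth
        latent field omitted from the fitted model; it shares sources with
        the covariates, so > 0 biases naive GLM slopes.
    seed : fixes all randomness end to end.
    """

    grid_side: int = 24
    betas: tuple = (0.5, 0.3, -0.4)
    family: str = "poisson"
    ac_range: float = 3.0
    confounder_strength: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.grid_side < 8:
            raise ValueError("grid_side must be >= 8")


@dataclass
class SyntheticDataset:
    """Generated data plus a ground-truth sidecar for assertions."""

    data: GridData
    truth: dict = field(default_factory=dict)


@dataclass
class HookDataset:
    """Actual/prediction pairs with coordinates plus ground truth."""

    actuals: np.ndarray
    predictions: np.ndarray
    coords: np.ndarray
    truth: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "actuals": self.actuals.astype(int),
            "predictions": self.predictions,
            "x": self.coords[:, 0],
            "y": self.coords[:, 1],
        })


def _standardize(f: np.ndarray) -> np.ndarray:
    s = f.std()
    return (f - f.mean()) / s if s > 0 else f - f.mean()


def _smooth_field(rng, side: int, sigma: float) -> np.ndarray:
    noise = rng.standard_normal((side, side))
    if sigma > 0:
        noise = gaussian_filter(noise, sigma=sigma, mode="wrap")
    return _standardize(noise)


def _grid_coords(side: int) -> np.ndarray:
    xs, ys = np.meshgrid(np.arange(1, side + 1), np.arange(1, side + 1))
    return np.column_stack([xs.ravel(), ys.ravel()])


def _simulate_response(rng, eta: np.ndarray, family: str) -> np.ndarray:
    if family == "poisson":
        return rng.poisson(np.exp(np.clip(eta, -20, 20))).astype(float)
    if family == "binomial":
        return rng.binomial(1, expit(eta)).astype(float)
    return eta + rng.standard_normal(eta.size)


def _covariate_model(cfg: SimConfig, names: tuple[str, str],
                     response_name: str) -> SyntheticDataset:
    rng = np.random.default_rng(cfg.seed)
    side = cfg.grid_side
    src1 = rng.standard_normal((side, side))
    src2 = rng.standard_normal((side, side))
    src3 = rng.standard_normal((side, side))

    def sm(f, sigma):
        return gaussian_filter(f, sigma=sigma, mode="wrap") if sigma > 0 else f

    x1 = _standardize(sm(src1, cfg.ac_range))
    x2 = _standardize(sm(src2, cfg.ac_range))
    # the confounder re-uses the covariate sources at twice the range, so it
    # is smooth AND correlated with the covariates' low-frequency parts
    conf = cfg.confounder_strength * _standardize(
        sm(src1, 2 * cfg.ac_range)
        + sm(src2, 2 * cfg.ac_range)
        + sm(src3, 2 * cfg.ac_range)
    )

    b0, b1, b2 = cfg.betas
    eta = b0 + b1 * x1 + b2 * x2 + conf
    y = _simulate_response(rng, eta.ravel(), cfg.family)

    coords = _grid_coords(side)
    covariates = pd.DataFrame({
        names[0]: x1.ravel(),
        names[1]: x2.ravel(),
    })
    data = GridData(coords=coords, response=y, covariates=covariates,
                    response_name=response_name, family_hint=cfg.family)
    truth = {
        "betas": list(cfg.betas),
        "covariate_names": list(names),
        "confounder": conf.ravel().tolist(),
        "config": asdict(cfg),
    }
    return SyntheticDataset(data=data, truth=truth)


def make_musdata_like(cfg: SimConfig = SimConfig()) -> SyntheticDataset:
    """Species counts vs pollution and exposure on a square grid."""
    return _covariate_model(cfg, ("pollution", "exposure"), "musculus")


def make_carlinadata_like(cfg: SimConfig = SimConfig()) -> SyntheticDataset:
    """Plant counts vs aridity and land use on an exactly square grid."""
    return _covariate_model(cfg, ("aridity", "land_use"), "carlina_horrida")


def make_hook_like(cfg: SimConfig = SimConfig(), shift_cells: int = 0,
                   prevalence: float = 0.3, noise: float = 0.1,
                   sharpness: float = 4.0,
                   patch_scale: float = 0.5) -> HookDataset:
    """Clustered presences with an optionally displaced prediction field.

    Actuals threshold a random field smoothed at ``patch_scale`` (a small
    scale, so presences form compact patches of one to a few cells) at the
    (1 - prevalence) quantile.  Predictions are a logistic transform of the
    same field rolled by ``shift_cells`` along BOTH grid axes (plus white
    noise): shift_cells = 1 turns every prediction into a diagonal one-cell
    near miss — still inside the queen neighbourhood, but off-cell — the
    regime where spatial and classical accuracy measures disagree.
    """
    if not (0.0 < prevalence < 1.0):
        raise ValueError("prevalence must be in (0, 1)")
    rng = np.random.default_rng(cfg.seed)
    side = cfg.grid_side
    g = _smooth_field(rng, side, patch_scale)
    cut = np.quantile(g, 1.0 - prevalence)
    actuals = (g >= cut).astype(float)

    shifted = np.roll(np.roll(g, shift_cells, axis=0), shift_cells, axis=1)
    lin = shifted + noise * rng.standard_normal((side, side))
    pcut = np.quantile(lin, 1.0 - prevalence)
    predictions = expit(sharpness * (lin - pcut) / max(lin.std(), 1e-12))

    coords = _grid_coords(side)
    truth = {
        "prevalence": prevalence,
        "shift_cells": shift_cells,
        "noise": noise,
        "config": asdict(cfg),
    }
    return HookDataset(actuals=actuals.ravel(), predictions=predictions.ravel(),
                       coords=coords, truth=truth)
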