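"""Exponential-family definitions (canonical links only).

Each family bundles the link, its inverse and derivative, the variance
function V(mu) and the log density used for likelihood-based criteria.
Only the three families relevant for lattice count/occurrence data are
provided: gaussian (identity), binomial (logit) and poisson (log).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.special import expit, gammaln

_EPS = 1e-10


@dataclass(frozen=True)
class Family:
    """A GLM family with canonical link.

    Attributes
    ----------
    name : one of ``gaussian``, ``binomial``, ``poisson``
    link_name : canonical link (identity / logit / log)
    variance : V(mu), the variance function
    inverse_link : mu = g^{-1}(eta)
    link : eta = g(mu)
    d_link : g'(mu) = d eta / d mu
    """

    name: str
    link_name: str
    variance: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    inverse_link: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    link: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    d_link: Callable[[np.ndarray], np.ndarray] = field(repr=False)

    def initialize(self, y: np.ndarray) -> np.ndarray:
        """Starting means for IRLS."""
        y = np.asarray(y, dtype=float)
        if self.name == "binomial":
            return (y + 0.5) / 2.0
        if self.name == "poisson":
            return np.maximum(y, 0.0) + 0.1
        return y.copy()

    def clip_mean(self, mu: np.ndarray) -> np.ndarray:
        if self.name == "binomial":
            return np.clip(mu, _EPS, 1.0 - _EPS)
        if self.name == "poisson":
            # upper bound keeps IRLS weights finite when a fit diverges
            return np.clip(mu, _EPS, 1e13)
        return mu

    def loglik(self, y: np.ndarray, mu: np.ndarray) -> float:
        """Sum of log densities; gaussian profiles out sigma^2 = MSE."""
        y = np.asarray(y, dtype=float)
        mu = self.clip_mean(np.asarray(mu, dtype=float))
        if self.name == "gaussian":
            n = y.size
            sigma2 = float(np.mean((y - mu) ** 2))
            sigma2 = max(sigma2, _EPS)
            return float(-0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0))
        if self.name == "poisson":
            return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1.0)))
        # binomial 0/1
        return float(np.sum(y * np.log(mu) + (1.0 - y) * np.log(1.0 - mu)))

    def quasi_loglik(self, y: np.ndarray, mu: np.ndarray, phi: float = 1.0) -> float:
        """Quasi-likelihood Q(mu; y) under independence, used by QIC."""
        y = np.asarray(y, dtype=float)
        mu = self.clip_mean(np.asarray(mu, dtype=float))
        if self.name == "gaussian":
            return float(-np.sum((y - mu) ** 2) / (2.0 * phi))
        if self.name == "poisson":
            return float(np.sum(y * np.log(mu) - mu) / phi)
        return float(np.sum(y * np.log(mu) + (1.0 - y) * np.log(1.0 - mu)) / phi)


GAUSSIAN = Family(
    name="gaussian",
    link_name="identity",
    variance=lambda mu: np.ones_like(np.asarray(mu, dtype=float)),
    inverse_link=lambda eta: np.asarray(eta, dtype=float),
    link=lambda mu: np.asarray(mu, dtype=float),
    d_link=lambda mu: np.ones_like(np.asarray(mu, dtype=float)),
)

BINOMIAL = Family(
    name="binomial",
    link_name="logit",
    variance=lambda mu: mu * (1.0 - mu),
    inverse_link=lambda eta: expit(eta),
    link=lambda mu: np.log(mu / (1.0 - mu)),
    d_link=lambda mu: 1.0 / (mu * (1.0 - mu)),
)

POISSON = Family(
    name="poisson",
    link_name="log",
    variance=lambda mu: np.asarray(mu, dtype=float),
    inverse_link=lambda eta: np.exp(np.clip(eta, -700, 700)),
    link=lambda mu: np.log(mu),
    d_link=lambda mu: 1.0 / np.asarray(mu, dtype=float),
)

_FAMILIES = {"gaussian": GAUSSIAN, "binomial": BINOMIAL, "poisson": POISSON}


def get_family(family) -> Family:
    """Resolve a family name or instance to a :class:`Family`."""
    if isinstance(family, Family):
        return family
    try:
        return _FAMILIES[str(family).lower()]
    except KeyError:
        raise ValueError(
            f"unknown family {family!r}; choose from {sorted(_FAMILIES)}"
        ) from None
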