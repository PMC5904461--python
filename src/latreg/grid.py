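"""Lattice containers: gridded observations and dyadic square embeddings.

Observations live on integer grid cells (x, y).  Wavelet transforms need a
square matrix whose side is a power of two, so scattered observations are
embedded into the smallest adequate dyadic square and padded.  ``x`` maps to
columns and ``y`` to rows (row order is increasing y); the convention is
arbitrary but fixed so that correlograms and wavelet components are
reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_PADFORMS = ("zeros", "mean", "mirror")


@dataclass
class GridData:
    """Observations keyed by integer lattice coordinates.

    Parameters
    ----------
    coords : (n, 2) integer array of (x, y) grid-cell indices, one row per
        observation; cells must be unique.
    response : length-n numeric vector.
    covariates : DataFrame of named numeric columns, n rows.
    response_name : column name used in formulas.
    family_hint : optional tag in {gaussian, binomial, poisson} used to
        validate the response range.
    """

    coords: np.ndarray
    response: np.ndarray
    covariates: pd.DataFrame
    response_name: str = "response"
    family_hint: str | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be an (n, 2) array of (x, y) pairs")
        if not np.issubdtype(self.coords.dtype, np.integer):
            as_int = np.asarray(self.coords, dtype=float)
            if not np.all(as_int == np.round(as_int)):
                raise ValueError("coordinates must be integer grid-cell indices")
            self.coords = as_int.astype(int)
        self.response = np.asarray(self.response, dtype=float)
        if not isinstance(self.covariates, pd.DataFrame):
            self.covariates = pd.DataFrame(self.covariates)
        n = self.coords.shape[0]
        if n < 4:
            raise ValueError("need at least 4 observations")
        if self.response.shape[0] != n or len(self.covariates) != n:
            raise ValueError("coords, response and covariates must share length")
        if len(np.unique(self.coords, axis=0)) != n:
            raise ValueError("duplicate grid cells: one observation per cell")
        if self.family_hint == "binomial" and not np.all(
            np.isin(self.response, (0.0, 1.0))
        ):
            raise ValueError("binomial response must contain only 0/1")
        if self.family_hint == "poisson" and (
            np.any(self.response < 0)
            or not np.all(self.response == np.round(self.response))
        ):
            raise ValueError("poisson response must be non-negative integers")

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    def variable(self, name: str) -> np.ndarray:
        """Return a variable (response or covariate) by name."""
        if name == self.response_name:
            return self.response
        if name in self.covariates.columns:
            return self.covariates[name].to_numpy(dtype=float)
        raise KeyError(f"no variable named {name!r}")

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"x": self.coords[:, 0], "y": self.coords[:, 1]})
        out[self.response_name] = self.response
        for c in self.covariates.columns:
            out[c] = self.covariates[c].to_numpy()
        return out

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        response: str,
        covariates: list[str] | None = None,
        family_hint: str | None = None,
    ) -> "GridData":
        if "x" not in frame.columns or "y" not in frame.columns:
            raise ValueError("frame must have 'x' and 'y' columns")
        if covariates is None:
            covariates = [
                c for c in frame.columns if c not in ("x", "y", response)
            ]
        return cls(
            coords=frame[["x", "y"]].to_numpy(),
            response=frame[response].to_numpy(dtype=float),
            covariates=frame[covariates].astype(float),
            response_name=response,
            family_hint=family_hint,
        )

    @classmethod
    def from_csv(cls, path, response: str, **kwargs) -> "GridData":
        """Read comma-delimited records with columns x, y, response, covariates."""
        return cls.from_frame(pd.read_csv(path), response=response, **kwargs)


@dataclass(frozen=True)
class PadSpec:
    """Boundary treatment for dyadic embedding.

    padform : how unobserved cells are filled — ``zeros``, ``mean`` (mean of
        the observed values) or ``mirror`` (values reflected outward across
        the bounding box of the observations).
    padzone : expansion factor (>= 1) applied to the data extent before the
        dyadic side is chosen; > 1 inserts a guard zone against wrap-around
        boundary effects of the periodic transform.
    """

    padform: str = "mean"
    padzone: float = 1.0

    def __post_init__(self) -> None:
        if self.padform not in _PADFORMS:
            raise ValueError(f"padform must be one of {_PADFORMS}")
        if not self.padzone >= 1.0:
            raise ValueError("padzone must be >= 1")


@dataclass
class LatticeFrame:
    """A 2^J x 2^J matrix embedding of one variable plus its index map."""

    matrix: np.ndarray
    index_map: np.ndarray  # (n, 2) of (row, col)
    J: int
    origin: tuple[int, int]  # (min_x, min_y)

    @property
    def side(self) -> int:
        return self.matrix.shape[0]


def _dyadic_side(extent: int, padzone: float) -> int:
    target = int(np.ceil(padzone * extent))
    J = max(0, int(np.ceil(np.log2(max(target, 1)))))
    return 2**J, J


def _mirror_index(i: np.ndarray, n: int) -> np.ndarray:
    """Reflect any non-negative index into [0, n) (symmetric, no edge repeat
    beyond the standard half-sample convention)."""
    if n == 1:
        return np.zeros_like(i)
    period = 2 * n
    j = np.mod(i, period)
    return np.where(j < n, j, period - 1 - j)


def embed(values, coords, pad: PadSpec = PadSpec()) -> LatticeFrame:
    """Embed one variable into a padded dyadic square matrix.

    Observed cells keep their values; all other cells receive the pad fill.
    Interior holes (cells inside the bounding box with no observation) are
    filled with the pad value as well — they are reported via a log message
    but never interpolated.
    """
    values = np.asarray(values, dtype=float)
    coords = np.asarray(coords)
    if not np.issubdtype(coords.dtype, np.integer):
        cf = np.asarray(coords, dtype=float)
        if not np.all(cf == np.round(cf)):
            raise ValueError("coordinates must be integer grid-cell indices")
        coords = cf.astype(int)
    if values.ndim != 1 or coords.shape != (values.size, 2):
        raise ValueError("values must be 1-D with matching (n, 2) coords")
    if values.size == 0:
        raise ValueError("cannot embed an empty variable")

    min_x, min_y = coords[:, 0].min(), coords[:, 1].min()
    cols = coords[:, 0] - min_x
    rows = coords[:, 1] - min_y
    extent = int(max(cols.max(), rows.max()) + 1)
    side, J = _dyadic_side(extent, pad.padzone)

    h = int(rows.max() + 1)
    w = int(cols.max() + 1)
    box = np.full((h, w), np.nan)
    box[rows, cols] = values
    holes = int(np.isnan(box).sum())
    if holes:
        logger.info(
            "embedding: %d unobserved cell(s) inside the bounding box filled "
            "with the pad value", holes,
        )

    mean_val = float(values.mean())
    if pad.padform == "zeros":
        fill = 0.0
        box = np.where(np.isnan(box), fill, box)
        matrix = np.full((side, side), fill)
        matrix[:h, :w] = box
    elif pad.padform == "mean":
        fill = mean_val
        box = np.where(np.isnan(box), fill, box)
        matrix = np.full((side, side), fill)
        matrix[:h, :w] = box
    else:  # mirror
        box = np.where(np.isnan(box), mean_val, box)
        ri = _mirror_index(np.arange(side), h)
        ci = _mirror_index(np.arange(side), w)
        matrix = box[np.ix_(ri, ci)]

    index_map = np.column_stack([rows, cols])
    return LatticeFrame(matrix=matrix, index_map=index_map, J=J,
                        origin=(int(min_x), int(min_y)))


def extract(frame: LatticeFrame) -> np.ndarray:
    """Observation values in original record order (inverse of embed)."""
    if frame.index_map.size == 0:
        raise ValueError("frame has no observations to extract")
    return frame.matrix[frame.index_map[:, 0], frame.index_map[:, 1]].copy()


def upscale(values, coords, scale: int = 1, pad: PadSpec | None = None,
            wavelet=None) -> np.ndarray:
    """Smooth component of a variable at a dyadic resolution level.

    ``scale=0`` returns the raw embedded matrix; ``scale=s >= 1`` returns the
    smooth (low-frequency) component of the 2-D wavelet decomposition at
    level s, rendered on the full 2^J x 2^J grid — a gradual, dyadic
    enlargement of effective cell size.  Default padding fills with the mean
    of the input vector.
    """
    from .wavelets import WaveletSpec, decompose  # local import: avoid cycle

    if pad is None:
        pad = PadSpec(padform="mean", padzone=1.0)
    if wavelet is None:
        wavelet = WaveletSpec()
    frame = embed(values, coords, pad)
    if scale < 0 or scale != int(scale):
        raise ValueError("scale must be a non-negative integer")
    scale = int(scale)
    if scale > frame.J:
        raise ValueError(f"scale {scale} exceeds dyadic depth J={frame.J}")
    if scale == 0:
        return frame.matrix.copy()
    dec = decompose(frame, wavelet, level=scale)
    return dec.smooths[scale - 1].copy()
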