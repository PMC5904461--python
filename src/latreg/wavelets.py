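"""Separable 2-D wavelet multiresolution analysis on dyadic lattice frames.

Components are returned as reconstructed full-resolution fields (a
multiresolution analysis), not decimated coefficients, so values at the
observation cells are always well defined.  Two families (haar and the
4-tap Daubechies extremal-phase filter, "d4") and two transforms are
supported: the decimated DWT with periodic boundary handling — boundary
control is delegated to the embedding pad zone — and the undecimated,
translation-invariant MODWT.

Key identities (tested):

* telescoping: smooth(s) == smooth(s+1) + detail(s+1),
* perfect reconstruction: input == smooth(L) + sum of details 1..L,
* haar DWT smooths equal nested 2x2 block averages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt

from .grid import GridData, LatticeFrame, PadSpec, embed, extract

_PYWT_NAME = {"haar": "haar", "d4": "db2"}
_PYWT_TRANSFORM = {"dwt": "dwt2", "modwt": "swt2"}


@dataclass(frozen=True)
class WaveletSpec:
    """Wavelet family + transform choice.

    family : ``haar`` (default) or ``d4``.
    transform : ``dwt`` (decimated, default) or ``modwt`` (undecimated,
        translation-invariant; preferred for variance/covariance work).
    max_level : optional cap on decomposition depth.
    """

    family: str = "haar"
    transform: str = "dwt"
    max_level: int | None = None

    def __post_init__(self):
        if self.family not in _PYWT_NAME:
            raise ValueError(f"family must be one of {sorted(_PYWT_NAME)}")
        if self.transform not in _PYWT_TRANSFORM:
            raise ValueError(
                f"transform must be one of {sorted(_PYWT_TRANSFORM)}"
            )

    @property
    def pywt_wavelet(self) -> str:
        return _PYWT_NAME[self.family]

    @property
    def pywt_transform(self) -> str:
        return _PYWT_TRANSFORM[self.transform]


@dataclass
class Decomposition2D:
    """Full multiresolution analysis of one lattice frame.

    ``details[s-1]`` holds the three orientation sub-bands (horizontal,
    vertical, diagonal) of level s; ``smooths[s-1]`` the smooth component at
    level s.  All arrays are full grid size.
    """

    details: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
    smooths: list[np.ndarray]
    spec: WaveletSpec
    original: np.ndarray

    @property
    def level(self) -> int:
        return len(self.smooths)

    def detail_sum(self, s: int) -> np.ndarray:
        """Sum of the three orientation sub-bands at level s."""
        h, v, d = self.details[s - 1]
        return h + v + d


def _max_depth(side: int) -> int:
    return int(np.log2(side))


def decompose(frame, spec: WaveletSpec = WaveletSpec(),
              level: int | None = None) -> Decomposition2D:
    """Multiresolution analysis of a LatticeFrame (or square matrix)."""
    mat = frame.matrix if isinstance(frame, LatticeFrame) else np.asarray(frame, float)
    side = mat.shape[0]
    if mat.shape[0] != mat.shape[1]:
        raise ValueError("frame must be square")
    depth = _max_depth(side)
    if level is None:
        level = spec.max_level if spec.max_level is not None else depth
    if level < 1 or level > depth:
        raise ValueError(
            f"level must be in 1..{depth} for a {side}x{side} frame"
        )
    comps = pywt.mra2(
        mat,
        spec.pywt_wavelet,
        level=level,
        transform=spec.pywt_transform,
        mode="periodization",
    )
    # comps: [smooth(L), details(L), ..., details(1)], each detail a 3-tuple
    smooth_L = comps[0]
    details = [tuple(np.asarray(b) for b in d) for d in reversed(comps[1:])]
    smooths: list[np.ndarray] = [None] * level
    smooths[level - 1] = smooth_L
    for s in range(level - 1, 0, -1):
        smooths[s - 1] = smooths[s] + sum(details[s])
    return Decomposition2D(details=details, smooths=smooths, spec=spec,
                           original=mat)


def filter_highpass(values, coords, level: int = 1,
                    spec: WaveletSpec = WaveletSpec(),
                    pad: PadSpec = PadSpec()) -> np.ndarray:
    """Remove the smooth component at ``level`` from a lattice variable.

    Embeds, decomposes, keeps only the detail levels 1..L (i.e. subtracts
    smooth(L)) and extracts back to observation order.  Smaller L removes
    more low-frequency structure; L=1 is the strongest filter.
    """
    frame = embed(values, coords, pad)
    dec = decompose(frame, spec, level=level)
    highpass = frame.matrix - dec.smooths[level - 1]
    return highpass[frame.index_map[:, 0], frame.index_map[:, 1]].copy()


def extract_component(values, coords, scale: int, detail: bool = True,
                      spec: WaveletSpec = WaveletSpec(),
                      pad: PadSpec = PadSpec()) -> np.ndarray:
    """Detail (or smooth) component at one scale, at the observation cells."""
    frame = embed(values, coords, pad)
    dec = decompose(frame, spec, level=scale)
    if detail:
        comp = dec.detail_sum(scale)
    else:
        comp = dec.smooths[scale - 1]
    return comp[frame.index_map[:, 0], frame.index_map[:, 1]].copy()


def _detail_coeffs(mat: np.ndarray, spec: WaveletSpec, level: int):
    """Orthonormal detail (and final smooth) coefficient sub-bands.

    Returns ``(details, smooth)`` with ``details[s-1]`` the three
    orientation coefficient arrays of level s.  Both transforms are energy
    preserving here (periodized DWT; norm-rescaled undecimated transform),
    so the level-wise sums of squares partition ``sum(mat**2)`` exactly.
    """
    if spec.transform == "dwt":
        coeffs = pywt.wavedec2(mat, spec.pywt_wavelet, level=level,
                               mode="periodization")
    else:
        coeffs = pywt.swt2(mat, spec.pywt_wavelet, level=level,
                           trim_approx=True, norm=True)
    smooth = np.asarray(coeffs[0])
    details = [list(map(np.asarray, d)) for d in reversed(coeffs[1:])]
    return details, smooth


def wavelet_varcov(data: GridData, terms=None,
                   spec: WaveletSpec = WaveletSpec("d4", "modwt"),
                   max_level: int | None = None,
                   pad: PadSpec = PadSpec(),
                   include_smooth: bool = False) -> pd.DataFrame:
    """Per-level wavelet variance of each variable and covariance of the
    response with each covariate.

    Variables are centred internally and embedded; the variance at level s
    is the mean over the embedded grid of the squared detail coefficients
    (all three orientations), the covariance the mean of the coefficient
    products.  Because the coefficient transforms are orthonormal, the
    per-level variances plus the smooth term partition the grid variance
    exactly; on a fully observed dyadic square that equals the variance of
    the data.  The d4/MODWT combination is the default as the numerically
    best-behaved for this purpose.

    ``include_smooth`` appends a row (index ``"smooth"``) with the
    contribution of the final smooth coefficients.
    """
    if terms is None:
        terms = list(data.covariates.columns)
    names = [data.response_name] + [t for t in terms if t != data.response_name]
    frames = {nm: embed(data.variable(nm) - np.mean(data.variable(nm)),
                        data.coords, pad) for nm in names}
    any_frame = next(iter(frames.values()))
    depth = _max_depth(any_frame.side)
    level = min(max_level, depth) if max_level is not None else depth
    cells = any_frame.side ** 2

    coeffs = {nm: _detail_coeffs(frames[nm].matrix, spec, level)
              for nm in names}
    resp = data.response_name
    rows = []
    for s in range(1, level + 1):
        row = {"level": s}
        for nm in names:
            bands = coeffs[nm][0][s - 1]
            row[f"var_{nm}"] = float(sum(np.sum(b**2) for b in bands) / cells)
        for nm in names[1:]:
            row[f"cov_{resp}_{nm}"] = float(
                sum(np.sum(by * bx) for by, bx in
                    zip(coeffs[resp][0][s - 1], coeffs[nm][0][s - 1])) / cells
            )
        rows.append(row)
    out = pd.DataFrame(rows).set_index("level")
    if include_smooth:
        srow = {}
        for nm in names:
            srow[f"var_{nm}"] = float(np.sum(coeffs[nm][1] ** 2) / cells)
        for nm in names[1:]:
            srow[f"cov_{resp}_{nm}"] = float(
                np.sum(coeffs[resp][1] * coeffs[nm][1]) / cells
            )
        out.loc["smooth"] = pd.Series(srow)
    return out
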