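import numpy as np
import pandas as pd
import pytest

import latreg as lr


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def full_grid_coords():
    """Coordinates of a fully observed 8x8 grid (1-based)."""
    xs, ys = np.meshgrid(np.arange(1, 9), np.arange(1, 9))
    return np.column_stack([xs.ravel(), ys.ravel()])


def grid_coords(side):
    xs, ys = np.meshgrid(np.arange(1, side + 1), np.arange(1, side + 1))
    return np.column_stack([xs.ravel(), ys.ravel()])


def gaussian_griddata(seed=0, side=12, betas=(1.0, 2.0, -1.5), noise=1.0):
    """A simple gaussian lattice data set with known coefficients."""
    rng = np.random.default_rng(seed)
    coords = grid_coords(side)
    n = side * side
    x1 = rng.standard_normal(n)
    x2 = rng.standard_normal(n)
    y = betas[0] + betas[1] * x1 + betas[2] * x2 + noise * rng.standard_normal(n)
    return lr.GridData(
        coords=coords,
        response=y,
        covariates=pd.DataFrame({"x1": x1, "x2": x2}),
        response_name="y",
    )


@pytest.fixture
def gauss_data():
    return gaussian_griddata()


@pytest.fixture
def musdata():
    return lr.make_musdata_like(lr.SimConfig(seed=7)).data
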