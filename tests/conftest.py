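import numpy as np
import pandas as pd
import pytest

from ldrank import (
    DEFAULT_SCHEME,
    IndicatorMeta,
    LandCoverGrid,
    NormalizedTable,
    Poset,
)
from ldrank.examples import six_county_example


@pytest.fixture
def fig_table() -> NormalizedTable:
    """Six-county worked example (oriented natural-group table)."""
    return six_county_example()


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def random_grid_pair(rng, shape=(12, 15), nodata_frac=0.1, cell_area=2.5):
    """A random land-cover grid pair sharing shape/scheme, with nodata holes."""
    codes = np.array(DEFAULT_SCHEME.codes)
    a = rng.choice(codes, size=shape)
    b = rng.choice(codes, size=shape)
    hole_a = rng.random(shape) < nodata_frac
    hole_b = rng.random(shape) < nodata_frac
    a = np.where(hole_a, -9999, a)
    b = np.where(hole_b, -9999, b)
    ga = LandCoverGrid(a, cell_area=cell_area, epoch=1990)
    gb = LandCoverGrid(b, cell_area=cell_area, epoch=2000)
    return ga, gb


def random_poset(rng, n_max=8, n_cols=3) -> Poset:
    """Random componentwise-order poset over <= n_max elements."""
    from ldrank import build_poset

    n = int(rng.integers(2, n_max + 1))
    # coarse value grid produces plenty of ties and comparabilities
    vals = rng.integers(0, 4, size=(n, n_cols)) / 3.0
    names = [f"u{i}" for i in range(n)]
    metas = [IndicatorMeta(f"f{j}", "natural") for j in range(n_cols)]
    df = pd.DataFrame(vals, index=names, columns=[m.name for m in metas])
    table = NormalizedTable(df, metas, oriented=True)
    return build_poset(table)
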