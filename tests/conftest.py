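import numpy as np
import pandas as pd
import pytest

from ecopattern import ClassGrid, Legend


@pytest.fixture
def legend():
    return Legend.default()


@pytest.fixture
def small_legend():
    return Legend(entries=((1, "forest"), (2, "grassland"), (3, "farmland")))


def make_grid(values, legend, cell_size_m=100.0, nodata=-9999, label=""):
    return ClassGrid(
        values=np.asarray(values, dtype=np.int64),
        cell_size_m=cell_size_m,
        legend=legend,
        nodata_code=nodata,
        epoch_label=label,
    )


@pytest.fixture
def uniform_grid(legend):
    """10×10 of forest, 100 m cells → exactly 1 km² / 100 ha."""
    return make_grid(np.ones((10, 10)), legend, label="t0")


@pytest.fixture
def random_grid(small_legend):
    rng = np.random.default_rng(7)
    return make_grid(
        rng.choice([1, 2, 3], size=(20, 20)), small_legend, label="rand"
    )


@pytest.fixture
def table4():
    """The published example transfer report: displayed 5×5 block (rows =
    destination epoch), per-row Total column, bottom Total row and the grand
    total, all in km²."""
    disp = ["forest", "grassland", "wetland", "farmland", "urban"]
    block = pd.DataFrame(
        [
            [476.24, 19.57, 0.07, 16.10, 0.08],
            [22.67, 66.31, 0.02, 6.44, 0.00],
            [0.07, 0.00, 17.16, 0.97, 0.32],
            [4.85, 0.002, 1.19, 511.86, 5.29],
            [0.67, 0.00, 0.69, 28.63, 33.96],
        ],
        index=disp,
        columns=disp,
    )
    total_col = pd.Series([512.06, 95.44, 18.52, 523.19, 63.95], index=disp)
    total_row = pd.Series([535.43, 86.36, 19.13, 564.72, 39.65], index=disp)
    return {
        "block": block,
        "total_col": total_col,
        "total_row": total_row,
        "grand_total": 1245.31,
        "display": disp,
    }
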