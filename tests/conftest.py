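import numpy as np
import pandas as pd
import pytest

from areakrig.core_geo import SamplePointSet
from areakrig.synthetic_data import make_region
from areakrig.variogram import VariogramModel


@pytest.fixture
def unit_square_pts():
    """Four corner points of the unit square (ids in reading order)."""
    return SamplePointSet(ids=np.arange(4), x=[0.0, 1.0, 0.0, 1.0],
                          y=[0.0, 0.0, 1.0, 1.0],
                          values=pd.DataFrame(index=range(4)))


@pytest.fixture
def random_pts():
    """20 random points in a 1 km square with one variable."""
    rng = np.random.default_rng(11)
    n = 20
    return SamplePointSet(
        ids=np.arange(n),
        x=rng.uniform(0, 1000, n), y=rng.uniform(0, 1000, n),
        values=pd.DataFrame({"v": rng.normal(50, 10, n)}),
    )


@pytest.fixture
def exp_model():
    """The reference exponential variogram: nugget 5, partial sill 20,
    effective range 20 km."""
    return VariogramModel("exponential", nugget=5.0, partial_sill=20.0,
                          range_a=20000.0)


@pytest.fixture
def small_region():
    return make_region(4, 3, 1000.0)


def make_pts(x, y, values=None, **kw):
    n = len(x)
    vals = pd.DataFrame(values if values else {}, index=range(n))
    return SamplePointSet(ids=np.arange(n), x=np.asarray(x, dtype=float),
                          y=np.asarray(y, dtype=float), values=vals, **kw)
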