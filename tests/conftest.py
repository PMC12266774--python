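import numpy as np
import pytest

from salamech.raster import RasterGrid
from salamech.synthetic import MonthlyClimate
from salamech.bioclim import BioclimStack


def make_grid(values, cell_size=3.0, origin=(0.0, 0.0), nodata=None) -> RasterGrid:
    values = np.asarray(values, float)
    mask = None if nodata is None else np.asarray(nodata, bool)
    return RasterGrid(values, cell_size, origin, mask)


def make_climate(month_values, shape=(8, 8), cell_size=3.0) -> MonthlyClimate:
    """Climate stack from {month: (tmin, tmax)} scalars or arrays."""
    tmins, tmaxs = {}, {}
    for m, (lo, hi) in month_values.items():
        tmins[m] = make_grid(np.broadcast_to(np.asarray(lo, float), shape).copy(), cell_size)
        tmaxs[m] = make_grid(np.broadcast_to(np.asarray(hi, float), shape).copy(), cell_size)
    return MonthlyClimate(tuple(sorted(month_values)), tmins, tmaxs)


def single_var_stack(values, cell_size=3.0, code="BIO1") -> BioclimStack:
    grid = make_grid(values, cell_size)
    return BioclimStack({code: grid}, (3, 4, 5), "2010")


@pytest.fixture(scope="session")
def standard_study():
    """The standard synthetic comparison study, assembled once per session."""
    from salamech.pipeline import standard_config, assemble_study

    cfg = standard_config(seed=0)
    return cfg, assemble_study(cfg)
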