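import numpy as np
import pytest

from geocoverage.data_io import ClusterRecord, CovariateRaster


@pytest.fixture
def toy_records():
    """Five clusters on a 100 km square with region labels and two years."""
    rows = [
        ("a", 10.0, 10.0, 2000, 20, 12, "west"),
        ("b", 30.0, 70.0, 2000, 25, 20, "west"),
        ("c", 60.0, 20.0, 2005, 30, 18, "east"),
        ("d", 80.0, 80.0, 2005, 15, 15, "east"),
        ("e", 50.0, 50.0, 2005, 10, 3, "east"),
    ]
    return [
        ClusterRecord(cluster_id=i, x=x, y=y, lon=x, lat=y, year=yr,
                      n_children=n, n_vaccinated=v, region=reg)
        for i, x, y, yr, n, v, reg in rows
    ]


@pytest.fixture
def small_raster():
    """4×5 raster on [0,50]×[0,40] km, cell 10 km, value = row*10 + col."""
    vals = np.arange(20, dtype=float).reshape(4, 5)
    return CovariateRaster(name="toy", origin_x=0.0, origin_y=0.0,
                           cell_size=10.0, values=vals)
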