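import numpy as np
import pytest
from shapely.geometry import Polygon

from rotadist.synthetic_landscape import LandscapeSpec, generate_fields, split_by_year
from rotadist.vector_io import FieldSite, Layer


@pytest.fixture
def unit_square_site():
    return FieldSite(
        id="sq1",
        geometry=Polygon([(0, 0), (1, 0), (1, 1), (0, 1)]),
        year=2016,
        crop="grain_pea",
    )


@pytest.fixture
def small_spec():
    return LandscapeSpec(n_fields=8, region_diameter_m=12_000, seed=5, years=(2015, 2016))


@pytest.fixture
def small_landscape(small_spec):
    layer = generate_fields(small_spec)
    return {
        "spec": small_spec,
        "all": layer,
        "previous": split_by_year(layer, 2015),
        "current": split_by_year(layer, 2016),
    }


def make_layer(polys, year=2015, crop="grain_pea", crs="EPSG:25832"):
    sites = [
        FieldSite(id=f"f{i}", geometry=p, year=year, crop=crop) for i, p in enumerate(polys)
    ]
    return Layer(sites=sites, crs_id=crs)


@pytest.fixture
def make_square_layer():
    def _make(centers, half=50.0, year=2015, crop="grain_pea"):
        polys = [
            Polygon(
                [
                    (x - half, y - half),
                    (x + half, y - half),
                    (x + half, y + half),
                    (x - half, y + half),
                ]
            )
            for x, y in centers
        ]
        return make_layer(polys, year=year, crop=crop)

    return _make
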