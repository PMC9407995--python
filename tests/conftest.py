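import numpy as np
import pytest

from greenaccess.access import DemandCell, Park, TravelTimeMatrix
from greenaccess.synthetic import CityConfig, generate_city


@pytest.fixture(scope="session")
def small_city():
    """A 10x10 city with a handful of parks, fixed seed."""
    cfg = CityConfig(
        grid_extent=10,
        population_total=50_000,
        n_parks_by_type={"comprehensive": 1, "theme": 1, "community": 3, "amusement": 3},
        seed=42,
    )
    return generate_city(cfg)


def make_toy_instance(S, P, T, mode="walking", t0=15.0):
    """Assemble aligned Park/DemandCell/TravelTimeMatrix objects from raw arrays.

    ``S`` park capacities in persons (converted to comprehensive-park areas),
    ``P`` cell populations, ``T`` a (cells x parks) minutes matrix.
    """
    parks = [
        Park(f"P{j}", "comprehensive", area_m2=s * 60.0, entrances=[[0.0, 0.0]])
        for j, s in enumerate(S)
    ]
    cells = [
        DemandCell(f"C{i}", x=0.0, y=0.0, population=float(p), street_id="S0")
        for i, p in enumerate(P)
    ]
    ttm = TravelTimeMatrix(
        mode, np.asarray(T, dtype=float),
        [c.id for c in cells], [p.id for p in parks], t0=t0,
    )
    return cells, parks, ttm
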