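import numpy as np
import pytest
from shapely.geometry import box

from chorotypes import (
    GradientSpec,
    ScanParams,
    SpeciesRange,
    build_network,
    kreft_jetz_gradient,
    scan_all,
)

SOUTH = frozenset(f"S{k}" for k in range(1, 16))
NORTH = frozenset(f"N{k}" for k in range(16, 31))


def random_box_community(rng: np.random.Generator, n_species: int):
    """Random overlapping rectangle community for oracle comparisons."""
    ranges = []
    for i in range(n_species):
        x, y = rng.uniform(0, 12, size=2)
        w, h = rng.uniform(1, 10, size=2)
        ranges.append(SpeciesRange(f"sp{i}", box(x, y, x + w, y + h)))
    return ranges


@pytest.fixture()
def bars():
    """Three 1-unit-tall bars: A=[0,10], B=[0,12], C=[2,14] along x.

    Hand-computed congruences: C_S(A,B) = 100/120 = 0.8333,
    C_S(B,C) = 100/144 = 0.69444, C_S(A,C) = 64/120 = 0.53333.
    """
    return [
        SpeciesRange("A", box(0, 0, 10, 1)),
        SpeciesRange("B", box(0, 0, 12, 1)),
        SpeciesRange("C", box(2, 0, 14, 1)),
    ]


@pytest.fixture()
def bars_net(bars):
    return build_network(bars, store_floor=0.1)


@pytest.fixture()
def bars_map(bars):
    return {r.species_id: r for r in bars}


@pytest.fixture(scope="session")
def gradient():
    return kreft_jetz_gradient(GradientSpec())


@pytest.fixture(scope="session")
def gradient_map(gradient):
    return {r.species_id: r for r in gradient}


@pytest.fixture(scope="session")
def gradient_net(gradient):
    return build_network(gradient, store_floor=0.1)


@pytest.fixture(scope="session")
def gradient_results(gradient_net, gradient_map):
    """Scans of all 30 references at each depth cap used in the study."""
    refs = list(gradient_map)
    return {
        depth: scan_all(refs, gradient_net, gradient_map, ScanParams(max_depth=depth))
        for depth in (3, 5, 7, 10)
    }
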