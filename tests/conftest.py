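import numpy as np
import pytest
import shapely

from greenrisk.simulate import make_lattice
from greenrisk.spatial import AreaUnitSet, build_adjacency


def tiny_lattice(rows: int, cols: int, cell_size: float = 1.0) -> AreaUnitSet:
    """Lattice helper without the >=4-unit floor of the simulator."""
    ids, geoms = [], []
    for r in range(rows):
        for c in range(cols):
            ids.append(f"u{r * cols + c:03d}")
            x0, y0 = c * cell_size, -r * cell_size
            geoms.append(shapely.box(x0, y0 - cell_size, x0 + cell_size, y0))
    return AreaUnitSet(unit_ids=ids, geometries=geoms)


@pytest.fixture(scope="session")
def lattice5_queen():
    return build_adjacency(make_lattice(5, 5), rule="queen")


@pytest.fixture(scope="session")
def lattice5_rook():
    return build_adjacency(make_lattice(5, 5), rule="rook")


@pytest.fixture()
def rng():
    return np.random.default_rng(20_260_928)
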