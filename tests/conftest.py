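import numpy as np
import pytest

from beardsim import CellType, ColonyLattice


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def build_lattice(cells, n_c=20, n_z=10, r_i=3):
    """A small lattice with the given {(x, y, z): CellType} contents."""
    lat = ColonyLattice(n_c=n_c, n_z=n_z, r_i=r_i)
    for pos, cell in cells.items():
        lat.place(pos, cell)
    return lat


def random_lattice(rng, n_c=12, n_z=8, r_i=3, fill=0.3):
    """A lattice with sites occupied independently at rate ``fill``."""
    lat = ColonyLattice(n_c=n_c, n_z=n_z, r_i=r_i)
    mask = rng.random((n_c, n_c, n_z)) < fill
    for x, y, z in zip(*np.nonzero(mask)):
        cell = CellType.SLOW if rng.random() < 0.5 else CellType.FAST
        lat.place((int(x), int(y), int(z)), cell)
    return lat
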