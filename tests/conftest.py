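import numpy as np
import pytest

from hyperview import density_surface as ds
from hyperview import fixtures


@pytest.fixture(scope="session")
def element_table():
    from hyperview.topology import ElementTable

    return ElementTable.load_default()


@pytest.fixture(scope="session")
def single_atom_grid():
    """Gaussian density of one r=1.5 A atom at the origin, default params."""
    mol = fixtures.make_diatomic(d=50.0)
    mol.atoms = mol.atoms[:1]
    grid = ds.compute_density_grid(mol, np.array([1.5]), ds.SurfaceParams())
    return grid


@pytest.fixture(scope="session")
def point_charge_64():
    return fixtures.make_point_charge_grid(q=1.0, n=64, extent=8.0)


@pytest.fixture(scope="session")
def charge_center_64():
    return fixtures.point_charge_center(n=64, extent=8.0)
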