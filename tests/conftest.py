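"""Shared fixtures: synthetic crystals, parameter sets and lattice sums."""

import numpy as np
import pytest

from synthonic.fixtures import (cubic_crystal, default_potential,
                                dipole_charges, dipole_crystal,
                                dipole_potential, water_charges,
                                water_molecule, zwitterion_charges,
                                zwitterion_crystal)
from synthonic.lattice import lattice_sum
from synthonic.potential import ChargeSet


@pytest.fixture(scope="session")
def zwit_structure():
    return zwitterion_crystal()


@pytest.fixture(scope="session")
def zwit_params():
    return default_potential()


@pytest.fixture(scope="session")
def zwit_charges():
    return ChargeSet(zwitterion_charges())


@pytest.fixture(scope="session")
def zwit_result(zwit_structure, zwit_params, zwit_charges):
    return lattice_sum(zwit_structure, zwit_params, zwit_charges, r_max=18.0)


@pytest.fixture(scope="session")
def dipole_setup():
    return (dipole_crystal(), dipole_potential(), ChargeSet(dipole_charges()))


@pytest.fixture(scope="session")
def cubic_setup():
    return (cubic_crystal(), default_potential(), ChargeSet({"X1": 0.0}))


@pytest.fixture(scope="session")
def water_probe():
    from synthonic.surface import probe_instance
    wm = water_molecule()
    return probe_instance(wm, coords=np.asarray(wm.frac))


@pytest.fixture(scope="session")
def merged_charges():
    merged = dict(zwitterion_charges())
    merged.update(water_charges())
    return ChargeSet(merged)
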