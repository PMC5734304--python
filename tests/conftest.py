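"""Shared fixtures: all test inputs are generated synthetically."""

import numpy as np
import pytest

from xtalkit.cell_symmetry import Grid_sampling, Spacegroup, make_cell
from xtalkit.synthetic import make_toy_model, toy_minimol

ALL_SPACEGROUPS = ["P1", "P-1", "P21", "C2", "P212121", "P43212", "P6322"]


@pytest.fixture
def cubic_cell():
    return make_cell(10, 10, 10)


@pytest.fixture
def ortho_cell():
    return make_cell(16, 18, 20)


@pytest.fixture
def mono_cell():
    return make_cell(6.2, 11.1, 7.4, 90, 103.4, 90)


@pytest.fixture
def p1():
    return Spacegroup.from_name("P1")


@pytest.fixture
def p212121():
    return Spacegroup.from_name("P212121")


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def toy_model(ortho_cell):
    return make_toy_model(ortho_cell, n_atoms=5, rng=7)


@pytest.fixture
def toy_mol(ortho_cell, toy_model):
    return toy_minimol(ortho_cell, toy_model, "P1")


def random_cell(rng):
    """A random but non-degenerate triclinic cell."""
    a, b, c = rng.uniform(8, 40, 3)
    alpha, beta, gamma = rng.uniform(70, 110, 3)
    return make_cell(a, b, c, alpha, beta, gamma)
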