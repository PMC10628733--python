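import numpy as np
import pytest

from stoichdir import StoichiometryMatrix


@pytest.fixture
def simple_matrix() -> StoichiometryMatrix:
    """4 reactants x 6 reactions, rank 4, nullity 2, every column both-signed."""
    entries = np.array([
        [-1, 0, 0, 2, -1, 0],
        [2, -1, 0, 0, 0, -1],
        [0, 1, -1, 0, 1, 0],
        [0, 0, 1, -1, 0, 1],
    ])
    return StoichiometryMatrix(entries, reactant_ids=list("ABCD"),
                               reaction_ids=[f"r{i}" for i in range(1, 7)])


@pytest.fixture
def positive_row_matrix() -> StoichiometryMatrix:
    """A network whose primitive null basis has row 0 = (2, 3): reaction r1's
    sequence terms are all > 1, forcing an unambiguous forward annotation."""
    entries = np.array([
        [-3, 2, 2, 2, 0, 1],
        [2, -3, -1, -2, 2, 1],
        [0, 1, 0, 1, -2, -2],
        [0, 2, 0, -1, -1, -1],
    ])
    return StoichiometryMatrix(entries, reactant_ids=list("ABCD"),
                               reaction_ids=[f"r{i}" for i in range(1, 7)])


@pytest.fixture
def half_reaction_matrix(simple_matrix) -> StoichiometryMatrix:
    """6 columns where r4 = -r1, r5 = -r2, r6 = -r3."""
    cols = simple_matrix.entries[:, :3]
    entries = np.hstack([cols, -cols])
    return StoichiometryMatrix(entries, reactant_ids=list("ABCD"),
                               reaction_ids=[f"r{i}" for i in range(1, 7)])
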