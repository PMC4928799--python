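import numpy as np
import pytest

from orthoconserve.datatypes import GeneSet, OrthologMatrix, SpeciesPanel


@pytest.fixture
def tiny_panel() -> SpeciesPanel:
    species = ("a_01", "a_02", "b_01", "b_02", "b_03")
    clade_of = {"a_01": "alpha", "a_02": "alpha", "b_01": "beta", "b_02": "beta", "b_03": "beta"}
    return SpeciesPanel(species, clade_of, reference_species="ref")


@pytest.fixture
def tiny_matrix(tiny_panel) -> OrthologMatrix:
    # hand-tallied counts: g0=0, g1=2 (alpha only), g2=3 (beta only), g3=5
    presence = np.array(
        [
            [0, 0, 0, 0, 0],
            [1, 1, 0, 0, 0],
            [0, 0, 1, 1, 1],
            [1, 1, 1, 1, 1],
        ],
        dtype=bool,
    )
    return OrthologMatrix(("g0", "g1", "g2", "g3"), tiny_panel.species, presence)


@pytest.fixture
def staircase_matrix() -> OrthologMatrix:
    # six genes with counts 0..5 over five species (g5 saturates at 5)
    presence = np.zeros((6, 5), dtype=bool)
    for i in range(6):
        presence[i, : min(i, 5)] = True
    return OrthologMatrix(
        tuple(f"g{i}" for i in range(6)), tuple(f"s{j}" for j in range(5)), presence
    )


@pytest.fixture
def directed_set() -> GeneSet:
    genes = ("g0", "g1", "g2", "g3")
    return GeneSet("deg", genes, {"g0": "up", "g1": "down", "g2": "up", "g3": "up"})
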