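"""Shared fixtures: tiny abstract ensembles and idealized 3D structures."""

import pytest

from rnaconsensus.annotation import Interaction, ModelInteractionSet
from rnaconsensus.helix import build_duplex
from rnaconsensus.model_io import ResidueRef


def make_residues(n, chain="A", bases="G"):
    """n residues on one chain; bases cycles over the given string."""
    return [
        ResidueRef(chain, k + 1, "", bases[k % len(bases)]) for k in range(n)
    ]


@pytest.fixture(scope="session")
def residues8():
    return make_residues(8, bases="GCAU")


@pytest.fixture
def abc_ensemble(residues8):
    """The three-model ensemble A={x,y}, B={x}, C={x,z} with memberships
    x: 1, y: 1/3, z: 1/3."""
    r = residues8
    x = Interaction("canonical_pair", r[0], r[7])
    y = Interaction("canonical_pair", r[1], r[6])
    z = Interaction("stacking", r[2], r[3])
    sets = [
        ModelInteractionSet("A", [x, y]),
        ModelInteractionSet("B", [x]),
        ModelInteractionSet("C", [x, z]),
    ]
    return sets, {"x": x, "y": y, "z": z}


@pytest.fixture(scope="session")
def duplex6():
    """Idealized six-pair A-form duplex (chains A and B)."""
    return build_duplex("GGCAGC", model_id="duplex6")


@pytest.fixture(scope="session")
def duplex4():
    return build_duplex("GCGC", model_id="duplex4")
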