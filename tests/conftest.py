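import warnings

import numpy as np
import pytest

from bios2net.features import annotate, featurize
from bios2net.structure_io import parse_structure, zero_pssm
from bios2net.synthetic import (
    FoldSpec,
    coil,
    generate_structure,
    hairpin,
    helix,
)


@pytest.fixture(scope="session")
def helix_structure():
    """Ideal 15-residue α-helix flanked by short coils, no coordinate noise."""
    spec = FoldSpec("helix15", [helix(15), coil(3), helix(5)], noise_sigma=0.0)
    return parse_structure(generate_structure(spec, seed=41), identifier="helix15")


@pytest.fixture(scope="session")
def hairpin_structure():
    """Ideal antiparallel β-hairpin with two 7-residue strands, no noise."""
    spec = FoldSpec("hp7", [coil(3), hairpin(7), coil(3)], noise_sigma=0.0)
    return parse_structure(generate_structure(spec, seed=42), identifier="hp7")


@pytest.fixture(scope="session")
def helix_cloud(helix_structure):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        annotation = annotate(helix_structure, asa_points=240)
        return featurize(helix_structure, zero_pssm(helix_structure.length),
                         annotation, label="helix15")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
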