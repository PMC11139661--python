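import numpy as np
import pytest

from blastonet.meshes import Embryo
from blastonet.synthetic import canonical_centers, icosphere

CANONICAL = {
    "tetrahedral": ((0, 0, 0, 4), "Tetrahedral", 3.0),
    "pseudotetrahedral": ((0, 0, 2, 2), "Pseudotetrahedral", 2.5),
    "planar": ((0, 0, 4, 0), "Planar", 2.0),
    "closed_y": ((0, 1, 2, 1), "Closed Y", 2.0),
    "linear": ((0, 2, 2, 0), "Linear", 1.5),
}


def make_sphere(radius=1.0, center=(0, 0, 0), subdivisions=2, cell_id="cell"):
    return icosphere(radius, center, subdivisions, cell_id)


def make_embryo(name, radius=1.0, subdivisions=2):
    centers = canonical_centers(name, radius)
    meshes = tuple(
        icosphere(radius, c, subdivisions, f"cell_{i}") for i, c in enumerate(centers)
    )
    return Embryo(embryo_id=name, blastomeres=meshes)


@pytest.fixture(scope="session")
def unit_sphere():
    return make_sphere()


@pytest.fixture(scope="session")
def canonical_embryos():
    return {name: make_embryo(name) for name in CANONICAL}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
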