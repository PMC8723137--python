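import numpy as np
import pytest

from voxscreen.structures import AnnotatedComplex, Atom
from voxscreen.synthetic import SyntheticComplexSpec, make_native_complex


def make_toy_complex(ab_coords, ag_coords, exposure=1.0, ab_chain="H", ag_chain="A"):
    """Hand-placed complex: one carbon CA atom per residue, uniform exposure."""
    atoms, serial = [], 1
    for i, c in enumerate(ab_coords):
        atoms.append(Atom(serial, "C", "CA", np.asarray(c, float),
                          (ab_chain, i + 1, ""), "ALA", True))
        serial += 1
    for i, c in enumerate(ag_coords):
        atoms.append(Atom(serial, "C", "CA", np.asarray(c, float),
                          (ag_chain, i + 1, ""), "GLY", True))
        serial += 1
    cx = AnnotatedComplex(
        atoms=atoms,
        role_of_chain={ab_chain: "antibody_heavy", ag_chain: "antigen"},
    )
    cx.rel_exposure = {k: exposure for k in cx.residue_keys()}
    return cx


@pytest.fixture(scope="session")
def native_pair():
    """One synthetic native complex with its planted contact set (seed 1)."""
    return make_native_complex(SyntheticComplexSpec(), np.random.default_rng(1))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
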