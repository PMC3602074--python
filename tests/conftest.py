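import numpy as np
import pytest
from hypothesis import settings

from dnaface.core import Atom, Chain, Residue, Structure

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def pseudo_cluster(coords, radius=1.7, chain_id="X", res_name="UNK"):
    """Structure of bare carbon pseudo-atoms with assigned radii."""
    chain = Chain(chain_id)
    res = Residue(res_name, 1)
    for i, c in enumerate(coords):
        res.atoms.append(Atom(i + 1, f"C{i + 1}", "C",
                              np.asarray(c, float), radius=radius))
    chain.residues.append(res)
    return Structure(chains=[chain])


@pytest.fixture(scope="session")
def toy_complex():
    """Contact-rich peptide-ssDNA complex with brute-force manifest."""
    from dnaface.synth import ToyComplexSpec, make_toy_complex

    return make_toy_complex(ToyComplexSpec(approach_distance=2.8, seed=7))


@pytest.fixture(scope="session")
def toy_complex_hb():
    """Toy complex whose manifest contains a cross-side hydrogen bond."""
    from dnaface.synth import ToyComplexSpec, make_toy_complex

    return make_toy_complex(ToyComplexSpec(approach_distance=2.8, seed=11))


@pytest.fixture(scope="session")
def tables():
    from dnaface.synth import packaged_tables

    return packaged_tables()
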