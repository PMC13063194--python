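import numpy as np
import pytest

from fragdecomp import PairwiseBackend, make_complex


@pytest.fixture(scope="session")
def complex_setup():
    """A seeded synthetic protein-ligand complex shared across tests."""
    structure, params, region_map = make_complex(
        site_residue=3, contact_distance=3.5, seed=1)
    ligand = next(r for r in structure.residues if r.kind == "ligand")
    return {
        "structure": structure,
        "params": params,
        "region_map": region_map,
        "ligand": ligand,
        "backend": PairwiseBackend(params),
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
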