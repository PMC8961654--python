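import numpy as np
import pytest

from pepspot import structio, threading
from pepspot.fixtures import ToyComplexSpec, make_toy_complex


@pytest.fixture(scope="session")
def blosum62():
    return threading.load_matrix("BLOSUM62")


@pytest.fixture(scope="session")
def toy_spec():
    # Receptor GLSDKGYR: L hydrophobic, D/K/R ionic, G/S/Y neither.
    return ToyComplexSpec(
        receptor_seq="GLSDKGYR",
        peptide_seq="PEATAPPEE",
        contact_plan=((1, 0), (3, 1), (4, 1), (2, 2)),
        seed=11,
    )


@pytest.fixture(scope="session")
def toy_pdb(toy_spec):
    return make_toy_complex(toy_spec)


@pytest.fixture(scope="session")
def toy_complex(toy_pdb):
    return structio.load_complex(toy_pdb, ["A"], "B")


def random_residue(rng, chain_id, seq_num, letter="A", n_atoms=None, scale=10.0):
    """A residue with random heavy atoms, for oracle comparisons."""
    from pepspot.modeling import AA3

    n = int(n_atoms if n_atoms is not None else rng.integers(1, 6))
    names = ["N", "CA", "C", "O", "CB"][:n]
    atoms = tuple(
        (name, *(float(c) for c in rng.uniform(-scale, scale, size=3)))
        for name in names
    )
    return structio.ResidueRecord(chain_id, seq_num, "", AA3.get(letter, "UNK"),
                                  letter, atoms)
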