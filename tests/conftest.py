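import numpy as np
import pytest

from exthmmm.core import DomainDefinitions, MolecularSystem, SelectionSpec
from exthmmm.fixtures import make_toy_fva


def ca_chain(n_residues: int, start: int = 1, spacing: float = 3.8,
             name: str = "CA") -> MolecularSystem:
    """Minimal straight-chain test system: one named atom per residue."""
    n = n_residues
    return MolecularSystem(
        atom_name=np.array([name] * n, dtype=object),
        residue_number=np.arange(start, start + n),
        residue_name=np.array(["ALA"] * n, dtype=object),
        segment_id=np.array(["PROT"] * n, dtype=object),
        element=np.array(["C"] * n, dtype=object),
        coordinates=np.column_stack([
            np.arange(n) * spacing, np.zeros(n), np.zeros(n)
        ]),
    )


@pytest.fixture(scope="session")
def toy_protein():
    return make_toy_fva(seed=2)


@pytest.fixture(scope="session")
def full_domain_defs():
    """Domain definitions including the A1/A3 blocks of the toy layout."""
    dd = DomainDefinitions()
    dd.domains = dict(dd.domains)
    dd.domains["A1"] = SelectionSpec("A1", [(29, 303)], ["CA"])
    dd.domains["A3"] = SelectionSpec("A3", [(1546, 1877)], ["CA"])
    return dd


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
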