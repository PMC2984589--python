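import numpy as np
import pytest

from ballcore.forcefield import AmberForceField, ForceFieldParameters
from ballcore.model import Atom, MolecularSystem, Residue
from ballcore.prep import FragmentDatabase


@pytest.fixture(scope="session")
def db():
    return FragmentDatabase()


@pytest.fixture(scope="session")
def params():
    return ForceFieldParameters.from_file()


def make_water(stretch: float = 0.0) -> MolecularSystem:
    """A single water; optionally one O-H bond stretched by *stretch* A."""
    system = MolecularSystem()
    chain = system.add_chain()
    res = chain.add_residue(Residue("HOH", 1))
    o = res.add_atom(Atom("O", "O", (0.0, 0.0, 0.0)))
    h1 = res.add_atom(Atom("H1", "H", (0.96 + stretch, 0.0, 0.0)))
    h2 = res.add_atom(Atom("H2", "H", (-0.2405, 0.9295, 0.0)))
    system.add_bond(o, h1)
    system.add_bond(o, h2)
    return system


@pytest.fixture
def water():
    return make_water()


@pytest.fixture
def stretched_water():
    return make_water(stretch=0.3)


def water_ff(system) -> AmberForceField:
    return AmberForceField().setup(system)


def random_chain_system(rng: np.random.Generator, n_residues: int = 2,
                        atoms_per_residue: int = 4) -> MolecularSystem:
    """A random (chemically meaningless) chain system for I/O and geometry tests."""
    elements = ["C", "N", "O", "S", "H"]
    system = MolecularSystem()
    chain = system.add_chain(id="A")
    serial = 1
    prev_atom = None
    for r in range(n_residues):
        res = chain.add_residue(Residue("UNK", r + 1))
        for a in range(atoms_per_residue):
            elem = elements[int(rng.integers(len(elements)))]
            atom = Atom(f"{elem}{a + 1}", elem, rng.uniform(-20, 20, 3), serial=serial)
            res.add_atom(atom)
            if prev_atom is not None and rng.random() < 0.7:
                system.add_bond(prev_atom, atom)
            prev_atom = atom
            serial += 1
    return system
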