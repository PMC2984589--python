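"""Hierarchical molecular data model.

The model is a rooted hierarchy ``MolecularSystem -> Chain -> Residue -> Atom``
plus a set of free (non-polymer) :class:`Molecule` containers, together with a
bond graph stored on the atoms themselves.  Every other part of the toolkit —
I/O, structure preparation, selections, force field, builders — consumes and
produces this model.

Traversal order is *document order*: chains in insertion order, then their
residues, then their atoms; free molecules after all chains.  Two traversals of
the same system always yield the same node sequence.

Atom identity is by object reference; serial numbers are I/O metadata only.
Coordinates are in Angstrom, charges in elementary charges.
"""

from __future__ import annotations

import copy as _copy
from typing import Callable, Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "SINGLE",
    "DOUBLE",
    "TRIPLE",
    "AROMATIC",
    "PERIODIC_TABLE",
    "Element",
    "Atom",
    "Bond",
    "Residue",
    "Chain",
    "Molecule",
    "MolecularSystem",
    "Processor",
    "CountingProcessor",
    "ProcessorError",
]

# Bond order codes.  AROMATIC deliberately matches the MDL V2000 code 4.
SINGLE = 1
DOUBLE = 2
TRIPLE = 3
AROMATIC = 4


class Element:
    """A chemical element: symbol, atomic number, mass (amu)."""

    __slots__ = ("symbol", "number", "mass")

    def __init__(self, symbol: str, number: int, mass: float):
        self.symbol = symbol
        self.number = number
        self.mass = mass

    def __repr__(self) -> str:  # pragma: no cover
        return f"Element({self.symbol})"


_ELEMENTS = [
    ("H", 1, 1.008), ("B", 5, 10.811), ("C", 6, 12.011), ("N", 7, 14.007),
    ("O", 8, 15.999), ("F", 9, 18.998), ("Na", 11, 22.990), ("Mg", 12, 24.305),
    ("P", 15, 30.974), ("S", 16, 32.066), ("Cl", 17, 35.453), ("K", 19, 39.098),
    ("Ca", 20, 40.078), ("Fe", 26, 55.845), ("Zn", 30, 65.38),
    ("Br", 35, 79.904), ("I", 53, 126.904),
]

#: Bundled periodic table, keyed by canonical symbol.
PERIODIC_TABLE: dict[str, Element] = {s: Element(s, n, m) for s, n, m in _ELEMENTS}


def normalize_element(symbol: str) -> str:
    """Return the canonical symbol for *symbol* (case-insensitive).

    Raises ``ValueError`` for symbols outside the bundled periodic table.
    """
    sym = symbol.strip().capitalize()
    if sym not in PERIODIC_TABLE:
        raise ValueError(f"unknown element symbol: {symbol!r}")
    return sym


class Bond:
    """An undirected bond between two atoms of the same system."""

    __slots__ = ("atom_a", "atom_b", "order")

    def __init__(self, atom_a: "Atom", atom_b: "Atom", order: int = SINGLE):
        if atom_a is atom_b:
            raise ValueError("bond endpoints must differ")
        if order not in (SINGLE, DOUBLE, TRIPLE, AROMATIC):
            raise ValueError(f"invalid bond order: {order!r}")
        self.atom_a = atom_a
        self.atom_b = atom_b
        self.order = order

    def partner(self, atom: "Atom") -> "Atom":
        """The other endpoint relative to *atom*."""
        if atom is self.atom_a:
            return self.atom_b
        if atom is self.atom_b:
            return self.atom_a
        raise ValueError("atom is not an endpoint of this bond")

    def __repr__(self) -> str:  # pragma: no cover
        return f"Bond({self.atom_a.name}-{self.atom_b.name}, order={self.order})"


class Atom:
    """A single atom.

    Positions are float64 3-vectors in Angstrom.  ``selected`` is the flag set
    by selection expressions and consumed by minimizers/dynamics.
    """

    __slots__ = (
        "serial", "name", "element", "position", "partial_charge",
        "formal_charge", "selected", "occupancy", "temp_factor",
        "type_name", "bonds", "hetero", "aromatic",
    )

    def __init__(
        self,
        name: str,
        element: str,
        position: Sequence[float] = (0.0, 0.0, 0.0),
        serial: int = 0,
        partial_charge: float = 0.0,
        formal_charge: int = 0,
        occupancy: float = 1.0,
        temp_factor: float = 0.0,
        hetero: bool = False,
    ):
        self.name = name
        self.element = normalize_element(element)
        pos = np.asarray(position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom position must be a finite 3-vector, got {position!r}")
        self.position = pos
        self.serial = serial
        self.partial_charge = partial_charge
        self.formal_charge = formal_charge
        self.selected = False
        self.occupancy = occupancy
        self.temp_factor = temp_factor
        self.type_name: Optional[str] = None  # force-field atom type
        self.bonds: list[Bond] = []
        self.hetero = hetero
        self.aromatic = False

    @property
    def mass(self) -> float:
        return PERIODIC_TABLE[self.element].mass

    def bonded_atoms(self) -> list["Atom"]:
        return [b.partner(self) for b in self.bonds]

    def bond_to(self, other: "Atom") -> Optional[Bond]:
        for b in self.bonds:
            if b.partner(self) is other:
                return b
        return None

    def __repr__(self) -> str:  # pragma: no cover
        return f"Atom({self.name!r}, {self.element})"


class Residue:
    """A residue: named, numbered group of atoms inside a chain."""

    __slots__ = ("name", "id", "insertion_code", "atoms",
                 "is_n_terminal", "is_c_terminal")

    def __init__(self, name: str, id: int = 1, insertion_code: str = ""):
        self.name = name
        self.id = id
        self.insertion_code = insertion_code
        self.atoms: list[Atom] = []
        self.is_n_terminal = False
        self.is_c_terminal = False

    def add_atom(self, atom: Atom) -> Atom:
        self.atoms.append(atom)
        return atom

    def atom_by_name(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def __repr__(self) -> str:  # pragma: no cover
        return f"Residue({self.name} {self.id}{self.insertion_code})"


class Chain:
    """An ordered sequence of residues with a one-character identifier."""

    __slots__ = ("id", "residues")

    def __init__(self, id: str = "A"):
        self.id = id
        self.residues: list[Residue] = []

    def add_residue(self, residue: Residue) -> Residue:
        self.residues.append(residue)
        return residue

    def atoms(self) -> Iterator[Atom]:
        for r in self.residues:
            yield from r.atoms

    def __repr__(self) -> str:  # pragma: no cover
        return f"Chain({self.id}, {len(self.residues)} residues)"


class Molecule:
    """A free (non-polymer) molecule: a flat, named atom container."""

    __slots__ = ("name", "atoms")

    def __init__(self, name: str = ""):
        self.name = name
        self.atoms: list[Atom] = []

    def add_atom(self, atom: Atom) -> Atom:
        self.atoms.append(atom)
        return atom


class ProcessorError(RuntimeError):
    """A processor raised; carries the node it was visiting."""

    def __init__(self, node, cause: BaseException):
        super().__init__(f"processor failed at {node!r}: {cause}")
        self.node = node
        self.cause = cause


class Processor:
    """Visitor over a molecular system in deterministic document order.

    Subclasses override any of the ``visit_*`` hooks; defaults are no-ops so a
    plain :class:`Processor` leaves the system untouched.  A hook returning
    ``False`` from ``visit_atom`` requests deletion of that atom (dangling
    bonds are cleaned up by :meth:`MolecularSystem.apply`).
    """

    def visit_system(self, system: "MolecularSystem"):
        pass

    def visit_chain(self, chain: Chain):
        pass

    def visit_residue(self, residue: Residue):
        pass

    def visit_molecule(self, molecule: Molecule):
        pass

    def visit_atom(self, atom: Atom):
        pass

    def __call__(self, system: "MolecularSystem") -> "MolecularSystem":
        return system.apply(self)


class CountingProcessor(Processor):
    """Counts visited nodes of each kind (test/diagnostic helper)."""

    def __init__(self):
        self.systems = self.chains = self.residues = self.molecules = self.atoms = 0

    def visit_system(self, system):
        self.systems += 1

    def visit_chain(self, chain):
        self.chains += 1

    def visit_residue(self, residue):
        self.residues += 1

    def visit_molecule(self, molecule):
        self.molecules += 1

    def visit_atom(self, atom):
        self.atoms += 1

    @property
    def total(self) -> int:
        return self.systems + self.chains + self.residues + self.molecules + self.atoms


class MolecularSystem:
    """Root container: ordered chains, free molecules, and the bond graph."""

    def __init__(self, name: str = ""):
        self.name = name
        self.chains: list[Chain] = []
        self.molecules: list[Molecule] = []

    # -- construction -----------------------------------------------------

    def add_chain(self, chain: Optional[Chain] = None, id: str = "A") -> Chain:
        if chain is None:
            chain = Chain(id)
        self.chains.append(chain)
        return chain

    def add_molecule(self, molecule: Optional[Molecule] = None, name: str = "") -> Molecule:
        if molecule is None:
            molecule = Molecule(name)
        self.molecules.append(molecule)
        return molecule

    def add_bond(self, a: Atom, b: Atom, order: int = SINGLE) -> Bond:
        """Create a bond between *a* and *b*; idempotent per atom pair.

        If the pair is already bonded the existing bond is returned unchanged.
        """
        existing = a.bond_to(b)
        if existing is not None:
            return existing
        bond = Bond(a, b, order)
        a.bonds.append(bond)
        b.bonds.append(bond)
        return bond

    def remove_bond(self, bond: Bond) -> None:
        bond.atom_a.bonds.remove(bond)
        bond.atom_b.bonds.remove(bond)

    def remove_atom(self, atom: Atom) -> None:
        """Delete *atom* and every bond incident to it."""
        for bond in list(atom.bonds):
            self.remove_bond(bond)
        for chain in self.chains:
            for res in chain.residues:
                if atom in res.atoms:
                    res.atoms.remove(atom)
                    return
        for mol in self.molecules:
            if atom in mol.atoms:
                mol.atoms.remove(atom)
                return

    # -- traversal --------------------------------------------------------

    def atoms(self) -> Iterator[Atom]:
        """All atoms in document order (chains first, then free molecules)."""
        for chain in self.chains:
            for res in chain.residues:
                yield from res.atoms
        for mol in self.molecules:
            yield from mol.atoms

    def residues(self) -> Iterator[Residue]:
        for chain in self.chains:
            yield from chain.residues

    def bonds(self) -> Iterator[Bond]:
        """Every bond exactly once, in document order of its first endpoint."""
        seen: set[int] = set()
        for atom in self.atoms():
            for bond in atom.bonds:
                if id(bond) not in seen:
                    seen.add(id(bond))
                    yield bond

    def atom_count(self) -> int:
        return sum(1 for _ in self.atoms())

    def coordinates(self) -> np.ndarray:
        """(N, 3) array of positions in traversal order (a copy)."""
        atoms = list(self.atoms())
        if not atoms:
            return np.zeros((0, 3))
        return np.array([a.position for a in atoms])

    def set_coordinates(self, coords: np.ndarray) -> None:
        atoms = list(self.atoms())
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        for atom, row in zip(atoms, coords):
            atom.position = row.copy()

    # -- processor protocol ----------------------------------------------

    def apply(self, proc) -> "MolecularSystem":
        """Apply *proc* to every node in document order.

        *proc* may be a :class:`Processor` or any callable taking the system.
        ``visit_atom`` returning ``False`` deletes the atom afterwards.
        """
        if not isinstance(proc, Processor):
            if callable(proc):
                proc(self)
                return self
            raise TypeError("proc must be a Processor or callable")

        doomed: list[Atom] = []

        def _visit(fn, node):
            try:
                return fn(node)
            except ProcessorError:
                raise
            except Exception as exc:
                raise ProcessorError(node, exc) from exc

        _visit(proc.visit_system, self)
        for chain in list(self.chains):
            _visit(proc.visit_chain, chain)
            for res in list(chain.residues):
                _visit(proc.visit_residue, res)
                for atom in list(res.atoms):
                    if _visit(proc.visit_atom, atom) is False:
                        doomed.append(atom)
        for mol in list(self.molecules):
            _visit(proc.visit_molecule, mol)
            for atom in list(mol.atoms):
                if _visit(proc.visit_atom, atom) is False:
                    doomed.append(atom)
        for atom in doomed:
            self.remove_atom(atom)
        return self

    # -- selection --------------------------------------------------------

    def deselect(self) -> None:
        """Clear every atom's selection flag."""
        for atom in self.atoms():
            atom.selected = False

    def selected_atoms(self) -> list[Atom]:
        return [a for a in self.atoms() if a.selected]

    # -- copying ----------------------------------------------------------

    def copy(self) -> "MolecularSystem":
        """Deep, independent copy (bond graph re-created on the copies)."""
        return _copy.deepcopy(self)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"MolecularSystem({self.name!r}, {len(self.chains)} chains, "
                f"{self.atom_count()} atoms)")
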