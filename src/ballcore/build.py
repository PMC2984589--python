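"""Molecule generation: peptides from torsions, SMILES (subset), bond orders.

The peptide builder extends a chain residue-by-residue with NeRF-style
internal-coordinate placement, driven by the bundled fragment templates and
the caller's phi/psi/omega angles.  The SMILES reader covers the organic
subset (no stereo, no isotopes); aromatic input is kekulized and implicit
hydrogens are materialized.  Bond-order assignment is an exact
branch-and-bound over {1,2,3} per bond against an atomic valence-penalty
table, results sorted by ascending total penalty.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .geometry import place_from_internal
from .model import (AROMATIC, Atom, Bond, Chain, Molecule, MolecularSystem,
                    PERIODIC_TABLE, Residue)
from .prep import FragmentDatabase

__all__ = [
    "TorsionSpec",
    "build_peptide",
    "SmilesError",
    "parse_smiles",
    "fill_valence",
    "AtomPenaltyTable",
    "BondOrderAssignment",
    "assign_bond_orders",
    "kekulize",
    "KekulizeError",
    "perceive_aromaticity",
    "ONE_TO_THREE",
]

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


# ---------------------------------------------------------------------------
# peptide builder
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TorsionSpec:
    """Backbone torsions per residue; a single pair broadcasts to all."""

    phi: tuple[float, ...]
    psi: tuple[float, ...]
    omega: tuple[float, ...]

    @classmethod
    def uniform(cls, phi: float, psi: float, omega: float = 180.0,
                n: int = 1) -> "TorsionSpec":
        return cls((phi,) * n, (psi,) * n, (omega,) * n)

    @classmethod
    def for_sequence(cls, n: int, phi, psi, omega=180.0) -> "TorsionSpec":
        def expand(v):
            if np.isscalar(v):
                return (float(v),) * n
            v = tuple(float(x) for x in v)
            if len(v) == 1:
                return v * n
            if len(v) != n:
                raise ValueError(f"torsion list length {len(v)} != sequence length {n}")
            return v
        spec = cls(expand(phi), expand(psi), expand(omega))
        for angles in (spec.phi, spec.psi, spec.omega):
            for a in angles:
                if not -180.0 < a <= 180.0 and not math.isclose(a, -180.0):
                    raise ValueError(f"torsion {a} outside (-180, 180]")
        return spec


def build_peptide(sequence: str, torsions=None,
                  db: Optional[FragmentDatabase] = None,
                  chain_id: str = "A") -> MolecularSystem:
    """Build an all-atom peptide from a one-letter sequence and torsions.

    *torsions* may be a :class:`TorsionSpec`, a ``(phi, psi)`` pair, or
    ``None`` (extended chain).  Sidechains take template ideal geometry;
    hydrogens are included and bonds built.
    """
    db = db or FragmentDatabase()
    if not sequence:
        raise ValueError("empty sequence")
    for pos, letter in enumerate(sequence):
        if letter.upper() not in ONE_TO_THREE:
            raise ValueError(f"unknown amino-acid letter {letter!r} at position {pos}")
    n = len(sequence)
    if torsions is None:
        spec = TorsionSpec((-180.0,) * n, (180.0,) * n, (180.0,) * n)
    elif isinstance(torsions, TorsionSpec):
        spec = torsions
        if len(spec.phi) == 1 and n > 1:
            spec = TorsionSpec(spec.phi * n, spec.psi * n, spec.omega * n)
    else:
        phi, psi = torsions[0], torsions[1]
        omega = torsions[2] if len(torsions) > 2 else 180.0
        spec = TorsionSpec.for_sequence(n, phi, psi, omega)

    system = MolecularSystem(name=sequence)
    chain = system.add_chain(id=chain_id)
    prev_res: Optional[Residue] = None

    for i, letter in enumerate(sequence.upper()):
        resname = ONE_TO_THREE[letter]
        if n == 1:
            variant = "free"
        elif i == 0:
            variant = "n_terminal"
        elif i == n - 1:
            variant = "c_terminal"
        else:
            variant = "internal"
        tpl = db.get_template(resname, variant)
        res = chain.add_residue(Residue(resname, i + 1))

        def token_value(token: str) -> float:
            if token == "PHI":
                return spec.phi[i]
            if token == "PSIPREV":
                return spec.psi[i - 1] if i > 0 else spec.psi[i]
            if token == "PSI180":
                v = spec.psi[i] + 180.0
                return v - 360.0 if v > 180.0 else v
            if token == "OMEGA":
                return spec.omega[i]
            raise ValueError(f"unknown torsion token {token!r}")

        for ta in tpl.atoms:
            pos = _place_template_atom(ta, res, prev_res, token_value)
            atom = Atom(ta.name, ta.element, pos, partial_charge=ta.charge)
            atom.type_name = ta.type_name
            res.add_atom(atom)
        prev_res = res

    db.build_bonds(system)
    return system


def _place_template_atom(ta, res: Residue, prev_res: Optional[Residue],
                         token_value) -> np.ndarray:
    def resolve(name):
        if name is None:
            return None
        if name.startswith("-"):
            return prev_res.atom_by_name(name[1:]) if prev_res else None
        return res.atom_by_name(name)

    refs = [resolve(r) for r in ta.refs]
    torsion = ta.torsion if isinstance(ta.torsion, float) else token_value(ta.torsion)

    # chain seeding: the very first backbone atoms have no upstream residue
    if refs[0] is None:
        return np.zeros(3)
    if refs[1] is None or refs[2] is None:
        r1 = refs[0].position
        r2 = refs[1].position if refs[1] is not None else r1 + np.array([-1.0, 0.0, 0.0])
        helper = r2 + np.array([0.0, -1.0, 0.0])
        return place_from_internal(r1, r2, helper, ta.length, ta.angle, torsion)
    return place_from_internal(refs[0].position, refs[1].position,
                               refs[2].position, ta.length, ta.angle, torsion)


# ---------------------------------------------------------------------------
# SMILES subset
# ---------------------------------------------------------------------------

class SmilesError(ValueError):
    def __init__(self, message: str, offset: Optional[int] = None):
        if offset is not None:
            message = f"{message} (at offset {offset})"
        super().__init__(message)
        self.offset = offset


_ORGANIC = ("Cl", "Br", "B", "C", "N", "O", "P", "S", "F", "I")
_AROMATIC_ORGANIC = ("b", "c", "n", "o", "p", "s")
_DEFAULT_VALENCE = {"B": 3, "C": 4, "N": 3, "O": 2, "P": 3, "S": 2,
                    "F": 1, "Cl": 1, "Br": 1, "I": 1, "H": 1}


def parse_smiles(text: str, add_hydrogens: bool = True) -> MolecularSystem:
    """Parse a SMILES string (subset) into a bonded heavy-atom graph.

    Aromatic input is kekulized before return; implicit hydrogens are
    materialized via :func:`fill_valence` unless *add_hydrogens* is false.
    Stereo marks and isotopes raise ``SmilesError`` ("unsupported SMILES
    feature").  Atoms carry no meaningful coordinates (all at origin).
    """
    system = MolecularSystem(name=text)
    mol = system.add_molecule(name=text)
    stack: list[Atom] = []
    prev: Optional[Atom] = None
    pending_order: Optional[int] = None
    ring_open: dict[int, tuple[Atom, Optional[int]]] = {}
    bracket_atoms: set[int] = set()
    counter = itertools.count(1)
    i = 0
    n = len(text)

    def new_atom(symbol: str, aromatic: bool, charge: int = 0,
                 explicit_h: int = 0, bracket: bool = False) -> Atom:
        nonlocal prev, pending_order
        atom = Atom(f"{symbol.upper()}{next(counter)}", symbol,
                    (0.0, 0.0, 0.0), formal_charge=charge)
        atom.aromatic = aromatic
        mol.add_atom(atom)
        if bracket:
            bracket_atoms.add(id(atom))
        if prev is not None:
            order = pending_order
            if order is None:
                order = AROMATIC if (aromatic and prev.aromatic) else 1
            system.add_bond(prev, atom, order)
        pending_order = None
        prev = atom
        for _ in range(explicit_h):
            h = Atom(f"H{next(counter)}", "H", (0.0, 0.0, 0.0))
            mol.add_atom(h)
            system.add_bond(atom, h, 1)
        return atom

    while i < n:
        ch = text[i]
        if ch in "/\\@":
            raise SmilesError("unsupported SMILES feature (stereochemistry)", i)
        if ch == ".":
            raise SmilesError("unsupported SMILES feature (disconnected parts)", i)
        if ch == "(":
            if prev is None:
                raise SmilesError("branch before any atom", i)
            stack.append(prev)
            i += 1
        elif ch == ")":
            if not stack:
                raise SmilesError("unbalanced parenthesis", i)
            prev = stack.pop()
            i += 1
        elif ch in "-=#":
            pending_order = {"-": 1, "=": 2, "#": 3}[ch]
            i += 1
        elif ch == ":":
            pending_order = AROMATIC
            i += 1
        elif ch.isdigit() or ch == "%":
            if ch == "%":
                if i + 2 >= n or not text[i + 1:i + 3].isdigit():
                    raise SmilesError("bad %nn ring closure", i)
                num = int(text[i + 1:i + 3])
                i += 3
            else:
                num = int(ch)
                i += 1
            if prev is None:
                raise SmilesError("ring closure before any atom", i)
            if num in ring_open:
                other, order0 = ring_open.pop(num)
                order = pending_order if pending_order is not None else order0
                if order is None:
                    order = AROMATIC if (prev.aromatic and other.aromatic) else 1
                if other is prev:
                    raise SmilesError("ring closure to the same atom", i)
                system.add_bond(prev, other, order)
            else:
                ring_open[num] = (prev, pending_order)
            pending_order = None
        elif ch == "[":
            j = text.find("]", i)
            if j < 0:
                raise SmilesError("unclosed bracket atom", i)
            _parse_bracket(text[i + 1:j], i + 1, new_atom)
            i = j + 1
        elif text[i:i + 2] in _ORGANIC:
            new_atom(text[i:i + 2], aromatic=False)
            i += 2
        elif ch in _ORGANIC:
            new_atom(ch, aromatic=False)
            i += 1
        elif ch in _AROMATIC_ORGANIC:
            new_atom(ch.upper(), aromatic=True)
            i += 1
        elif ch.isspace():
            i += 1
        else:
            raise SmilesError(f"unexpected character {ch!r}", i)

    if stack:
        raise SmilesError("unbalanced parenthesis", n)
    if ring_open:
        nums = ", ".join(map(str, sorted(ring_open)))
        raise SmilesError(f"unclosed ring closure digit(s): {nums}", n)
    if mol.atoms == []:
        raise SmilesError("empty SMILES", 0)

    kekulize(system)
    if add_hydrogens:
        fill_valence(system, _suppress=bracket_atoms)
    return system


def _parse_bracket(body: str, offset: int, new_atom):
    i = 0
    if not body:
        raise SmilesError("empty bracket atom", offset)
    if body[0].isdigit():
        raise SmilesError("unsupported SMILES feature (isotope)", offset)
    aromatic = False
    if body[i].islower():
        symbol = body[i].upper()
        aromatic = True
        i += 1
    else:
        if i + 1 < len(body) and body[i:i + 2] in ("Cl", "Br", "Na", "Mg",
                                                   "Ca", "Fe", "Zn"):
            symbol = body[i:i + 2]
            i += 2
        else:
            symbol = body[i]
            i += 1
    if symbol not in PERIODIC_TABLE:
        raise SmilesError(f"unknown element {symbol!r} in bracket", offset)
    explicit_h = 0
    charge = 0
    while i < len(body):
        ch = body[i]
        if ch == "@":
            raise SmilesError("unsupported SMILES feature (stereochemistry)",
                              offset + i)
        if ch == "H":
            i += 1
            if i < len(body) and body[i].isdigit():
                explicit_h = int(body[i])
                i += 1
            else:
                explicit_h = 1
        elif ch in "+-":
            sign = 1 if ch == "+" else -1
            i += 1
            if i < len(body) and body[i].isdigit():
                charge = sign * int(body[i])
                i += 1
            else:
                charge = sign
                while i < len(body) and body[i] == ch:
                    charge += sign
                    i += 1
        else:
            raise SmilesError(f"unexpected {ch!r} in bracket atom", offset + i)
    new_atom(symbol, aromatic, charge=charge, explicit_h=explicit_h, bracket=True)


def fill_valence(system: MolecularSystem, _suppress: Optional[set] = None) -> MolecularSystem:
    """Materialize implicit hydrogens on heavy atoms.

    Hydrogens added = default valence - bond-order sum + charge adjustment
    (cationic N gains a slot, anionic O/S/N lose one), floored at 0.  Atoms
    in *_suppress* (bracket atoms: H count was explicit) are skipped.
    """
    suppress = _suppress or set()
    counter = itertools.count(1)
    for container in list(system.molecules) + [r for r in system.residues()]:
        for atom in list(container.atoms):
            if atom.element == "H" or id(atom) in suppress:
                continue
            default = _DEFAULT_VALENCE.get(atom.element)
            if default is None:
                continue
            order_sum = sum(b.order if b.order != AROMATIC else 1.5
                            for b in atom.bonds)
            if atom.element == "N" and atom.formal_charge > 0:
                default = 4
            elif atom.formal_charge < 0:
                default += atom.formal_charge
            elif atom.element in ("N", "P", "S") and atom.formal_charge > 0:
                default += atom.formal_charge
            missing = int(round(default - order_sum))
            for _ in range(max(0, missing)):
                h = Atom(f"H{next(counter)}x", "H", atom.position)
                container.atoms.append(h)
                system.add_bond(atom, h, 1)
    return system


# ---------------------------------------------------------------------------
# bond orders / kekulization / aromaticity
# ---------------------------------------------------------------------------

class AtomPenaltyTable:
    """Allowed valence sums per (element, formal charge); linear deviation
    penalty of ``unit_penalty`` per missing/excess valence unit."""

    def __init__(self, allowed: dict[tuple[str, int], list[int]],
                 unit_penalty: int = 32):
        self.allowed = allowed
        self.unit_penalty = unit_penalty
        for key, vals in allowed.items():
            if not vals:
                raise ValueError(f"no allowed valences for {key}")

    @classmethod
    def from_file(cls, path: Optional[str] = None) -> "AtomPenaltyTable":
        if path is None:
            path = Path(resources.files("ballcore").joinpath("data", "penalties.txt"))
        allowed: dict[tuple[str, int], list[int]] = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#")[0].strip()
            if not line:
                continue
            f = line.split()
            elem, charge, valence, penalty = f[0], int(f[1]), int(f[2]), int(f[3])
            if penalty == 0:
                allowed.setdefault((elem, charge), []).append(valence)
        return cls(allowed)

    def penalty(self, element: str, charge: int, valence_sum: int) -> int:
        vals = self.allowed.get((element, charge))
        if vals is None:
            vals = self.allowed.get((element, 0))
        if vals is None:
            raise ValueError(f"element {element!r} not in penalty table")
        return self.unit_penalty * min(abs(valence_sum - v) for v in vals)


@dataclass(frozen=True)
class BondOrderAssignment:
    """A complete bond -> order mapping with its total penalty."""

    orders: tuple[int, ...]          # parallel to the bond list it was made for
    penalty: int
    bonds: tuple[Bond, ...] = ()

    def apply(self) -> None:
        for bond, order in zip(self.bonds, self.orders):
            bond.order = order


def assign_bond_orders(system: MolecularSystem,
                       table: Optional[AtomPenaltyTable] = None,
                       max_results: int = 10) -> list[BondOrderAssignment]:
    """Enumerate bond-order assignments sorted by ascending penalty.

    Heavy-heavy bonds take orders in {1,2,3}; bonds to hydrogen are fixed
    single.  The first returned assignment is globally minimal; ties break
    lexicographically on the order tuple.  Orders in the system itself are
    left untouched — call ``result.apply()`` to commit one.
    """
    table = table or AtomPenaltyTable.from_file()
    atoms = list(system.atoms())
    for a in atoms:
        if a.element != "H":
            try:
                table.penalty(a.element, a.formal_charge, 0)
            except ValueError as exc:
                raise ValueError(str(exc)) from exc
    index = {id(a): i for i, a in enumerate(atoms)}
    all_bonds = list(system.bonds())
    var_bonds = [b for b in all_bonds
                 if b.atom_a.element != "H" and b.atom_b.element != "H"]
    # fixed valence contribution from X-H bonds
    base = [0] * len(atoms)
    for b in all_bonds:
        if b not in var_bonds:
            base[index[id(b.atom_a)]] += 1
            base[index[id(b.atom_b)]] += 1

    bonds_per_atom: list[list[int]] = [[] for _ in atoms]
    for bi, b in enumerate(var_bonds):
        bonds_per_atom[index[id(b.atom_a)]].append(bi)
        bonds_per_atom[index[id(b.atom_b)]].append(bi)

    heavy = [i for i, a in enumerate(atoms) if a.element != "H"]

    def atom_penalty(i: int, valence: int) -> int:
        return table.penalty(atoms[i].element, atoms[i].formal_charge, valence)

    def atom_lower_bound(i: int, assigned_sum: int, remaining: int) -> int:
        vals = table.allowed.get((atoms[i].element, atoms[i].formal_charge)) \
            or table.allowed.get((atoms[i].element, 0))
        lo = assigned_sum + remaining          # every remaining bond >= 1
        hi = assigned_sum + 3 * remaining
        best = min(max(0, lo - v, v - hi) for v in vals)
        return table.unit_penalty * best

    results: list[tuple[int, tuple[int, ...]]] = []
    orders = [0] * len(var_bonds)

    def bound_ok(partial_penalty: int) -> bool:
        if len(results) < max_results:
            return True
        return partial_penalty <= results[-1][0]

    def dfs(bi: int, sums: list[int], assigned_count: list[int]):
        if bi == len(var_bonds):
            total = sum(atom_penalty(i, sums[i]) for i in heavy)
            entry = (total, tuple(orders))
            if len(results) < max_results or entry < results[-1]:
                results.append(entry)
                results.sort()
                del results[max_results:]
            return
        bond = var_bonds[bi]
        ia, ib = index[id(bond.atom_a)], index[id(bond.atom_b)]
        for order in (1, 2, 3):
            orders[bi] = order
            sums[ia] += order
            sums[ib] += order
            assigned_count[ia] += 1
            assigned_count[ib] += 1
            lb = 0
            for i in heavy:
                rem = len(bonds_per_atom[i]) - assigned_count[i]
                lb += atom_lower_bound(i, sums[i], rem)
                if not bound_ok(lb):
                    break
            if bound_ok(lb):
                dfs(bi + 1, sums, assigned_count)
            sums[ia] -= order
            sums[ib] -= order
            assigned_count[ia] -= 1
            assigned_count[ib] -= 1

    dfs(0, list(base), [0] * len(atoms))
    return [BondOrderAssignment(orders=o, penalty=p, bonds=tuple(var_bonds))
            for p, o in results]


class KekulizeError(ValueError):
    pass


def _needs_double(atom: Atom, aromatic_bonds: set[int]) -> bool:
    """Whether an atom of the aromatic subgraph must receive one double bond."""
    degree = len(atom.bonds)
    if atom.element == "C":
        return atom.formal_charge == 0
    if atom.element == "N":
        if atom.formal_charge > 0:
            return degree == 3  # e.g. pyridinium without H counted separately
        return degree == 2     # pyridine-type; pyrrole-type (3 connections) not
    if atom.element in ("O", "S"):
        return False           # furan/thiophene-type lone-pair donors
    return False


def kekulize(system: MolecularSystem) -> MolecularSystem:
    """Replace AROMATIC bond orders with an alternating single/double pattern.

    A perfect matching over the atoms that require a double bond; pyrrole-type
    N and O/S contribute lone pairs and stay single-bonded.
    """
    aromatic_bonds = [b for b in system.bonds() if b.order == AROMATIC]
    if not aromatic_bonds:
        return system
    bond_ids = set(map(id, aromatic_bonds))
    atoms = {id(a): a for b in aromatic_bonds for a in (b.atom_a, b.atom_b)}
    need = {aid for aid, a in atoms.items() if _needs_double(a, bond_ids)}

    graph = nx.Graph()
    graph.add_nodes_from(need)
    for b in aromatic_bonds:
        ia, ib = id(b.atom_a), id(b.atom_b)
        if ia in need and ib in need:
            graph.add_edge(ia, ib, bond=b)
    matching = nx.algorithms.matching.max_weight_matching(graph, maxcardinality=True)
    matched_atoms = {a for pair in matching for a in pair}
    if matched_atoms != need:
        raise KekulizeError("non-kekulizable aromatic system")
    matched_bonds = {id(graph.edges[u, v]["bond"]) for u, v in matching}
    for b in aromatic_bonds:
        b.order = 2 if id(b) in matched_bonds else 1
    return system


def _sssr(system: MolecularSystem) -> list[list[Atom]]:
    graph = nx.Graph()
    atoms = list(system.atoms())
    index = {id(a): i for i, a in enumerate(atoms)}
    graph.add_nodes_from(range(len(atoms)))
    for b in system.bonds():
        graph.add_edge(index[id(b.atom_a)], index[id(b.atom_b)])
    rings = nx.minimum_cycle_basis(graph)
    out = []
    for ring in sorted(rings, key=lambda r: (len(r), sorted(r))):
        # order the ring atoms along the cycle
        sub = graph.subgraph(ring)
        try:
            cyc = nx.find_cycle(sub)
        except nx.NetworkXNoCycle:  # pragma: no cover
            continue
        ordered = [edge[0] for edge in cyc]
        out.append([atoms[i] for i in ordered])
    return out


def _pi_electrons(atom: Atom, ring: set[int]) -> Optional[int]:
    """pi-electron contribution of *atom* in an SSSR ring, None if not sp2-capable."""
    orders = [b.order for b in atom.bonds]
    has_double = any(o == 2 for o in orders)
    has_aromatic = any(o == AROMATIC for o in orders)
    degree = len(atom.bonds)
    if atom.element == "C":
        if atom.formal_charge == 1 and degree == 3:
            return 0
        if has_double or has_aromatic:
            return 1
        return None
    if atom.element == "N":
        if has_double:
            return 1
        if degree == 3 or (has_aromatic and degree == 3):
            return 2
        if has_aromatic and degree == 2:
            return 1
        return 2 if degree == 3 else None
    if atom.element in ("O", "S"):
        if has_double and not has_aromatic:
            # exocyclic C=O style; in-ring double O is not typical — treat sp2
            return 1 if any(b.order == 2 and id(b.partner(atom)) in ring
                            for b in atom.bonds) else 2
        return 2
    return None


def perceive_aromaticity(system: MolecularSystem) -> MolecularSystem:
    """Mark bonds of Hueckel-aromatic SSSR rings as AROMATIC.

    A ring qualifies when every member is sp2-capable (C/N/O/S with suitable
    bonding) and the pi-electron count is 4n+2 (double-bond atoms contribute
    1, lone-pair heteroatoms 2, carbocations 0).
    """
    for ring in _sssr(system):
        ring_ids = set(map(id, ring))
        electrons = 0
        ok = True
        for atom in ring:
            if atom.element not in ("C", "N", "O", "S"):
                ok = False
                break
            pi = _pi_electrons(atom, ring_ids)
            if pi is None:
                ok = False
                break
            electrons += pi
        if not ok or electrons < 2 or (electrons - 2) % 4 != 0:
            continue
        for atom in ring:
            atom.aromatic = True
            for b in atom.bonds:
                if id(b.partner(atom)) in ring_ids:
                    b.order = AROMATIC
    return system
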