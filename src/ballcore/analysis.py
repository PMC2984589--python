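"""Structure analysis: hydrogen bonds, secondary structure, RMSD.

Hydrogen bonds are found geometrically (donor N/O/S with an attached H,
acceptor N/O, D...A <= 3.5 A, D-H...A angle >= 120 deg).  Backbone H-bonds
for secondary structure use the electrostatic energy model

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)   kcal/mol

with a bond declared below -0.5 kcal/mol.  Secondary structure is a reduced
3-state scheme: H (helix, two consecutive 4-turns), E (strand, bridge
patterns), C (everything else).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .geometry import measure_angle, measure_distance
from .model import Atom, MolecularSystem, Residue

__all__ = [
    "HydrogenBond",
    "detect_hydrogen_bonds",
    "backbone_hbond_energy",
    "SecondaryStructureAssignment",
    "assign_secondary_structure",
    "compute_rmsd",
    "HBOND_DISTANCE_CUTOFF",
    "HBOND_ANGLE_CUTOFF",
    "HBOND_ENERGY_CUTOFF",
]

HBOND_DISTANCE_CUTOFF = 3.5   # A, donor...acceptor
HBOND_ANGLE_CUTOFF = 120.0    # deg, D-H...A
HBOND_ENERGY_CUTOFF = -0.5    # kcal/mol, backbone energetic model
_CLASH_SENTINEL = -9.9

_DONOR_ELEMENTS = ("N", "O", "S")
_ACCEPTOR_ELEMENTS = ("N", "O")


@dataclass(frozen=True)
class HydrogenBond:
    donor: Atom
    hydrogen: Atom
    acceptor: Atom
    distance: float       # donor-acceptor, A
    angle: float          # D-H...A, degrees
    energy: Optional[float] = None  # backbone model only


def detect_hydrogen_bonds(system: MolecularSystem,
                          distance_cutoff: float = HBOND_DISTANCE_CUTOFF,
                          angle_cutoff: float = HBOND_ANGLE_CUTOFF) -> list[HydrogenBond]:
    """All geometric hydrogen bonds in donor traversal order."""
    atoms = list(system.atoms())
    donors = []
    for a in atoms:
        if a.element in _DONOR_ELEMENTS:
            hs = [n for n in a.bonded_atoms() if n.element == "H"]
            if hs:
                donors.append((a, hs))
    acceptors = [a for a in atoms if a.element in _ACCEPTOR_ELEMENTS]
    bonds = []
    for donor, hs in donors:
        for acceptor in acceptors:
            if acceptor is donor:
                continue
            d = measure_distance(donor, acceptor)
            if d > distance_cutoff:
                continue
            for h in hs:
                try:
                    ang = measure_angle(donor, h, acceptor)
                except ValueError:
                    continue
                if ang >= angle_cutoff:
                    bonds.append(HydrogenBond(donor, h, acceptor, d, ang))
                    break  # one bond per donor-acceptor pair
    return bonds


def backbone_hbond_energy(n: Atom, h: Atom, c: Atom, o: Atom) -> float:
    """Electrostatic backbone H-bond energy (donor N-H, acceptor C=O)."""
    r_on = measure_distance(o, n)
    r_ch = measure_distance(c, h)
    r_oh = measure_distance(o, h)
    r_cn = measure_distance(c, n)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        return _CLASH_SENTINEL
    return 0.084 * 332.0 * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


@dataclass
class SecondaryStructureAssignment:
    """Per-residue state H/E/C keyed by residue object identity order."""

    residues: list[Residue]
    states: list[str]

    def state_of(self, residue: Residue) -> str:
        return self.states[self.residues.index(residue)]

    def __iter__(self):
        return iter(zip(self.residues, self.states))

    def string(self) -> str:
        return "".join(self.states)


def _backbone_hbond_set(residues: list[Residue]) -> set[tuple[int, int]]:
    """(donor_index, acceptor_index) pairs with model energy < cutoff."""
    out = set()
    for i, donor_res in enumerate(residues):
        n = donor_res.atom_by_name("N")
        h = donor_res.atom_by_name("H") or donor_res.atom_by_name("H1")
        if n is None or h is None:
            continue
        for j, acc_res in enumerate(residues):
            if abs(i - j) < 2:
                continue
            c = acc_res.atom_by_name("C")
            o = acc_res.atom_by_name("O")
            if c is None or o is None:
                continue
            if measure_distance(n, o) > 5.5:
                continue
            if backbone_hbond_energy(n, h, c, o) < HBOND_ENERGY_CUTOFF:
                out.add((i, j))
    return out


def assign_secondary_structure(system: MolecularSystem) -> SecondaryStructureAssignment:
    """Reduced DSSP-like 3-state assignment from backbone H-bond patterns.

    A 4-turn at i exists when N-H of residue i+4 bonds the C=O of residue i;
    two consecutive 4-turns make residues i+1..i+4 helical.  Bridges between
    sequence-distant residues mark strands.  H wins over E.
    """
    residues = [r for c in system.chains for r in c.residues
                if r.atom_by_name("CA") is not None]
    n = len(residues)
    states = ["C"] * n
    hbond = _backbone_hbond_set(residues)  # (donor i, acceptor j): N-H(i) -> O(j)

    turn4 = [False] * n
    for i in range(n - 4):
        if (i + 4, i) in hbond:
            turn4[i] = True
    # strands via bridges
    for i in range(n):
        for j in range(n):
            if abs(i - j) <= 2:
                continue
            parallel = ((i, j - 1) in hbond and (j + 1, i) in hbond) or \
                       ((j, i - 1) in hbond and (i + 1, j) in hbond)
            antiparallel = ((i, j) in hbond and (j, i) in hbond) or \
                           ((i + 1, j - 1) in hbond and (j + 1, i - 1) in hbond)
            if parallel or antiparallel:
                states[i] = "E"
                states[j] = "E"
    # helices take precedence
    for i in range(n - 4):
        if turn4[i] and i + 1 < n and turn4[i + 1]:
            for k in range(i + 1, min(i + 5, n)):
                states[k] = "H"
    return SecondaryStructureAssignment(residues, states)


def compute_rmsd(system_a, system_b, atom_matching: Optional[list] = None) -> float:
    """Optimal-superposition RMSD (Kabsch) between matched atoms.

    *atom_matching* is a list of (atom_a, atom_b) pairs; by default atoms are
    paired in traversal order (systems must then have equal atom counts).
    """
    if atom_matching is None:
        a_atoms = list(system_a.atoms()) if isinstance(system_a, MolecularSystem) else None
        if a_atoms is not None:
            b_atoms = list(system_b.atoms())
            if len(a_atoms) != len(b_atoms):
                raise ValueError("atom counts differ; provide an explicit matching")
            p = np.array([a.position for a in a_atoms])
            q = np.array([a.position for a in b_atoms])
        else:
            p = np.asarray(system_a, dtype=float)
            q = np.asarray(system_b, dtype=float)
    else:
        p = np.array([a.position for a, _ in atom_matching])
        q = np.array([b.position for _, b in atom_matching])
    if len(p) < 3:
        raise ValueError("need at least 3 matched atoms for superposition")
    p = p - p.mean(axis=0)
    q = q - q.mean(axis=0)
    h = p.T @ q
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])  # reflection guard
    r = vt.T @ diag @ u.T
    p_rot = p @ r.T
    return float(np.sqrt(np.mean(np.sum((p_rot - q) ** 2, axis=1))))
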