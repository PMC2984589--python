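"""Geometry primitives: distances, angles, torsions, internal-coordinate placement.

All public functions take and return Angstrom / degrees; radians appear only
inside the numeric kernels.  Torsions follow the IUPAC convention: cis = 0,
sign by the right-hand rule about the b->c axis, range (-180, 180].
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np

from .model import Atom, Bond, MolecularSystem

__all__ = [
    "measure_distance",
    "measure_angle",
    "measure_dihedral",
    "set_dihedral",
    "place_from_internal",
    "rotation_about_axis",
]


def _vec(p) -> np.ndarray:
    return p.position if isinstance(p, Atom) else np.asarray(p, dtype=float)


def measure_distance(a, b) -> float:
    """Euclidean distance between two positions (or atoms), Angstrom."""
    return float(np.linalg.norm(_vec(a) - _vec(b)))


def measure_angle(a, b, c) -> float:
    """Angle at vertex *b*, degrees, in [0, 180]."""
    u = _vec(a) - _vec(b)
    v = _vec(c) - _vec(b)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise ValueError("degenerate angle: zero-length arm")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return math.degrees(math.acos(cosang))


def measure_dihedral(a, b, c, d) -> float:
    """Torsion angle a-b-c-d, degrees in (-180, 180], IUPAC sign convention."""
    p0, p1, p2, p3 = _vec(a), _vec(b), _vec(c), _vec(d)
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if nb2 < 1e-12 or np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise ValueError("undefined torsion: collinear points")
    # atan2 two-vector formulation; numerically stable near 0 and 180
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2) / nb2
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """3x3 rotation matrix about *axis* (Rodrigues), right-handed."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        raise ValueError("zero-length rotation axis")
    k = axis / n
    t = math.radians(angle_deg)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + math.sin(t) * K + (1.0 - math.cos(t)) * (K @ K)


def _component_atoms(start: Atom, barrier: Bond) -> set[int]:
    """ids of atoms reachable from *start* without crossing *barrier*."""
    seen = {id(start)}
    stack = [start]
    while stack:
        atom = stack.pop()
        for bond in atom.bonds:
            if bond is barrier:
                continue
            other = bond.partner(atom)
            if id(other) not in seen:
                seen.add(id(other))
                stack.append(other)
    return seen


def set_dihedral(system: MolecularSystem, a: Atom, b: Atom, c: Atom, d: Atom,
                 target: float) -> MolecularSystem:
    """Rotate the d-side of the b-c bond rigidly so torsion a-b-c-d = *target*.

    The b-c bond must exist and must not be part of a ring.
    """
    bond = b.bond_to(c)
    if bond is None:
        raise ValueError("atoms b and c are not bonded")
    d_side = _component_atoms(c, bond)
    if id(b) in d_side:
        raise ValueError("cannot rotate ring bond")
    current = measure_dihedral(a, b, c, d)
    delta = target - current
    if abs(delta) < 1e-13:
        return system
    R = rotation_about_axis(c.position - b.position, delta)
    origin = b.position
    for atom in system.atoms():
        if id(atom) in d_side:
            atom.position = origin + R @ (atom.position - origin)
    return system


def place_from_internal(r1: np.ndarray, r2: np.ndarray, r3: np.ndarray,
                        length: float, angle_deg: float,
                        torsion_deg: float) -> np.ndarray:
    """NeRF placement: position of a new atom X given three references.

    X is at *length* from r1, with angle X-r1-r2 = *angle_deg* and torsion
    X-r1-r2-r3 = *torsion_deg*.
    """
    r1 = np.asarray(r1, float)
    r2 = np.asarray(r2, float)
    r3 = np.asarray(r3, float)
    bc = r1 - r2
    nbc = np.linalg.norm(bc)
    if nbc < 1e-9:
        raise ValueError("degenerate internal-coordinate reference (r1 == r2)")
    bc /= nbc
    ab = r2 - r3
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-9:
        # collinear references: any perpendicular works; torsion is arbitrary
        helper = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(helper, bc)) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(helper, bc)
        nn = np.linalg.norm(n)
    n /= nn
    m = np.cross(n, bc)
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    d = np.array([
        -length * math.cos(ang),
        length * math.sin(ang) * math.cos(tor),
        length * math.sin(ang) * math.sin(tor),
    ])
    frame = np.column_stack([bc, m, n])
    return r1 + frame @ d
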