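"""AMBER-functional-form molecular mechanics energy and analytic gradient.

Energy terms::

    E = sum k_r (r - r0)^2
      + sum k_theta (theta - theta0)^2
      + sum V_n/2 (1 + cos(n phi - gamma))
      + sum eps [ (rmin/r)^12 - 2 (rmin/r)^6 ]        (1-4 divided by scnb)
      + sum 332.0637 q_i q_j / r                       (1-4 divided by scee)

1-2 and 1-3 pairs are excluded from the nonbonded sums; 1-4 pairs are scaled.
Pairs beyond the cutoff (hard truncation, 0 disables) contribute nothing.
All energies in kcal/mol, gradients in kcal/mol/A.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np

from .model import Atom, MolecularSystem
from .prep import FragmentDatabase

__all__ = [
    "ForceFieldParameters",
    "InteractionLists",
    "EnergyReport",
    "ForceFieldError",
    "assign_types_and_charges",
    "build_interactions",
    "compute_energy",
    "compute_gradient",
    "set_movable_from_selection",
    "AmberForceField",
]


class ForceFieldError(RuntimeError):
    pass


@dataclass
class EnergyReport:
    stretch: float = 0.0
    bend: float = 0.0
    torsion: float = 0.0
    vdw: float = 0.0
    electrostatic: float = 0.0

    @property
    def total(self) -> float:
        return self.stretch + self.bend + self.torsion + self.vdw + self.electrostatic

    def __str__(self):
        return (f"E_total={self.total:.4f} (stretch={self.stretch:.4f} "
                f"bend={self.bend:.4f} torsion={self.torsion:.4f} "
                f"vdw={self.vdw:.4f} elec={self.electrostatic:.4f}) kcal/mol")


class ForceFieldParameters:
    """Typed parameter tables loaded from the bundled text format."""

    def __init__(self):
        self.types: dict[str, tuple[float, float, float]] = {}  # eps, rmin/2, mass
        self.stretch: dict[tuple[str, str], tuple[float, float]] = {}
        self.bend: list[tuple[tuple[str, str, str], float, float]] = []
        self.torsion: dict[tuple[str, str, str, str], list[tuple[float, int, float]]] = {}
        self.scee = 1.2
        self.scnb = 2.0
        self.coulomb = 332.0637
        self.cutoff = 12.0

    @classmethod
    def from_file(cls, path: Optional[str] = None) -> "ForceFieldParameters":
        if path is None:
            path = Path(resources.files("ballcore").joinpath("data", "amber_params.txt"))
        params = cls()
        section = None
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#")[0].strip()
            if not line:
                continue
            if line.startswith("["):
                section = line.strip("[]").strip()
                continue
            f = line.split()
            if section == "options":
                key, value = f[0], f[1]
                if key in ("scee", "scnb", "coulomb", "cutoff"):
                    setattr(params, key, float(value))
            elif section == "types":
                eps, rmin2, mass = map(float, f[1:4])
                if eps < 0:
                    raise ValueError(f"{path}:{lineno}: negative epsilon")
                params.types[f[0]] = (eps, rmin2, mass)
            elif section == "stretch":
                k, r0 = float(f[2]), float(f[3])
                if k < 0 or r0 <= 0:
                    raise ValueError(f"{path}:{lineno}: bad stretch parameters")
                params.stretch[tuple(sorted((f[0], f[1])))] = (k, r0)
            elif section == "bend":
                params.bend.append(((f[0], f[1], f[2]), float(f[3]), float(f[4])))
            elif section == "torsion":
                key = (f[0], f[1], f[2], f[3])
                vhalf, n, gamma = float(f[4]), int(f[5]), float(f[6])
                if not 1 <= n <= 6:
                    raise ValueError(f"{path}:{lineno}: periodicity out of range")
                params.torsion.setdefault(key, []).append((vhalf, n, gamma))
            else:
                raise ValueError(f"{path}:{lineno}: line outside a known section")
        return params

    # -- parameter lookup --------------------------------------------------

    def stretch_for(self, t1: str, t2: str) -> tuple[float, float]:
        key = tuple(sorted((t1, t2)))
        if key not in self.stretch:
            raise ForceFieldError(f"missing stretch parameter for types {t1}-{t2}")
        return self.stretch[key]

    def bend_for(self, t1: str, t2: str, t3: str) -> tuple[float, float]:
        best = None
        best_wild = 99
        for (p1, p2, p3), k, theta0 in self.bend:
            for c1, c2, c3 in ((p1, p2, p3), (p3, p2, p1)):
                if c2 not in (t2, "X"):
                    continue
                if c1 not in (t1, "X") or c3 not in (t3, "X"):
                    continue
                wild = (c1 == "X") + (c2 == "X") + (c3 == "X")
                if wild < best_wild:
                    best, best_wild = (k, theta0), wild
        if best is None:
            raise ForceFieldError(f"missing bend parameter for types {t1}-{t2}-{t3}")
        return best

    def torsion_for(self, t1: str, t2: str, t3: str, t4: str) -> list[tuple[float, int, float]]:
        for key in ((t1, t2, t3, t4), (t4, t3, t2, t1)):
            if key in self.torsion:
                return self.torsion[key]
        for key in (("X", t2, t3, "X"), ("X", t3, t2, "X")):
            if key in self.torsion:
                return self.torsion[key]
        raise ForceFieldError(
            f"missing torsion parameter for types {t1}-{t2}-{t3}-{t4}")

    def mass_of(self, type_name: str) -> float:
        if type_name not in self.types:
            raise ForceFieldError(f"unknown atom type {type_name!r}")
        return self.types[type_name][2]


@dataclass
class InteractionLists:
    """Index-based interaction lists over a fixed atom ordering."""

    atoms: list[Atom] = field(default_factory=list)
    # stretches: (i, j, k, r0)
    stretches: np.ndarray = None
    stretch_params: np.ndarray = None
    bends: np.ndarray = None
    bend_params: np.ndarray = None  # k, theta0 (radians)
    torsions: np.ndarray = None
    torsion_params: list = field(default_factory=list)  # per quad: [(vhalf, n, gamma_rad)]
    nonbonded_full: np.ndarray = None
    nonbonded_14: np.ndarray = None
    excluded: set = field(default_factory=set)
    eps_i: np.ndarray = None
    rmin2_i: np.ndarray = None
    charges: np.ndarray = None


def assign_types_and_charges(system: MolecularSystem,
                             db: Optional[FragmentDatabase] = None) -> MolecularSystem:
    """Give every atom the type and partial charge of its template atom.

    Raises :class:`ForceFieldError` listing every unmatched atom.
    """
    db = db or FragmentDatabase()
    offenders: list[str] = []
    for chain in system.chains:
        for res in chain.residues:
            tpl = db.template_for(chain, res)
            if tpl is None:
                offenders.extend(f"{chain.id}/{res.name}{res.id}:{a.name}"
                                 for a in res.atoms)
                continue
            for atom in res.atoms:
                ta = tpl.atom(atom.name)
                if ta is None:
                    offenders.append(f"{chain.id}/{res.name}{res.id}:{atom.name}")
                    continue
                atom.type_name = ta.type_name
                atom.partial_charge = ta.charge
    for mol in system.molecules:
        for atom in mol.atoms:
            if atom.type_name is None:
                offenders.append(f"mol/{mol.name}:{atom.name}")
    if offenders:
        raise ForceFieldError(
            "cannot assign force-field types/charges to: " + ", ".join(offenders))
    return system


def build_interactions(system: MolecularSystem,
                       params: ForceFieldParameters) -> InteractionLists:
    """Enumerate stretches, bends, torsions, and nonbonded pair classes."""
    atoms = list(system.atoms())
    index = {id(a): i for i, a in enumerate(atoms)}
    for a in atoms:
        if a.type_name is None:
            raise ForceFieldError(f"atom {a.name!r} has no force-field type")
        if a.type_name not in params.types:
            raise ForceFieldError(f"unknown atom type {a.type_name!r} on atom {a.name!r}")

    lists = InteractionLists(atoms=atoms)
    neighbors: list[list[int]] = [[] for _ in atoms]
    bond_pairs = []
    for bond in system.bonds():
        i, j = index[id(bond.atom_a)], index[id(bond.atom_b)]
        neighbors[i].append(j)
        neighbors[j].append(i)
        bond_pairs.append((i, j))

    stretches, sparams = [], []
    for i, j in bond_pairs:
        k, r0 = params.stretch_for(atoms[i].type_name, atoms[j].type_name)
        stretches.append((i, j))
        sparams.append((k, r0))

    bends, bparams = [], []
    for j, nb in enumerate(neighbors):
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                i, k = nb[a], nb[b]
                kf, theta0 = params.bend_for(atoms[i].type_name,
                                             atoms[j].type_name,
                                             atoms[k].type_name)
                bends.append((i, j, k))
                bparams.append((kf, math.radians(theta0)))

    torsions, tparams = [], []
    seen_quads = set()
    for j, k in bond_pairs:
        for i in neighbors[j]:
            if i == k:
                continue
            for l in neighbors[k]:
                if l == j or l == i:
                    continue
                quad = (i, j, k, l) if (i, j, k, l) <= (l, k, j, i) else (l, k, j, i)
                if quad in seen_quads:
                    continue
                seen_quads.add(quad)
                terms = params.torsion_for(atoms[quad[0]].type_name,
                                           atoms[quad[1]].type_name,
                                           atoms[quad[2]].type_name,
                                           atoms[quad[3]].type_name)
                torsions.append(quad)
                tparams.append([(v, n, math.radians(g)) for v, n, g in terms])

    # exclusion classes
    pair12 = {frozenset(p) for p in bond_pairs}
    pair13 = set()
    for i, j, k in bends:
        pair13.add(frozenset((i, k)))
    pair14 = set()
    for i, j, k, l in torsions:
        p = frozenset((i, l))
        if p not in pair12 and p not in pair13:
            pair14.add(p)
    excluded = pair12 | pair13

    n = len(atoms)
    full, scaled = [], []
    for i in range(n):
        for j in range(i + 1, n):
            p = frozenset((i, j))
            if p in excluded:
                continue
            (scaled if p in pair14 else full).append((i, j))

    lists.stretches = np.array(stretches, dtype=int).reshape(-1, 2)
    lists.stretch_params = np.array(sparams, dtype=float).reshape(-1, 2)
    lists.bends = np.array(bends, dtype=int).reshape(-1, 3)
    lists.bend_params = np.array(bparams, dtype=float).reshape(-1, 2)
    lists.torsions = np.array(torsions, dtype=int).reshape(-1, 4)
    lists.torsion_params = tparams
    lists.nonbonded_full = np.array(full, dtype=int).reshape(-1, 2)
    lists.nonbonded_14 = np.array(scaled, dtype=int).reshape(-1, 2)
    lists.excluded = excluded
    lists.eps_i = np.array([params.types[a.type_name][0] for a in atoms])
    lists.rmin2_i = np.array([params.types[a.type_name][1] for a in atoms])
    lists.charges = np.array([a.partial_charge for a in atoms])
    return lists


def _torsion_geometry(coords, quads):
    """phi (radians) and d(phi)/d(position) for each torsion quadruple."""
    a, b, c, d = (coords[quads[:, i]] for i in range(4))
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=1)
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", np.cross(n1, n2), b2) / nb2
    phi = np.arctan2(y, x)
    n1sq = np.einsum("ij,ij->i", n1, n1)
    n2sq = np.einsum("ij,ij->i", n2, n2)
    # standard analytic derivatives (validated against finite differences)
    dphi_da = (-nb2 / n1sq)[:, None] * n1
    dphi_dd = (nb2 / n2sq)[:, None] * n2
    s12 = np.einsum("ij,ij->i", b1, b2) / nb2 ** 2
    s32 = np.einsum("ij,ij->i", b3, b2) / nb2 ** 2
    dphi_db = -(1.0 + s12)[:, None] * dphi_da + s32[:, None] * dphi_dd
    dphi_dc = -(dphi_da + dphi_db + dphi_dd)
    return phi, dphi_da, dphi_db, dphi_dc, dphi_dd


def _evaluate(coords: np.ndarray, lists: InteractionLists,
              params: ForceFieldParameters, want_gradient: bool):
    # divergent dynamics can feed nonfinite coordinates through here; the
    # caller (run_md) detects and reports them, so suppress numpy noise
    with np.errstate(invalid="ignore", over="ignore", divide="ignore"):
        return _evaluate_inner(coords, lists, params, want_gradient)


def _evaluate_inner(coords: np.ndarray, lists: InteractionLists,
                    params: ForceFieldParameters, want_gradient: bool):
    n = len(coords)
    report = EnergyReport()
    grad = np.zeros((n, 3)) if want_gradient else None

    # stretches
    if len(lists.stretches):
        i, j = lists.stretches[:, 0], lists.stretches[:, 1]
        dv = coords[i] - coords[j]
        r = np.linalg.norm(dv, axis=1)
        k, r0 = lists.stretch_params[:, 0], lists.stretch_params[:, 1]
        report.stretch = float(np.sum(k * (r - r0) ** 2))
        if want_gradient:
            dEdr = 2.0 * k * (r - r0)
            f = (dEdr / r)[:, None] * dv
            np.add.at(grad, i, f)
            np.add.at(grad, j, -f)

    # bends
    if len(lists.bends):
        ii, jj, kk = lists.bends[:, 0], lists.bends[:, 1], lists.bends[:, 2]
        u = coords[ii] - coords[jj]
        v = coords[kk] - coords[jj]
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        cos_t = np.clip(np.einsum("ij,ij->i", u, v) / (nu * nv), -1.0, 1.0)
        theta = np.arccos(cos_t)
        kf, theta0 = lists.bend_params[:, 0], lists.bend_params[:, 1]
        report.bend = float(np.sum(kf * (theta - theta0) ** 2))
        if want_gradient:
            sin_t = np.sqrt(np.maximum(1.0 - cos_t ** 2, 1e-12))
            dEdt = 2.0 * kf * (theta - theta0)
            uhat = u / nu[:, None]
            vhat = v / nv[:, None]
            dt_di = (cos_t[:, None] * uhat - vhat) / (nu * sin_t)[:, None]
            dt_dk = (cos_t[:, None] * vhat - uhat) / (nv * sin_t)[:, None]
            np.add.at(grad, ii, dEdt[:, None] * dt_di)
            np.add.at(grad, kk, dEdt[:, None] * dt_dk)
            np.add.at(grad, jj, -dEdt[:, None] * (dt_di + dt_dk))

    # torsions
    if len(lists.torsions):
        phi, da, db, dc, dd = _torsion_geometry(coords, lists.torsions)
        e = np.zeros(len(phi))
        dEdphi = np.zeros(len(phi))
        for t, terms in enumerate(lists.torsion_params):
            for vhalf, nper, gamma in terms:
                e[t] += vhalf * (1.0 + math.cos(nper * phi[t] - gamma))
                dEdphi[t] += -vhalf * nper * math.sin(nper * phi[t] - gamma)
        report.torsion = float(np.sum(e))
        if want_gradient:
            quads = lists.torsions
            np.add.at(grad, quads[:, 0], dEdphi[:, None] * da)
            np.add.at(grad, quads[:, 1], dEdphi[:, None] * db)
            np.add.at(grad, quads[:, 2], dEdphi[:, None] * dc)
            np.add.at(grad, quads[:, 3], dEdphi[:, None] * dd)

    # nonbonded
    for pairs, vdw_scale, ele_scale in (
            (lists.nonbonded_full, 1.0, 1.0),
            (lists.nonbonded_14, 1.0 / params.scnb, 1.0 / params.scee)):
        if not len(pairs):
            continue
        i, j = pairs[:, 0], pairs[:, 1]
        dv = coords[i] - coords[j]
        r = np.linalg.norm(dv, axis=1)
        if np.any(r < 1e-6):
            raise ForceFieldError("singular nonbonded distance")
        if params.cutoff > 0:
            mask = r <= params.cutoff
            if not np.all(mask):
                i, j, dv, r = i[mask], j[mask], dv[mask], r[mask]
        eps = np.sqrt(lists.eps_i[i] * lists.eps_i[j])
        rmin = lists.rmin2_i[i] + lists.rmin2_i[j]
        ratio6 = np.zeros_like(r)
        nz = rmin > 0
        ratio6[nz] = (rmin[nz] / r[nz]) ** 6
        e_vdw = eps * (ratio6 ** 2 - 2.0 * ratio6) * vdw_scale
        qq = params.coulomb * lists.charges[i] * lists.charges[j]
        e_ele = qq / r * ele_scale
        report.vdw += float(np.sum(e_vdw))
        report.electrostatic += float(np.sum(e_ele))
        if want_gradient:
            # dE/dr for both terms
            dvdw = eps * 12.0 * (ratio6 - ratio6 ** 2) / r * vdw_scale
            dele = -qq / r ** 2 * ele_scale
            f = ((dvdw + dele) / r)[:, None] * dv
            np.add.at(grad, i, f)
            np.add.at(grad, j, -f)

    return report, grad


def compute_energy(system_or_coords, lists: InteractionLists,
                   params: ForceFieldParameters) -> EnergyReport:
    """Per-term energies for the current coordinates."""
    coords = _coords_of(system_or_coords, lists)
    report, _ = _evaluate(coords, lists, params, want_gradient=False)
    return report


def compute_gradient(system_or_coords, lists: InteractionLists,
                     params: ForceFieldParameters) -> np.ndarray:
    """Analytic dE/dposition, (N, 3), kcal/mol/A (unmasked)."""
    coords = _coords_of(system_or_coords, lists)
    _, grad = _evaluate(coords, lists, params, want_gradient=True)
    return grad


def _coords_of(system_or_coords, lists: InteractionLists) -> np.ndarray:
    if isinstance(system_or_coords, MolecularSystem):
        return np.array([a.position for a in lists.atoms])
    return np.asarray(system_or_coords, dtype=float)


def set_movable_from_selection(system: MolecularSystem) -> np.ndarray:
    """Boolean movable mask over traversal order.

    Selected atoms are movable; an empty selection means all atoms movable.
    The full system always contributes to the energy — the mask only gates
    displacement in minimizers and dynamics.
    """
    flags = np.array([a.selected for a in system.atoms()], dtype=bool)
    if not flags.any():
        return np.ones_like(flags)
    return flags


class AmberForceField:
    """Convenience facade bundling parameters, typed system, and lists."""

    def __init__(self, params: Optional[ForceFieldParameters] = None,
                 db: Optional[FragmentDatabase] = None):
        self.params = params or ForceFieldParameters.from_file()
        self.db = db or FragmentDatabase()
        self.system: Optional[MolecularSystem] = None
        self.lists: Optional[InteractionLists] = None

    def setup(self, system: MolecularSystem, assign: bool = True) -> "AmberForceField":
        if assign:
            assign_types_and_charges(system, self.db)
        self.system = system
        self.lists = build_interactions(system, self.params)
        return self

    def update(self) -> "AmberForceField":
        """Rebuild interaction lists after topology changes."""
        self.lists = build_interactions(self.system, self.params)
        return self

    def energy(self, coords: Optional[np.ndarray] = None) -> EnergyReport:
        return compute_energy(coords if coords is not None else self.system,
                              self.lists, self.params)

    def gradient(self, coords: Optional[np.ndarray] = None) -> np.ndarray:
        return compute_gradient(coords if coords is not None else self.system,
                                self.lists, self.params)

    def masses(self) -> np.ndarray:
        return np.array([self.params.mass_of(a.type_name) for a in self.lists.atoms])

    def movable_mask(self) -> np.ndarray:
        return set_movable_from_selection(self.system)
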