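"""Fragment-database structure preparation.

A :class:`FragmentDatabase` holds per-residue reference templates (atom
names, elements, force-field types, partial charges, ideal internal
geometry, intra-residue bonds) in four variants (internal / n_terminal /
c_terminal / free), a name-normalization map, and drives the preparation
pipeline::

    system.apply(db.normalize_names)
    system.apply(db.add_hydrogens)
    system.apply(db.build_bonds)
    report = check_residues(system, db)

plus the rotamer machinery (:class:`RotamerLibrary`, :func:`apply_rotamer`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .geometry import measure_distance, place_from_internal, set_dihedral
from .model import Atom, Chain, MolecularSystem, Residue

log = logging.getLogger(__name__)

__all__ = [
    "TemplateAtom",
    "FragmentTemplate",
    "FragmentDatabase",
    "CheckReport",
    "Finding",
    "Rotamer",
    "RotamerLibrary",
    "check_residues",
    "apply_rotamer",
    "most_likely_rotamer",
    "CHI_ATOMS",
]

VARIANTS = ("internal", "n_terminal", "c_terminal", "free")

#: chi-angle defining atom quadruples per residue, chi1..chi4 order.
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}

# fallback X-H bond lengths by heavy element
_H_LENGTH = {"C": 1.09, "N": 1.01, "O": 0.96, "S": 1.34}


@dataclass(frozen=True)
class TemplateAtom:
    name: str
    element: str
    type_name: str
    charge: float
    refs: tuple[Optional[str], Optional[str], Optional[str]]
    length: float
    angle: float
    torsion: object  # float or builder token string (PHI/PSIPREV/PSI180/OMEGA)


@dataclass
class FragmentTemplate:
    name: str
    variant: str
    atoms: list[TemplateAtom] = field(default_factory=list)
    bonds: list[tuple[str, str, int]] = field(default_factory=list)

    @property
    def net_charge(self) -> int:
        return round(sum(a.charge for a in self.atoms))

    def atom(self, name: str) -> Optional[TemplateAtom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def hydrogen_names(self) -> list[str]:
        return [a.name for a in self.atoms if a.element == "H"]

    def validate(self):
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate atom names in template {self.name} {self.variant}")
        placed: set[str] = set()
        for a in self.atoms:
            for ref in a.refs:
                if ref and not ref.startswith("-") and ref not in placed:
                    raise ValueError(
                        f"template {self.name} {self.variant}: atom {a.name} "
                        f"references {ref} before it is defined")
            placed.add(a.name)
        total = sum(a.charge for a in self.atoms)
        if abs(total - round(total)) > 1e-6:
            raise ValueError(
                f"template {self.name} {self.variant}: charge sum {total} not integral")


@dataclass(frozen=True)
class Rotamer:
    chis: tuple[Optional[float], ...]
    probability: float


class RotamerLibrary:
    """Per-residue rotamers, sorted descending by probability."""

    def __init__(self, rotamers: dict[str, list[Rotamer]]):
        self.rotamers = rotamers
        for res, lst in rotamers.items():
            total = sum(r.probability for r in lst)
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"rotamer probabilities for {res} sum to {total}")
            if any(lst[i].probability < lst[i + 1].probability for i in range(len(lst) - 1)):
                raise ValueError(f"rotamers for {res} not sorted by probability")

    @classmethod
    def from_file(cls, path) -> "RotamerLibrary":
        table: dict[str, list[Rotamer]] = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#")[0].strip()
            if not line:
                continue
            fields = line.split()
            res = fields[0].upper()
            chis = tuple(None if f == "-" else float(f) for f in fields[1:5])
            prob = float(fields[5])
            table.setdefault(res, []).append(Rotamer(chis, prob))
        return cls(table)

    def __contains__(self, res: str) -> bool:
        return res.upper() in self.rotamers

    def __getitem__(self, res: str) -> list[Rotamer]:
        key = res.upper()
        if key not in self.rotamers:
            raise KeyError(f"no rotamers for residue {res!r}")
        return self.rotamers[key]


SEVERITIES = ("info", "warning", "error")
KINDS = ("missing_atom", "unknown_residue", "bond_length_deviation",
         "charge_anomaly", "atom_clash", "unknown_atom")


@dataclass(frozen=True)
class Finding:
    severity: str
    kind: str
    locator: str
    message: str


class CheckReport:
    def __init__(self):
        self.findings: list[Finding] = []

    def add(self, severity: str, kind: str, locator: str, message: str):
        assert severity in SEVERITIES and kind in KINDS
        self.findings.append(Finding(severity, kind, locator, message))

    def is_clean(self) -> bool:
        return not self.findings

    def has_errors(self) -> bool:
        return any(f.severity == "error" for f in self.findings)

    def __iter__(self):
        return iter(self.findings)

    def __len__(self):
        return len(self.findings)

    def __str__(self):
        if self.is_clean():
            return "clean"
        return "\n".join(f"{f.severity:<8s}{f.kind:<22s}{f.locator:<12s}{f.message}"
                         for f in self.findings)


def _data_path(filename: str) -> Path:
    return Path(resources.files("ballcore").joinpath("data", filename))


class FragmentDatabase:
    """Bundled (or user-supplied) fragment templates + normalization map."""

    def __init__(self, data_dir: Optional[str] = None):
        base = Path(data_dir) if data_dir else _data_path("")
        self.templates: dict[tuple[str, str], FragmentTemplate] = {}
        self.aliases: dict[tuple[str, Optional[str]], str] = {}
        self._load_fragments(base / "fragments.txt")
        self._load_names(base / "names.txt")
        self.warnings: list[str] = []

    # -- loading ----------------------------------------------------------

    def _load_fragments(self, path: Path):
        current: Optional[FragmentTemplate] = None
        for lineno, raw in enumerate(path.read_text().splitlines(), 1):
            line = raw.split("#")[0].strip()
            if not line:
                continue
            if line.startswith("[residue"):
                fields = line.strip("[]").split()
                if len(fields) != 3 or fields[2] not in VARIANTS:
                    raise ValueError(f"{path}:{lineno}: bad section header {raw!r}")
                current = FragmentTemplate(fields[1].upper(), fields[2])
                self.templates[(current.name, current.variant)] = current
            elif line.startswith("atom"):
                if current is None:
                    raise ValueError(f"{path}:{lineno}: atom outside residue section")
                f = line.split()
                name, elem, typ = f[1], f[2], f[3]
                charge = float(f[4])
                refs = tuple(None if r == "." else r for r in f[5:8])
                length = float(f[8])
                angle = float(f[9])
                tor = f[10]
                try:
                    tor = float(tor)
                except ValueError:
                    pass  # builder token
                current.atoms.append(TemplateAtom(name, elem, typ, charge,
                                                  refs, length, angle, tor))
            elif line.startswith("bond"):
                if current is None:
                    raise ValueError(f"{path}:{lineno}: bond outside residue section")
                f = line.split()
                current.bonds.append((f[1], f[2], int(f[3])))
            else:
                raise ValueError(f"{path}:{lineno}: unrecognized line {raw!r}")
        for tpl in self.templates.values():
            tpl.validate()

    def _load_names(self, path: Path):
        for raw in path.read_text().splitlines():
            line = raw.split("#")[0].strip()
            if not line:
                continue
            f = line.split()
            alias, canonical = f[0], f[1]
            residue = f[2].upper() if len(f) > 2 else None
            self.aliases[(alias.upper(), residue)] = canonical

    # -- lookup -----------------------------------------------------------

    def has_residue(self, name: str) -> bool:
        return (name.upper(), "internal") in self.templates

    def get_template(self, name: str, variant: str = "internal") -> FragmentTemplate:
        key = (name.upper(), variant)
        if key not in self.templates:
            raise KeyError(f"no template for residue {name!r} variant {variant!r}")
        return self.templates[key]

    @staticmethod
    def variant_of(chain: Chain, residue: Residue) -> str:
        amino = [r for r in chain.residues]
        if residue.is_n_terminal and residue.is_c_terminal:
            return "free"
        if residue.is_n_terminal:
            return "n_terminal"
        if residue.is_c_terminal:
            return "c_terminal"
        if residue in amino:
            idx = amino.index(residue)
            first, last = idx == 0, idx == len(amino) - 1
            if first and last:
                return "free"
            if first:
                return "n_terminal"
            if last:
                return "c_terminal"
        return "internal"

    def template_for(self, chain: Optional[Chain], residue: Residue) -> Optional[FragmentTemplate]:
        if not self.has_residue(residue.name):
            return None
        if residue.name.upper() == "HOH":
            return self.get_template("HOH", "free")
        variant = self.variant_of(chain, residue) if chain is not None else "free"
        return self.get_template(residue.name, variant)

    def normalize_atom_name(self, name: str, residue_name: Optional[str] = None) -> str:
        name = name.strip()
        key = name.upper()
        res = residue_name.upper() if residue_name else None
        if (key, res) in self.aliases:
            return self.aliases[(key, res)]
        if (key, None) in self.aliases:
            return self.aliases[(key, None)]
        if name and name[0].isdigit():  # 1HB -> HB1
            return name[1:] + name[0]
        return name

    # -- preparation processors (apply as callables) ----------------------

    def normalize_names(self, system: MolecularSystem) -> MolecularSystem:
        """Strip padding and map aliases to canonical template names."""
        for chain in system.chains:
            for res in chain.residues:
                tpl = self.template_for(chain, res)
                for atom in res.atoms:
                    new = self.normalize_atom_name(atom.name, res.name)
                    if tpl is not None and tpl.atom(new) is None and tpl.atom(atom.name.strip()):
                        new = atom.name.strip()  # alias would leave the template
                    atom.name = new
        for mol in system.molecules:
            for atom in mol.atoms:
                atom.name = atom.name.strip()
        return system

    def add_hydrogens(self, system: MolecularSystem) -> MolecularSystem:
        """Create every template hydrogen missing from each known residue.

        Placement uses the template's ideal internal coordinates relative to
        atoms already present; when a torsion reference is unavailable the
        hydrogen falls back to ideal geometry around its heavy-atom parent.
        Existing atoms are never moved.
        """
        for chain in system.chains:
            prev_res: Optional[Residue] = None
            for res in chain.residues:
                tpl = self.template_for(chain, res)
                if tpl is None:
                    log.warning("add_hydrogens: unknown residue %s %s", res.name, res.id)
                    prev_res = res
                    continue
                self._add_hydrogens_to(system, res, tpl, prev_res)
                prev_res = res
        for mol in system.molecules:
            pass  # free molecules are handled via fill_valence (build module)
        return system

    def _resolve_ref(self, name: Optional[str], res: Residue,
                     prev_res: Optional[Residue]) -> Optional[Atom]:
        if name is None:
            return None
        if name.startswith("-"):
            return prev_res.atom_by_name(name[1:]) if prev_res is not None else None
        return res.atom_by_name(name)

    def _add_hydrogens_to(self, system: MolecularSystem, res: Residue,
                          tpl: FragmentTemplate, prev_res: Optional[Residue]):
        # new hydrogens get template charges only when the residue already
        # carries charges; otherwise charge assignment is the force field's job
        charged = any(abs(a.partial_charge) > 1e-12 for a in res.atoms)
        for ta in tpl.atoms:
            if ta.element != "H" or res.atom_by_name(ta.name) is not None:
                continue
            r1 = self._resolve_ref(ta.refs[0], res, prev_res)
            if r1 is None:
                continue  # parent heavy atom absent; reported by check_residues
            r2 = self._resolve_ref(ta.refs[1], res, prev_res)
            r3 = self._resolve_ref(ta.refs[2], res, prev_res)
            torsion = ta.torsion if isinstance(ta.torsion, float) else None
            if r2 is not None and r3 is not None and torsion is not None:
                pos = place_from_internal(r1.position, r2.position, r3.position,
                                          ta.length, ta.angle, torsion)
            else:
                pos = self._fallback_position(r1, r2, ta)
            atom = Atom(ta.name, "H", pos,
                        partial_charge=ta.charge if charged else 0.0)
            atom.type_name = ta.type_name
            res.add_atom(atom)
            system.add_bond(r1, atom)

    def _fallback_position(self, r1: Atom, r2: Optional[Atom],
                           ta: TemplateAtom) -> np.ndarray:
        """Ideal placement when torsion references are missing."""
        length = ta.length or _H_LENGTH.get(r1.element, 1.0)
        neighbors = r1.bonded_atoms()
        if r2 is None and neighbors:
            r2 = neighbors[0]
        if r2 is None:
            return r1.position + np.array([length, 0.0, 0.0])
        angle = ta.angle if ta.angle else 109.47
        others = [n for n in neighbors if n is not r2]
        if others:
            # keep new H staggered away from an existing neighbour
            pos = place_from_internal(r1.position, r2.position,
                                      others[0].position, length, angle, 180.0)
        else:
            helper = r2.position + np.array([0.37, 1.11, 0.52])  # arbitrary non-collinear
            pos = place_from_internal(r1.position, r2.position, helper,
                                      length, angle, 60.0)
        return pos

    def build_bonds(self, system: MolecularSystem) -> MolecularSystem:
        """Create template bonds plus peptide and disulfide links.

        Intra-residue bonds come from the template name pairs (only when both
        atoms exist).  Sequence-adjacent residues get a C(i)-N(i+1) bond when
        the distance is <= 2.0 A; SG-SG pairs <= 2.5 A become disulfides.
        Never duplicates an existing bond.
        """
        for chain in system.chains:
            prev: Optional[Residue] = None
            for res in chain.residues:
                tpl = self.template_for(chain, res)
                if tpl is not None:
                    for name_a, name_b, order in tpl.bonds:
                        a = res.atom_by_name(name_a)
                        b = res.atom_by_name(name_b)
                        if a is not None and b is not None:
                            system.add_bond(a, b, order)
                if prev is not None:
                    c = prev.atom_by_name("C")
                    n = res.atom_by_name("N")
                    if c is not None and n is not None and \
                            measure_distance(c, n) <= 2.0:
                        system.add_bond(c, n, 1)
                prev = res
        # disulfides
        sgs = [a for r in system.residues() if r.name.upper() == "CYS"
               for a in r.atoms if a.name == "SG"]
        for i in range(len(sgs)):
            for j in range(i + 1, len(sgs)):
                if measure_distance(sgs[i], sgs[j]) <= 2.5:
                    system.add_bond(sgs[i], sgs[j], 1)
        return system


def _template_bond_length(tpl: FragmentTemplate, name_a: str, name_b: str) -> Optional[float]:
    for ta in tpl.atoms:
        if ta.name == name_a and ta.refs[0] == name_b:
            return ta.length
        if ta.name == name_b and ta.refs[0] == name_a:
            return ta.length
    return None


def check_residues(system: MolecularSystem, db: FragmentDatabase) -> CheckReport:
    """Validate residues against their templates.

    Emits: missing template atoms (error), atoms not in the template
    (warning), bonded pairs deviating > 15 % from the template length
    (warning), residue charge sums off the template integer by > 0.05 e
    (warning), non-bonded pairs closer than 0.5 A (error), and unknown
    residue names (error).
    """
    report = CheckReport()
    for chain in system.chains:
        for res in chain.residues:
            loc = f"{chain.id}/{res.name}{res.id}{res.insertion_code}"
            tpl = db.template_for(chain, res)
            if tpl is None:
                report.add("error", "unknown_residue", loc,
                           f"residue name {res.name!r} not in fragment database")
                continue
            present = {a.name for a in res.atoms}
            for ta in tpl.atoms:
                if ta.name not in present:
                    report.add("error", "missing_atom", loc,
                               f"template atom {ta.name} missing")
            tpl_names = {a.name for a in tpl.atoms}
            for name in sorted(present - tpl_names):
                report.add("warning", "unknown_atom", loc,
                           f"atom {name} not in template for {res.name}")
            # bond lengths: intra-residue vs template; peptide/disulfide links
            res_atoms = set(map(id, res.atoms))
            for atom in res.atoms:
                for bond in atom.bonds:
                    other = bond.partner(atom)
                    if id(other) in res_atoms:
                        if other.name <= atom.name:
                            continue  # each intra pair once
                        ideal = _template_bond_length(tpl, atom.name, other.name)
                    elif atom.name == "C" and other.name == "N":
                        ideal = 1.33  # peptide bond, checked from the C side
                    elif atom.name == "SG" and other.name == "SG" and id(atom) < id(other):
                        ideal = 2.04
                    else:
                        continue
                    if ideal is None:
                        continue
                    d = measure_distance(atom, other)
                    if abs(d - ideal) / ideal > 0.15:
                        report.add("warning", "bond_length_deviation", loc,
                                   f"bond {atom.name}-{other.name} length "
                                   f"{d:.3f} A deviates from template {ideal:.3f} A")
            total = sum(a.partial_charge for a in res.atoms)
            if abs(total - tpl.net_charge) > 0.05:
                report.add("warning", "charge_anomaly", loc,
                           f"residue charge {total:.3f} differs from template "
                           f"net {tpl.net_charge}")
    # clashes: non-bonded pairs < 0.5 A, system-wide
    atoms = list(system.atoms())
    if atoms:
        coords = np.array([a.position for a in atoms])
        n = len(atoms)
        for i in range(n):
            d2 = np.sum((coords[i + 1:] - coords[i]) ** 2, axis=1)
            for off in np.nonzero(d2 < 0.25)[0]:
                j = i + 1 + int(off)
                if atoms[i].bond_to(atoms[j]) is None:
                    report.add("error", "atom_clash", f"atoms {i + 1},{j + 1}",
                               f"non-bonded atoms {atoms[i].name}/{atoms[j].name} "
                               f"are {math.sqrt(float(d2[off])):.3f} A apart")
    return report


def most_likely_rotamer(library: RotamerLibrary, residue_name: str) -> Rotamer:
    """Maximum-probability rotamer; ties broken by list order."""
    rotamers = library[residue_name]
    return max(rotamers, key=lambda r: r.probability)  # stable: first max wins


def apply_rotamer(system: MolecularSystem, residue: Residue,
                  rotamer: Rotamer) -> MolecularSystem:
    """Drive the residue's chi torsions to the rotamer's angles (chi1->chiN)."""
    quads = CHI_ATOMS.get(residue.name.upper(), [])
    for i, chi in enumerate(rotamer.chis):
        if chi is None or i >= len(quads):
            continue
        names = quads[i]
        atoms = [residue.atom_by_name(n) for n in names]
        if any(a is None for a in atoms):
            missing = [n for n, a in zip(names, atoms) if a is None]
            raise ValueError(
                f"cannot set chi{i + 1} of {residue.name} {residue.id}: "
                f"missing atom(s) {', '.join(missing)}")
        set_dihedral(system, *atoms, chi)
    return system
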