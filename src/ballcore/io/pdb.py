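"""PDB coordinate-section reader/writer (wwPDB v3.3 fixed-column subset).

Handled records: ATOM, HETATM, TER, CONECT, END.  Everything else is ignored.
Coordinates come from columns 31-54 (1-based), the element from columns 77-78
with a fallback to the leading letters of the atom name.  altLoc handling is
configurable (first seen or highest occupancy, default the latter).
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass
from typing import IO, Iterable, Union

from ..model import Atom, Chain, MolecularSystem, Residue, PERIODIC_TABLE

log = logging.getLogger(__name__)

__all__ = ["PdbParseOptions", "PdbFormatError", "read_pdb", "write_pdb"]


class PdbFormatError(ValueError):
    pass


@dataclass(frozen=True)
class PdbParseOptions:
    keep_hetero: bool = True
    altloc_policy: str = "highest_occupancy"  # or "first"
    strict: bool = False

    def __post_init__(self):
        if self.altloc_policy not in ("first", "highest_occupancy"):
            raise ValueError(f"unknown altloc policy: {self.altloc_policy}")


def _guess_element(atom_name: str, hetero: bool) -> str:
    """Element from an atom name when columns 77-78 are absent.

    Two-letter symbols are only accepted for HETATM names (protein atom names
    like "CA" are calcium lookalikes but mean carbon-alpha).
    """
    name = atom_name.strip().lstrip("0123456789")
    if not name:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    if hetero and len(name) >= 2:
        two = name[:2].capitalize()
        if two in PERIODIC_TABLE and two not in ("Ca", "Na"):
            return two
    one = name[0].upper()
    if one in PERIODIC_TABLE:
        return one
    two = name[:2].capitalize()
    if two in PERIODIC_TABLE:
        return two
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")


def read_pdb(source: Union[str, IO[str]],
             opts: PdbParseOptions | None = None) -> MolecularSystem:
    """Parse a PDB text stream (or path) into a :class:`MolecularSystem`.

    One residue is created per (chainID, resSeq, iCode); TER closes the
    current chain; CONECT records become (deduplicated) bonds.
    """
    opts = opts or PdbParseOptions()
    if isinstance(source, str):
        with open(source) as fh:
            return read_pdb(fh, opts)

    system = MolecularSystem()
    chain: Chain | None = None
    residue: Residue | None = None
    residue_key = None
    chain_open = False  # False after TER: next ATOM starts a new chain
    serial_map: dict[int, Atom] = {}
    # (residue_key, name) -> (atom, altloc, occupancy) for altLoc resolution
    alt_seen: dict[tuple, tuple[Atom, str, float]] = {}

    def fail(lineno: int, msg: str):
        if opts.strict:
            raise PdbFormatError(f"line {lineno}: {msg}")
        log.warning("skipping PDB line %d: %s", lineno, msg)

    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        record = line[:6].rstrip().upper()
        if record in ("ATOM", "HETATM"):
            hetero = record == "HETATM"
            if hetero and not opts.keep_hetero:
                continue
            if len(line) < 54:
                fail(lineno, "record too short for coordinates")
                continue
            try:
                serial = int(line[6:11])
            except ValueError:
                serial = 0
            name = line[12:16].strip()
            altloc = line[16:17].strip()
            resname = line[17:20].strip() or line[17:21].strip()
            chain_id = line[21:22].strip() or "A"
            try:
                resseq = int(line[22:26])
            except ValueError:
                fail(lineno, f"bad residue number {line[22:26]!r}")
                continue
            icode = line[26:27].strip()
            try:
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except ValueError:
                fail(lineno, f"unparseable coordinate field {line[30:54]!r}")
                continue
            occupancy = 1.0
            tempf = 0.0
            if len(line) >= 60:
                try:
                    occupancy = float(line[54:60])
                except ValueError:
                    pass
            if len(line) >= 66:
                try:
                    tempf = float(line[60:66])
                except ValueError:
                    pass
            element = line[76:78].strip() if len(line) >= 77 else ""
            try:
                if element:
                    element = element.capitalize()
                    if element not in PERIODIC_TABLE:
                        element = _guess_element(name, hetero)
                else:
                    element = _guess_element(name, hetero)
            except ValueError as exc:
                fail(lineno, str(exc))
                continue

            if chain is None or chain.id != chain_id or not chain_open:
                chain = system.add_chain(id=chain_id)
                chain_open = True
                residue = None
                residue_key = None
            key = (len(system.chains) - 1, chain_id, resseq, icode)
            if residue is None or key != residue_key:
                residue = chain.add_residue(Residue(resname, resseq, icode))
                residue_key = key

            akey = (key, name)
            if altloc and akey in alt_seen:
                prev_atom, _prev_loc, prev_occ = alt_seen[akey]
                if opts.altloc_policy == "highest_occupancy" and occupancy > prev_occ:
                    prev_atom.position = Atom(name, element, (x, y, z)).position
                    prev_atom.occupancy = occupancy
                    prev_atom.temp_factor = tempf
                    prev_atom.serial = serial
                    serial_map[serial] = prev_atom
                    alt_seen[akey] = (prev_atom, altloc, occupancy)
                continue

            atom = Atom(name, element, (x, y, z), serial=serial,
                        occupancy=occupancy, temp_factor=tempf, hetero=hetero)
            residue.add_atom(atom)
            serial_map[serial] = atom
            if altloc:
                alt_seen[akey] = (atom, altloc, occupancy)
        elif record == "TER":
            chain_open = False
            residue = None
            residue_key = None
        elif record == "CONECT":
            fields = [line[6 + 5 * i:11 + 5 * i] for i in range(5)]
            serials = []
            for f in fields:
                f = f.strip()
                if f:
                    try:
                        serials.append(int(f))
                    except ValueError:
                        fail(lineno, f"bad CONECT serial {f!r}")
            if len(serials) >= 2 and serials[0] in serial_map:
                a = serial_map[serials[0]]
                for s in serials[1:]:
                    b = serial_map.get(s)
                    if b is not None and b is not a:
                        system.add_bond(a, b)  # add_bond dedups
        elif record == "END":
            break
    return system


def _format_atom_name(atom: Atom) -> str:
    """PDB name field alignment: element in cols 13-14, so one-letter-element
    names of length <= 3 are right-shifted by one."""
    name = atom.name[:4]
    if len(name) < 4 and len(atom.element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(system: MolecularSystem, sink: Union[str, IO[str]]) -> None:
    """Write fixed-column ATOM/HETATM records, TER per chain, END last.

    Serials are renumbered 1..N in traversal order; serials above 99999 wrap
    (with a warning) because the fixed columns cannot widen.
    """
    if isinstance(sink, str):
        with open(sink, "w") as fh:
            write_pdb(system, fh)
            return

    serial = 0
    wrapped = False

    def next_serial() -> int:
        nonlocal serial, wrapped
        serial += 1
        if serial > 99999:
            if not wrapped:
                warnings.warn("PDB serial overflow: wrapping above 99999")
                wrapped = True
            return serial % 100000
        return serial

    def emit(atom: Atom, resname: str, chain_id: str, resseq: int, icode: str):
        x, y, z = atom.position
        if max(abs(x), abs(y), abs(z)) >= 10000.0:
            raise ValueError("coordinate unrepresentable in PDB (|x| >= 10000 A)")
        record = "HETATM" if atom.hetero else "ATOM  "
        elem = atom.element.upper().rjust(2)
        sink.write(
            f"{record}{next_serial():5d} {_format_atom_name(atom)} "
            f"{resname[:3]:>3s} {chain_id[:1]:1s}{resseq % 10000:4d}{icode[:1]:1s}"
            f"   {x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.temp_factor:6.2f}"
            f"          {elem}\n")

    for chain in system.chains:
        for res in chain.residues:
            for atom in res.atoms:
                emit(atom, res.name, chain.id, res.id, res.insertion_code or " ")
        sink.write("TER\n")
    for i, mol in enumerate(system.molecules):
        for atom in mol.atoms:
            emit(atom, mol.name[:3] or "UNL", " ", i + 1, " ")
    sink.write("END\n")
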