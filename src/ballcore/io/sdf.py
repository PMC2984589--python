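"""MOL/SDF V2000 reader/writer.

Supports the V2000 connection table (counts line, atom block, bond block),
``M  CHG`` formal-charge lines, ``M  END`` terminators and ``$$$$`` record
separators.  Bond order code 4 maps to the AROMATIC order and back.
"""

from __future__ import annotations

from typing import IO, Union

from ..model import AROMATIC, Atom, MolecularSystem

__all__ = ["read_sdf", "write_sdf", "SdfFormatError"]


class SdfFormatError(ValueError):
    pass


def _parse_mol_block(lines: list[str], record_index: int) -> MolecularSystem:
    if len(lines) < 4:
        raise SdfFormatError("truncated MOL block: missing counts line")
    name = lines[0].strip()
    counts = lines[3]
    try:
        n_atoms = int(counts[0:3])
        n_bonds = int(counts[3:6])
    except (ValueError, IndexError):
        raise SdfFormatError(f"bad counts line: {counts!r}") from None

    system = MolecularSystem(name=name)
    mol = system.add_molecule(name=name)
    atoms: list[Atom] = []
    idx = 4
    for i in range(n_atoms):
        if idx >= len(lines):
            raise SdfFormatError("truncated MOL block: atom block ends early")
        line = lines[idx]
        idx += 1
        try:
            x = float(line[0:10])
            y = float(line[10:20])
            z = float(line[20:30])
            symbol = line[31:34].strip()
        except (ValueError, IndexError):
            raise SdfFormatError(f"bad atom line {idx}: {line!r}") from None
        atoms.append(mol.add_atom(Atom(symbol, symbol, (x, y, z), serial=i + 1)))
    for _ in range(n_bonds):
        if idx >= len(lines):
            raise SdfFormatError("truncated MOL block: bond block ends early")
        line = lines[idx]
        idx += 1
        try:
            a = int(line[0:3])
            b = int(line[3:6])
            code = int(line[6:9])
        except (ValueError, IndexError):
            raise SdfFormatError(f"bad bond line {idx}: {line!r}") from None
        if not (1 <= a <= n_atoms and 1 <= b <= n_atoms):
            raise SdfFormatError(f"bond references nonexistent atom: {line!r}")
        order = AROMATIC if code == 4 else code
        system.add_bond(atoms[a - 1], atoms[b - 1], order)

    saw_end = False
    while idx < len(lines):
        line = lines[idx]
        idx += 1
        if line.startswith("M  END"):
            saw_end = True
            break
        if line.startswith("M  CHG"):
            fields = line.split()
            try:
                n = int(fields[2])
                pairs = fields[3:3 + 2 * n]
                for j in range(n):
                    ai = int(pairs[2 * j])
                    chg = int(pairs[2 * j + 1])
                    atoms[ai - 1].formal_charge = chg
            except (ValueError, IndexError):
                raise SdfFormatError(f"bad M  CHG line: {line!r}") from None
    if not saw_end:
        raise SdfFormatError(f"truncated MOL block (record {record_index + 1}): missing M  END")
    return system


def read_sdf(source: Union[str, IO[str]]) -> list[MolecularSystem]:
    """Read an SD file; one :class:`MolecularSystem` per ``$$$$`` record."""
    if isinstance(source, str):
        with open(source) as fh:
            return read_sdf(fh)
    systems = []
    block: list[str] = []
    for raw in source.read().split("\n"):
        if raw.startswith("$$$$"):
            if any(ln.strip() for ln in block):
                systems.append(_parse_mol_block(block, len(systems)))
            block = []
        else:
            block.append(raw)
    if any(ln.strip() for ln in block):
        systems.append(_parse_mol_block(block, len(systems)))
    return systems


def _write_mol_block(system: MolecularSystem, sink: IO[str]) -> None:
    atoms = list(system.atoms())
    bonds = list(system.bonds())
    index = {id(a): i + 1 for i, a in enumerate(atoms)}
    sink.write(f"{system.name or ''}\n")
    sink.write("  ballcore\n")
    sink.write("\n")
    sink.write(f"{len(atoms):3d}{len(bonds):3d}  0  0  0  0  0  0  0  0999 V2000\n")
    for atom in atoms:
        x, y, z = atom.position
        sink.write(f"{x:10.4f}{y:10.4f}{z:10.4f} {atom.element:<3s} 0  0  0  0  0  0  0  0  0  0  0  0\n")
    for bond in bonds:
        code = 4 if bond.order == AROMATIC else bond.order
        sink.write(f"{index[id(bond.atom_a)]:3d}{index[id(bond.atom_b)]:3d}{code:3d}  0\n")
    charged = [(index[id(a)], a.formal_charge) for a in atoms if a.formal_charge]
    for start in range(0, len(charged), 8):
        group = charged[start:start + 8]
        sink.write(f"M  CHG{len(group):3d}" +
                   "".join(f"{i:4d}{c:4d}" for i, c in group) + "\n")
    sink.write("M  END\n")


def write_sdf(systems, sink: Union[str, IO[str]]) -> None:
    """Write one or more systems as an SD file (``$$$$`` separated)."""
    if isinstance(sink, str):
        with open(sink, "w") as fh:
            write_sdf(systems, fh)
            return
    if isinstance(systems, MolecularSystem):
        systems = [systems]
    for system in systems:
        _write_mol_block(system, sink)
        sink.write("$$$$\n")
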