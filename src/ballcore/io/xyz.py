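"""Plain XYZ reader/writer: count line, comment line, then "symbol x y z"."""

from __future__ import annotations

from typing import IO, Union

from ..model import Atom, MolecularSystem

__all__ = ["read_xyz", "write_xyz", "XyzFormatError"]


class XyzFormatError(ValueError):
    pass


def read_xyz(source: Union[str, IO[str]]) -> MolecularSystem:
    if isinstance(source, str):
        with open(source) as fh:
            return read_xyz(fh)
    lines = source.read().splitlines()
    if not lines:
        raise XyzFormatError("empty XYZ input")
    try:
        count = int(lines[0].strip())
    except ValueError:
        raise XyzFormatError(f"bad XYZ atom count line: {lines[0]!r}") from None
    comment = lines[1] if len(lines) > 1 else ""
    atom_lines = [ln for ln in lines[2:] if ln.strip()]
    if len(atom_lines) < count:
        raise XyzFormatError(
            f"XYZ atom count mismatch: header says {count}, found {len(atom_lines)}")
    system = MolecularSystem(name=comment.strip())
    mol = system.add_molecule(name=comment.strip())
    for i, line in enumerate(atom_lines[:count]):
        parts = line.split()
        if len(parts) < 4:
            raise XyzFormatError(f"bad XYZ atom line {i + 3}: {line!r}")
        symbol = parts[0]
        try:
            x, y, z = (float(p) for p in parts[1:4])
        except ValueError:
            raise XyzFormatError(f"bad XYZ coordinates on line {i + 3}: {line!r}") from None
        mol.add_atom(Atom(symbol, symbol, (x, y, z), serial=i + 1))
    return system


def write_xyz(system: MolecularSystem, sink: Union[str, IO[str]]) -> None:
    if isinstance(sink, str):
        with open(sink, "w") as fh:
            write_xyz(system, fh)
            return
    atoms = list(system.atoms())
    sink.write(f"{len(atoms)}\n")
    sink.write(f"{system.name or ''}\n")
    for atom in atoms:
        x, y, z = atom.position
        sink.write(f"{atom.element:<2s} {x:.6f} {y:.6f} {z:.6f}\n")
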