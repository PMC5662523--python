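"""XYZ codec: count line, comment line, then ``symbol x y z`` per atom (Å).

XYZ carries no bonds; conversions through it lose bond data (flagged by the
dispatcher in :mod:`chemstore.convert`).
"""

from __future__ import annotations

from . import elements
from .model import Molecule


class XyzParseError(ValueError):
    pass


def read_xyz(text: str) -> Molecule:
    lines = text.splitlines()
    if not lines:
        raise XyzParseError("empty XYZ input")
    try:
        count = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise XyzParseError(f"bad atom count line: {lines[0]!r}") from None
    comment = lines[1].strip() if len(lines) > 1 else ""
    atom_lines = [ln for ln in lines[2:] if ln.strip()]
    if len(atom_lines) < count:
        raise XyzParseError(
            f"count line claims {count} atoms but body has {len(atom_lines)}"
        )
    numbers: list[int] = []
    coords: list[float] = []
    for ln in atom_lines[:count]:
        parts = ln.split()
        if len(parts) < 4:
            raise XyzParseError(f"bad atom line: {ln!r}")
        try:
            numbers.append(elements.atomic_number(parts[0]))
        except ValueError as exc:
            raise XyzParseError(str(exc)) from None
        try:
            coords.extend(float(p) for p in parts[1:4])
        except ValueError:
            raise XyzParseError(f"bad coordinate in line: {ln!r}") from None
    return Molecule(atomic_numbers=numbers, coords_3d=coords, name=comment or None)


def write_xyz(mol: Molecule) -> str:
    lines = [str(mol.atom_count), mol.name or ""]
    for i, z in enumerate(mol.atomic_numbers):
        x, y, zc = mol.atom_position(i)
        lines.append(f"{elements.symbol(z):<3s} {x:14.6f} {y:14.6f} {zc:14.6f}")
    return "\n".join(lines) + "\n"
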