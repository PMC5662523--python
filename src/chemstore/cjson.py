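"""Chemical JSON codec: the array-oriented, visualization-focused dialect.

Layout: a top-level ``chemicalJson`` version integer, ``atoms.elements.number``
(atomic numbers), ``atoms.coords.3d`` (flat 3N angstrom array, atom i at
offset 3i), ``bonds.connections.index`` (flat pairs) with ``bonds.order``,
optional ``vibrations`` (frequencies, intensities, per-mode ``eigenVectors``)
and an optional ``volume`` block. Unknown keys round-trip untouched for
forward compatibility.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Any

from .model import (
    Bond,
    Molecule,
    ValidationError,
    VibrationalData,
    VolumetricData,
)

FORMAT_VERSION = 1

_KNOWN_TOP_KEYS = {
    "chemicalJson", "name", "inchi", "inchikey", "atoms", "bonds",
    "vibrations", "volume", "properties",
}


@dataclass
class Violation:
    """One structural problem found by :func:`validate_cjson`."""

    path: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.path}: {self.message}"


def validate_cjson(doc: Any) -> list[Violation]:
    """Check a parsed JSON object against the structural invariants.

    Returns a list of violations (empty iff valid); violations are data,
    not exceptions, so a caller can report every problem at once.
    """
    out: list[Violation] = []
    if not isinstance(doc, dict):
        return [Violation("$", "document must be a JSON object")]

    atoms = doc.get("atoms", {})
    numbers = _dig(atoms, "elements", "number") or []
    coords = _dig(atoms, "coords", "3d") or []
    if not isinstance(numbers, list):
        out.append(Violation("atoms.elements.number", "must be an array"))
        numbers = []
    if not isinstance(coords, list):
        out.append(Violation("atoms.coords.3d", "must be an array"))
        coords = []
    n = len(numbers)
    if len(coords) != 3 * n:
        out.append(
            Violation(
                "atoms.coords.3d",
                f"length {len(coords)} != 3 x {n} elements (flat 3N layout)",
            )
        )
    for i, z in enumerate(numbers):
        if not isinstance(z, int) or not 1 <= z <= 118:
            out.append(
                Violation(f"atoms.elements.number[{i}]", f"atomic number out of range: {z!r}")
            )

    bonds = doc.get("bonds")
    if bonds is not None:
        conn = _dig(bonds, "connections", "index") or []
        order = bonds.get("order", []) if isinstance(bonds, dict) else []
        if len(conn) % 2 != 0:
            out.append(
                Violation("bonds.connections.index", f"length {len(conn)} is odd")
            )
        elif order and len(order) != len(conn) // 2:
            out.append(
                Violation(
                    "bonds.order",
                    f"length {len(order)} != connection pairs {len(conn) // 2}",
                )
            )
        for i, idx in enumerate(conn):
            if not isinstance(idx, int) or not 0 <= idx < n:
                out.append(
                    Violation(
                        f"bonds.connections.index[{i}]",
                        f"atom index {idx!r} out of range [0, {n})",
                    )
                )
        for pair in range(len(conn) // 2):
            if conn[2 * pair] == conn[2 * pair + 1]:
                out.append(
                    Violation(
                        f"bonds.connections.index[{2 * pair}]",
                        f"self-bond on atom {conn[2 * pair]}",
                    )
                )
        for i, o in enumerate(order):
            if not isinstance(o, int) or o < 1:
                out.append(Violation(f"bonds.order[{i}]", f"bond order must be >= 1, got {o!r}"))

    vib = doc.get("vibrations")
    if vib is not None:
        freqs = vib.get("frequencies", []) if isinstance(vib, dict) else []
        modes = vib.get("eigenVectors", []) if isinstance(vib, dict) else []
        intens = vib.get("intensities") if isinstance(vib, dict) else None
        if len(modes) != len(freqs):
            out.append(
                Violation(
                    "vibrations.eigenVectors",
                    f"{len(modes)} mode vectors for {len(freqs)} frequencies",
                )
            )
        if intens is not None and len(intens) != len(freqs):
            out.append(
                Violation("vibrations.intensities", "length must match frequencies")
            )
        for i, m in enumerate(modes):
            if not isinstance(m, list) or len(m) != 3 * n:
                out.append(
                    Violation(
                        f"vibrations.eigenVectors[{i}]",
                        f"mode vector length must be 3 x {n}",
                    )
                )

    vol = doc.get("volume")
    if vol is not None and isinstance(vol, dict):
        dims = vol.get("dimensions", [])
        values = vol.get("values", [])
        if len(dims) != 3 or any(not isinstance(d, int) or d < 1 for d in dims):
            out.append(Violation("volume.dimensions", f"must be 3 positive integers, got {dims!r}"))
        elif len(values) != dims[0] * dims[1] * dims[2]:
            out.append(
                Violation(
                    "volume.values",
                    f"length {len(values)} != {dims[0]}x{dims[1]}x{dims[2]}",
                )
            )
    return out


def parse_cjson(
    text: str,
) -> tuple[Molecule, VibrationalData | None, VolumetricData | None]:
    """Parse Chemical JSON text into core model objects.

    Unknown top-level keys are preserved in ``Molecule.extras`` so that a
    later write round-trips them. Raises :class:`ValidationError` listing
    every structural violation, or ``json.JSONDecodeError`` on bad JSON.
    """
    doc = json.loads(text)
    violations = validate_cjson(doc)
    if violations:
        raise ValidationError(
            "invalid Chemical JSON: " + "; ".join(str(v) for v in violations)
        )

    atoms = doc.get("atoms", {})
    numbers = list(_dig(atoms, "elements", "number") or [])
    coords = [float(c) for c in (_dig(atoms, "coords", "3d") or [])]

    bonds: list[Bond] = []
    bsec = doc.get("bonds")
    if bsec:
        conn = _dig(bsec, "connections", "index") or []
        order = bsec.get("order") or [1] * (len(conn) // 2)
        bonds = [
            Bond(conn[2 * i], conn[2 * i + 1], order[i]) for i in range(len(conn) // 2)
        ]

    extras = {k: v for k, v in doc.items() if k not in _KNOWN_TOP_KEYS}
    mol = Molecule(
        atomic_numbers=numbers,
        coords_3d=coords,
        bonds=bonds,
        name=doc.get("name"),
        inchi=doc.get("inchi"),
        inchikey=doc.get("inchikey"),
        extras=extras,
    )

    vib = None
    vsec = doc.get("vibrations")
    if vsec:
        vib = VibrationalData(
            frequencies=[float(f) for f in vsec.get("frequencies", [])],
            modes=[[float(x) for x in m] for m in vsec.get("eigenVectors", [])],
            intensities=(
                [float(x) for x in vsec["intensities"]]
                if vsec.get("intensities") is not None
                else None
            ),
        )

    vol = None
    volsec = doc.get("volume")
    if volsec:
        vol = VolumetricData(
            origin=tuple(volsec.get("origin", (0.0, 0.0, 0.0))),
            spacing=tuple(volsec.get("spacing", (1.0, 1.0, 1.0))),
            dims=tuple(volsec.get("dimensions")),
            values=[float(v) for v in volsec.get("values", [])],
            label=volsec.get("label", ""),
        )
    return mol, vib, vol


def build_cjson(
    mol: Molecule,
    vib: VibrationalData | None = None,
    vol: VolumetricData | None = None,
) -> dict[str, Any]:
    """Build the Chemical JSON document dict for a molecule."""
    doc: dict[str, Any] = {"chemicalJson": FORMAT_VERSION}
    if mol.name is not None:
        doc["name"] = mol.name
    if mol.inchi is not None:
        doc["inchi"] = mol.inchi
    if mol.inchikey is not None:
        doc["inchikey"] = mol.inchikey
    doc["atoms"] = {
        "elements": {"number": list(mol.atomic_numbers)},
        "coords": {"3d": list(mol.coords_3d)},
    }
    if mol.bonds:
        conn: list[int] = []
        orders: list[int] = []
        for b in mol.bonds:
            conn.extend((b.a, b.b))
            orders.append(b.order)
        doc["bonds"] = {"connections": {"index": conn}, "order": orders}
    if vib is not None:
        vsec: dict[str, Any] = {
            "frequencies": list(vib.frequencies),
            "eigenVectors": [list(m) for m in vib.modes],
        }
        if vib.intensities is not None:
            vsec["intensities"] = list(vib.intensities)
        doc["vibrations"] = vsec
    if vol is not None:
        doc["volume"] = {
            "origin": list(vol.origin),
            "spacing": list(vol.spacing),
            "dimensions": list(vol.dims),
            "values": list(vol.values),
            "label": vol.label,
        }
    doc.update(mol.extras)
    return doc


def write_cjson(
    mol: Molecule,
    vib: VibrationalData | None = None,
    vol: VolumetricData | None = None,
    indent: int | None = 2,
) -> str:
    """Serialize to Chemical JSON text.

    Numbers use Python's shortest round-trip float representation, so
    ``parse_cjson(write_cjson(x))`` reproduces coordinates exactly.
    """
    return json.dumps(build_cjson(mol, vib, vol), indent=indent)


def _dig(obj: Any, *keys: str) -> Any:
    for k in keys:
        if not isinstance(obj, dict):
            return None
        obj = obj.get(k)
    return obj
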