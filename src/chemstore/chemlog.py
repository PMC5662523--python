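"""ChemLog JSON codec: the object-oriented, unit-annotated log replacement.

A ChemLog document stores a sequence of calculations (one run of a quantum
chemistry code may chain several tasks) in a ``calculations`` array. Each
object of interest carries an ``id`` tag ("Molecule.2", "Atom.1.Mol.2",
"BasisSet.1", ...); to avoid duplicating information, a later use of the same
object is written as the id string, a pointer to the first mention. Physical
values are objects with explicit ``value`` and ``units`` keys.

Reference semantics are strict document order: an id may be defined once, and
a reference string must point to an id defined earlier in the document.
References are recognized only at the linking keys ``molecule``, ``basisSet``,
``calculationSetup`` and ``atom``; strings elsewhere are literals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Iterator

from .model import BOHR_TO_ANGSTROM, Molecule, Quantity, ValidationError
from . import elements

#: Keys whose string values are id-tag references.
REFERENCE_KEYS = frozenset({"molecule", "basisSet", "calculationSetup", "atom"})

_LENGTH_FACTORS = {"angstrom": 1.0, "bohr": BOHR_TO_ANGSTROM, "au": BOHR_TO_ANGSTROM}


class ReferenceError_(ValidationError):
    """A dangling, duplicate, or forward id-tag reference."""


@dataclass
class ChemLogCalculation:
    """One calculation in the sequence, with references already resolved."""

    setup: dict[str, Any]
    molecule: dict[str, Any]
    results: dict[str, Any]
    raw: dict[str, Any] = field(repr=False, default_factory=dict)

    @property
    def theory(self) -> str:
        return str(self.setup.get("theory", ""))

    @property
    def task(self) -> str:
        return str(self.setup.get("task", ""))


@dataclass
class ChemLogDocument:
    """A parsed ChemLog document: metadata, ordered calculations, registry."""

    simulation: dict[str, Any]
    calculations: list[ChemLogCalculation]
    registry: dict[str, Any]
    raw: dict[str, Any] = field(repr=False, default_factory=dict)

    def resolve_reference(self, idtag: str) -> Any:
        """Return the first-mention object registered under ``idtag``.

        Resolution is by identity: two resolutions of the same tag return
        the same object.
        """
        if not idtag or idtag not in self.registry:
            raise ReferenceError_(f"unknown id-tag: {idtag!r}")
        return self.registry[idtag]


def _walk(obj: Any, parent_key: str | None = None) -> Iterator[tuple[str | None, Any]]:
    """Depth-first, document-order walk yielding (reference-bearing key, value)."""
    if isinstance(obj, dict):
        yield (parent_key, obj)
        for k, v in obj.items():
            yield from _walk(v, k if k in REFERENCE_KEYS else None)
    elif isinstance(obj, list):
        for item in obj:
            yield from _walk(item, parent_key)
    elif isinstance(obj, str) and parent_key is not None:
        yield (parent_key, obj)


def parse_chemlog(text: str) -> ChemLogDocument:
    """Parse ChemLog JSON text, building the id registry and checking that
    every reference resolves to an earlier definition.

    Raises :class:`ReferenceError_` on duplicate, forward, or dangling
    id-tags; ``json.JSONDecodeError`` on malformed JSON.
    """
    data = json.loads(text)
    if not isinstance(data, dict):
        raise ValidationError("ChemLog document must be a JSON object")
    registry: dict[str, Any] = {}
    # single pass in document order: definitions must precede references
    for key, node in _walk(data):
        if isinstance(node, dict):
            idtag = node.get("id")
            if isinstance(idtag, str) and idtag:
                if idtag in registry:
                    raise ReferenceError_(f"duplicate id-tag: {idtag!r}")
                registry[idtag] = node
        elif isinstance(node, str):
            if node not in registry:
                raise ReferenceError_(
                    f"reference {node!r} under key {key!r} does not resolve to an "
                    "earlier id-tag (dangling or forward reference)"
                )

    calculations = []
    for raw_calc in data.get("calculations", []):
        setup = _deref(raw_calc.get("calculationSetup", {}), registry)
        molecule = _deref(raw_calc.get("molecule", {}), registry)
        results = raw_calc.get("calculationResults", {})
        calculations.append(
            ChemLogCalculation(setup=setup, molecule=molecule, results=results, raw=raw_calc)
        )
    return ChemLogDocument(
        simulation=data.get("simulation", {}),
        calculations=calculations,
        registry=registry,
        raw=data,
    )


def _deref(value: Any, registry: dict[str, Any]) -> Any:
    if isinstance(value, str):
        if value not in registry:
            raise ReferenceError_(f"unknown id-tag: {value!r}")
        return registry[value]
    return value


def write_chemlog(doc: ChemLogDocument | dict[str, Any], indent: int | None = 2) -> str:
    """Serialize a ChemLog document.

    The first mention of each id-tagged object is written inline; any later
    occurrence of an object whose id has already been emitted is written as
    its id-tag string (only at the reference-bearing keys). Writing a parsed
    document is the identity on its JSON structure.
    """
    data = doc.raw if isinstance(doc, ChemLogDocument) else doc
    emitted: set[str] = set()
    return json.dumps(_dedup(data, emitted, at_ref_key=False), indent=indent)


def _dedup(obj: Any, emitted: set[str], at_ref_key: bool) -> Any:
    if isinstance(obj, dict):
        idtag = obj.get("id")
        if at_ref_key and isinstance(idtag, str) and idtag in emitted:
            return idtag
        if isinstance(idtag, str) and idtag:
            emitted.add(idtag)
        return {
            k: _dedup(v, emitted, at_ref_key=k in REFERENCE_KEYS) for k, v in obj.items()
        }
    if isinstance(obj, list):
        return [_dedup(item, emitted, at_ref_key) for item in obj]
    return obj


def extract_molecule(doc: ChemLogDocument, calc_index: int) -> Molecule:
    """Flatten a calculation's per-atom objects into a core :class:`Molecule`.

    Coordinates are converted to angstrom using each atom's declared units.
    """
    if not 0 <= calc_index < len(doc.calculations):
        raise IndexError(
            f"calculation index {calc_index} out of range [0, {len(doc.calculations)})"
        )
    mol_obj = doc.calculations[calc_index].molecule
    atoms = mol_obj.get("atoms")
    if not atoms:
        raise ValidationError(f"calculation {calc_index} has no atoms")
    numbers: list[int] = []
    coords: list[float] = []
    for atom in atoms:
        elem = atom.get("element")
        if isinstance(elem, int):
            numbers.append(elem)
        else:
            numbers.append(elements.atomic_number(str(elem)))
        cobj = atom.get("coordinates")
        if cobj is None or "value" not in cobj:
            raise ValidationError(f"atom {atom.get('id')!r} missing coordinates")
        units = str(cobj.get("units", "angstrom")).lower()
        try:
            factor = _LENGTH_FACTORS[units]
        except KeyError:
            raise ValidationError(f"unknown length units {units!r}") from None
        coords.extend(float(x) * factor for x in cobj["value"])
    return Molecule(
        atomic_numbers=numbers,
        coords_3d=coords,
        name=mol_obj.get("name"),
        id=mol_obj.get("id"),
    )


# -- document construction helpers ----------------------------------------


def molecule_block(
    mol: Molecule, mol_id: str, units: str = "angstrom"
) -> dict[str, Any]:
    """Build a ChemLog molecule object (per-atom objects, explicit units)."""
    factor = 1.0 / _LENGTH_FACTORS[units]
    atoms = []
    for i, z in enumerate(mol.atomic_numbers):
        x, y, zc = mol.atom_position(i)
        atoms.append(
            {
                "id": f"Atom.{i + 1}.Mol.{mol_id.rsplit('.', 1)[-1]}",
                "element": elements.symbol(z),
                "coordinates": {
                    "value": [x * factor, y * factor, zc * factor],
                    "units": units,
                },
            }
        )
    block: dict[str, Any] = {"id": mol_id, "atoms": atoms}
    if mol.name:
        block["name"] = mol.name
    return block


def quantity_object(q: Quantity) -> dict[str, Any]:
    return {"value": q.value, "units": q.units}


def build_document(
    simulation: dict[str, Any], calculations: list[dict[str, Any]]
) -> ChemLogDocument:
    """Assemble raw calculation dicts into a parsed, validated document.

    Shared objects may be passed inline repeatedly; serialization dedups
    them. The assembled document is validated by a write/parse cycle.
    """
    raw = {"simulation": simulation, "calculations": calculations}
    return parse_chemlog(write_chemlog(raw, indent=None))
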