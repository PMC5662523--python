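"""CML (Chemical Markup Language) subset codec.

Supported subset: ``molecule/atomArray/atom(@id,@elementType,@x3,@y3,@z3)``
and ``bondArray/bond(@atomRefs2,@order)``; atom ids written as ``a1..aN``.
"""

from __future__ import annotations

from lxml import etree

from . import elements
from .model import Bond, Molecule


class CmlParseError(ValueError):
    pass


def read_cml(text: str | bytes) -> Molecule:
    try:
        root = etree.fromstring(text.encode() if isinstance(text, str) else text)
    except etree.XMLSyntaxError as exc:
        raise CmlParseError(f"malformed XML: {exc}") from None

    # tolerate a default CML namespace
    def findall(el: etree._Element, tag: str) -> list[etree._Element]:
        return [c for c in el.iter() if etree.QName(c).localname == tag]

    mol_el = root if etree.QName(root).localname == "molecule" else None
    if mol_el is None:
        mols = findall(root, "molecule")
        if not mols:
            raise CmlParseError("no <molecule> element found")
        mol_el = mols[0]

    numbers: list[int] = []
    coords: list[float] = []
    id_to_index: dict[str, int] = {}
    for atom in findall(mol_el, "atom"):
        sym = atom.get("elementType")
        if sym is None:
            raise CmlParseError("atom missing elementType attribute")
        try:
            numbers.append(elements.atomic_number(sym))
        except ValueError as exc:
            raise CmlParseError(str(exc)) from None
        try:
            coords.extend(float(atom.get(a, "0")) for a in ("x3", "y3", "z3"))
        except ValueError:
            raise CmlParseError(f"bad coordinate on atom {atom.get('id')!r}")
        aid = atom.get("id")
        if aid:
            id_to_index[aid] = len(numbers) - 1

    bonds: list[Bond] = []
    for bond in findall(mol_el, "bond"):
        refs = (bond.get("atomRefs2") or "").split()
        if len(refs) != 2:
            raise CmlParseError(f"bad atomRefs2: {bond.get('atomRefs2')!r}")
        try:
            a, b = (id_to_index[r] for r in refs)
        except KeyError as exc:
            raise CmlParseError(f"atomRefs2 names unknown atom id {exc.args[0]!r}") from None
        bonds.append(Bond(a, b, int(bond.get("order", "1"))))

    return Molecule(
        atomic_numbers=numbers,
        coords_3d=coords,
        bonds=bonds,
        name=mol_el.get("title"),
    )


def write_cml(mol: Molecule) -> str:
    mol_el = etree.Element("molecule")
    if mol.name:
        mol_el.set("title", mol.name)
    atom_array = etree.SubElement(mol_el, "atomArray")
    for i, z in enumerate(mol.atomic_numbers):
        x, y, zc = mol.atom_position(i)
        etree.SubElement(
            atom_array,
            "atom",
            id=f"a{i + 1}",
            elementType=elements.symbol(z),
            x3=repr(x),
            y3=repr(y),
            z3=repr(zc),
        )
    if mol.bonds:
        bond_array = etree.SubElement(mol_el, "bondArray")
        for b in mol.bonds:
            etree.SubElement(
                bond_array,
                "bond",
                atomRefs2=f"a{b.a + 1} a{b.b + 1}",
                order=str(b.order),
            )
    return etree.tostring(mol_el, pretty_print=True, encoding="unicode")
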