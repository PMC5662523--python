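"""Core in-memory model: molecules, bonds, calculations, and derived properties.

Every codec (Chemical JSON, ChemLog JSON, XYZ, CML) and the data service map
into these types. Coordinates are always stored in angstrom; codecs convert
on ingest. Atom and bond indices are 0-based.
"""

from __future__ import annotations

import hashlib
from collections import Counter
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

from . import elements

#: Closed vocabulary of physical units used by :class:`Quantity`.
UNIT_VOCABULARY = frozenset(
    {"hartree", "eV", "cm-1", "angstrom", "bohr", "amu", "debye", "dimensionless"}
)

#: CODATA 2018 bohr radius in angstrom.
BOHR_TO_ANGSTROM = 0.529177210903


class ValidationError(ValueError):
    """An object violates a structural invariant of the model or a format."""


@dataclass(frozen=True)
class Bond:
    """A bond between two atoms, identified by 0-based indices.

    ``order`` is a positive integer (1 single, 2 double, ...).
    """

    a: int
    b: int
    order: int = 1

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValidationError(f"bond endpoints must be distinct, got {self.a}")
        if self.order < 1:
            raise ValidationError(f"bond order must be >= 1, got {self.order}")

    def canonical(self) -> "Bond":
        """Endpoints sorted ascending; used for order-independent comparison."""
        if self.a <= self.b:
            return self
        return Bond(self.b, self.a, self.order)


@dataclass
class Molecule:
    """A molecular structure.

    ``coords_3d`` is a flat list of length 3 * atom_count in angstrom; atom
    ``i`` occupies slots ``3i, 3i+1, 3i+2``. ``inchi``/``inchikey`` are
    accepted as supplied metadata and never computed internally.
    """

    atomic_numbers: list[int]
    coords_3d: list[float]
    bonds: list[Bond] = field(default_factory=list)
    name: str | None = None
    inchi: str | None = None
    inchikey: str | None = None
    id: str | None = None
    extras: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        n = len(self.atomic_numbers)
        if len(self.coords_3d) != 3 * n:
            raise ValidationError(
                f"coords_3d length {len(self.coords_3d)} != 3 x {n} atoms"
            )
        for z in self.atomic_numbers:
            if not 1 <= z <= elements.MAX_ATOMIC_NUMBER:
                raise ValidationError(f"atomic number out of range [1, 118]: {z}")
        for bond in self.bonds:
            for idx in (bond.a, bond.b):
                if not 0 <= idx < n:
                    raise ValidationError(
                        f"bond index {idx} out of range [0, {n})"
                    )

    # -- derived properties -------------------------------------------------

    @property
    def atom_count(self) -> int:
        return len(self.atomic_numbers)

    def atom_position(self, i: int) -> tuple[float, float, float]:
        """Cartesian position of atom ``i`` in angstrom.

        The flat coordinate array stores each atom's position at offset 3i.
        """
        if not 0 <= i < self.atom_count:
            raise IndexError(f"atom index {i} out of range [0, {self.atom_count})")
        return (self.coords_3d[3 * i], self.coords_3d[3 * i + 1], self.coords_3d[3 * i + 2])

    def molecular_mass(self) -> float:
        """Sum of conventional standard atomic weights, in amu."""
        return sum(elements.atomic_weight(z) for z in self.atomic_numbers)

    def hill_formula(self) -> str:
        """Hill-order formula: C, then H, then other elements alphabetically.

        With no carbon present all symbols are alphabetical. Counts of 1 are
        omitted. Empty molecule gives the empty string.
        """
        counts = Counter(elements.symbol(z) for z in self.atomic_numbers)
        if not counts:
            return ""
        ordered: list[str] = []
        if "C" in counts:
            ordered.append("C")
            if "H" in counts:
                ordered.append("H")
            ordered.extend(sorted(s for s in counts if s not in ("C", "H")))
        else:
            ordered.extend(sorted(counts))
        return "".join(
            s if counts[s] == 1 else f"{s}{counts[s]}" for s in ordered
        )

    def heavy_atom_count(self) -> int:
        """Number of non-hydrogen atoms."""
        return sum(1 for z in self.atomic_numbers if z != 1)

    def structure_key(self) -> str:
        """Deterministic digest of the molecular graph.

        Serves as a deduplication key when no InChIKey is supplied: equal for
        equal graphs regardless of atom input order. The graph (atoms colored
        by atomic number, edges by bond order) is canonicalized with a
        Weisfeiler-Lehman hash, combined with the element multiset so
        bondless structures with different compositions stay distinct.
        Geometry is not hashed: the key identifies the molecular graph,
        mirroring the role of an InChIKey, not a conformer.
        """
        import networkx as nx

        g = nx.Graph()
        for i, z in enumerate(self.atomic_numbers):
            g.add_node(i, z=str(z))
        for b in self.bonds:
            g.add_edge(b.a, b.b, order=str(b.order))
        wl = nx.weisfeiler_lehman_graph_hash(g, node_attr="z", edge_attr="order")
        composition = ",".join(str(z) for z in sorted(self.atomic_numbers))
        return hashlib.sha1(f"{composition}|{wl}".encode()).hexdigest()


@dataclass
class VibrationalData:
    """Normal modes: frequencies (cm-1), optional IR intensities (km/mol),
    and per-mode flat 3N displacement vectors (unitless directions)."""

    frequencies: list[float]
    modes: list[list[float]]
    intensities: list[float] | None = None

    def __post_init__(self) -> None:
        if len(self.modes) != len(self.frequencies):
            raise ValidationError(
                f"{len(self.modes)} mode vectors for {len(self.frequencies)} frequencies"
            )
        if self.intensities is not None and len(self.intensities) != len(self.frequencies):
            raise ValidationError("intensities length must match frequencies")
        lengths = {len(m) for m in self.modes}
        if len(lengths) > 1 or (lengths and next(iter(lengths)) % 3 != 0):
            raise ValidationError("each mode vector must have length 3 x atom_count")

    def validate_for(self, mol: Molecule) -> None:
        for m in self.modes:
            if len(m) != 3 * mol.atom_count:
                raise ValidationError(
                    f"mode vector length {len(m)} != 3 x {mol.atom_count} atoms"
                )


@dataclass
class VolumetricData:
    """A primitive container for gridded volumetric data (e.g. an orbital).

    ``values`` is flat with z fastest-varying (Gaussian cube convention);
    origin and spacing in angstrom.
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    dims: tuple[int, int, int]
    values: list[float]
    label: str = ""

    def __post_init__(self) -> None:
        nx, ny, nz = self.dims
        if min(self.dims) < 1:
            raise ValidationError(f"dims must be positive, got {self.dims}")
        if len(self.values) != nx * ny * nz:
            raise ValidationError(
                f"values length {len(self.values)} != {nx}x{ny}x{nz}"
            )


@dataclass(frozen=True)
class Quantity:
    """A physical value with an explicit unit from a closed vocabulary."""

    value: float
    units: str

    def __post_init__(self) -> None:
        if self.units not in UNIT_VOCABULARY:
            raise ValidationError(
                f"unknown units {self.units!r}; expected one of {sorted(UNIT_VOCABULARY)}"
            )


@dataclass
class Calculation:
    """A quantum-chemistry calculation linked to a parent molecule.

    Carries provenance (code, theory, calculation types), a mapping of named
    properties as unit-annotated quantities, and optional vibrational and
    volumetric results.
    """

    id: str
    molecule_id: str
    code: str = ""
    theory: str = ""
    calculation_types: list[str] = field(default_factory=list)
    file_id: str | None = None
    properties: dict[str, Quantity] = field(default_factory=dict)
    vibrations: VibrationalData | None = None
    volumes: list[VolumetricData] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.molecule_id:
            raise ValidationError("calculation requires a non-empty molecule_id")


def molecules_equal(
    a: Molecule, b: Molecule, coord_tol: float = 0.0, compare_bonds: bool = True
) -> bool:
    """Field-wise equality on elements, coordinates, and (optionally) bonds."""
    if a.atomic_numbers != b.atomic_numbers:
        return False
    if len(a.coords_3d) != len(b.coords_3d):
        return False
    if coord_tol == 0.0:
        if a.coords_3d != b.coords_3d:
            return False
    elif any(abs(x - y) > coord_tol for x, y in zip(a.coords_3d, b.coords_3d)):
        return False
    if compare_bonds:
        if sorted((bd.canonical().a, bd.canonical().b, bd.order) for bd in a.bonds) != sorted(
            (bd.canonical().a, bd.canonical().b, bd.order) for bd in b.bonds
        ):
            return False
    return True
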