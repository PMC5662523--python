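"""Deterministic fixtures: the canonical water molecule, seeded random
molecules/logs/queries. Every suite runs from these with no external data.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from . import query as query_mod
from .model import Bond, Molecule, Quantity, VibrationalData
from .nwchem import LogFixtureSpec, LogTask

_ORGANIC_POOL = [1, 6, 7, 8, 9, 15, 16, 17, 35]


def canonical_water() -> Molecule:
    """The package's running example: a water molecule.

    O at the origin, H atoms at (+-0.757, 0.586, 0) angstrom — a standard
    experimental-style geometry (O-H 0.9573 angstrom, H-O-H 104.5 degrees).
    """
    return Molecule(
        atomic_numbers=[8, 1, 1],
        coords_3d=[0.0, 0.0, 0.0, 0.757, 0.586, 0.0, -0.757, 0.586, 0.0],
        bonds=[Bond(0, 1, 1), Bond(0, 2, 1)],
        name="water",
    )


@dataclass
class RandomMoleculeSpec:
    """Recipe for seeded random molecule generation."""

    seed: int
    n_atoms: tuple[int, int] = (1, 12)
    element_pool: list[int] = field(default_factory=lambda: list(_ORGANIC_POOL))
    bond_density: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 <= self.bond_density <= 1.0:
            raise ValueError("bond density must be in [0, 1]")


def random_molecule(spec: RandomMoleculeSpec) -> Molecule:
    """Deterministic random molecule satisfying every model invariant.

    Bonds are drawn on a spanning tree plus extra edges (density-controlled)
    so bond indices always form a connected, plausible graph; no geometric
    bond perception is attempted.
    """
    rng = random.Random(spec.seed)
    n = rng.randint(*spec.n_atoms)
    numbers = [rng.choice(spec.element_pool) for _ in range(n)]
    coords = [round(rng.uniform(-8.0, 8.0), 6) for _ in range(3 * n)]
    bonds: list[Bond] = []
    if spec.bond_density > 0 and n > 1:
        # spanning tree keeps the graph connected
        order = list(range(n))
        rng.shuffle(order)
        seen = {order[0]}
        for idx in order[1:]:
            partner = rng.choice(sorted(seen))
            bonds.append(Bond(min(idx, partner), max(idx, partner), rng.choice([1, 1, 1, 2])))
            seen.add(idx)
        existing = {(b.a, b.b) for b in bonds}
        extras = int(spec.bond_density * n)
        for _ in range(extras):
            a, b = rng.randrange(n), rng.randrange(n)
            if a == b:
                continue
            key = (min(a, b), max(a, b))
            if key in existing:
                continue
            existing.add(key)
            bonds.append(Bond(*key, rng.choice([1, 2])))
    name = f"mol-{spec.seed}"
    return Molecule(atomic_numbers=numbers, coords_3d=coords, bonds=bonds, name=name)


def random_vibrations(mol: Molecule, seed: int, n_modes: int | None = None) -> VibrationalData:
    """Seeded vibrational data with plausible magnitudes for a molecule."""
    rng = random.Random(seed)
    n = mol.atom_count
    if n_modes is None:
        n_modes = max(3 * n - 6, 1)
    freqs = sorted(round(rng.uniform(100.0, 3800.0), 2) for _ in range(n_modes))
    intensities = [round(rng.uniform(0.0, 150.0), 4) for _ in range(n_modes)]
    modes = [
        [round(rng.uniform(-1.0, 1.0), 6) for _ in range(3 * n)] for _ in range(n_modes)
    ]
    return VibrationalData(frequencies=freqs, modes=modes, intensities=intensities)


def random_log_spec(seed: int) -> LogFixtureSpec:
    """Seeded synthetic log recipe: 1-3 chained tasks over one molecule."""
    rng = random.Random(seed)
    mol = random_molecule(RandomMoleculeSpec(seed=rng.randrange(2**31), n_atoms=(2, 8)))
    n_tasks = rng.randint(1, 3)
    tasks: list[LogTask] = []
    basis = rng.choice(["sto-3g", "6-31g*", "cc-pvdz", "def2-svp"])
    for _ in range(n_tasks):
        kind = rng.choice(["scf", "dft", "frequency"])
        energy = Quantity(round(rng.uniform(-500.0, -1.0), 8), "hartree")
        vib = None
        if kind == "frequency":
            vib = random_vibrations(mol, seed=rng.randrange(2**31))
        tasks.append(LogTask(kind=kind, basis=basis, energy=energy, vibrations=vib))
    units = rng.choice(["angstrom", "bohr"])
    return LogFixtureSpec(
        molecule=mol, tasks=tasks, geometry_units=units, seed=rng.randrange(2**31)
    )


def random_query(seed: int) -> query_mod.Node:
    """Seeded random query AST over the searchable fields."""
    rng = random.Random(seed)

    def comparison() -> query_mod.Node:
        if rng.random() < 0.7:
            field_name = rng.choice(["mass", "atomCount", "heavyAtomCount"])
            op = rng.choice(query_mod.NUMERIC_OPS)
            if field_name == "mass":
                lit: float = round(rng.uniform(1.0, 400.0), 3)
            else:
                lit = float(rng.randint(0, 12))
            return query_mod.Comparison(field_name, op, lit)
        field_name = rng.choice(["name", "formula"])
        op = rng.choice(query_mod.STRING_OPS)
        lit_s = rng.choice(["mol", "C", "H2", "O", "water", "mol-1", "Cl"])
        return query_mod.Comparison(field_name, op, lit_s)

    def node(depth: int) -> query_mod.Node:
        if depth <= 0 or rng.random() < 0.4:
            return comparison()
        cls = rng.choice([query_mod.And, query_mod.Or])
        return cls(node(depth - 1), node(depth - 1))

    return node(rng.randint(1, 3))
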