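import random

import pytest
from hypothesis import settings

from chemstore.fixtures import RandomMoleculeSpec, canonical_water, random_molecule
from chemstore.model import Bond, Molecule

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def water() -> Molecule:
    return canonical_water()


@pytest.fixture
def methane() -> Molecule:
    return Molecule(
        atomic_numbers=[6, 1, 1, 1, 1],
        coords_3d=[
            0.0, 0.0, 0.0,
            0.629, 0.629, 0.629,
            -0.629, -0.629, 0.629,
            -0.629, 0.629, -0.629,
            0.629, -0.629, -0.629,
        ],
        bonds=[Bond(0, i) for i in range(1, 5)],
        name="methane",
    )


@pytest.fixture
def random_molecules() -> list[Molecule]:
    return [random_molecule(RandomMoleculeSpec(seed=s)) for s in range(100)]


def permute_atoms(mol: Molecule, seed: int) -> Molecule:
    """Same molecule with atoms listed in a different (seeded) order."""
    rng = random.Random(seed)
    n = mol.atom_count
    perm = list(range(n))
    rng.shuffle(perm)  # perm[new] = old
    inverse = {old: new for new, old in enumerate(perm)}
    coords: list[float] = []
    for old in perm:
        coords.extend(mol.coords_3d[3 * old : 3 * old + 3])
    return Molecule(
        atomic_numbers=[mol.atomic_numbers[old] for old in perm],
        coords_3d=coords,
        bonds=[Bond(inverse[b.a], inverse[b.b], b.order) for b in mol.bonds],
        name=mol.name,
    )
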