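"""Optional InChI/InChIKey provider hook.

The core model treats InChI and InChIKey as supplied metadata and never
computes them itself. A chemistry toolkit can be attached here to compute
real identifiers; :func:`rdkit_provider` builds one from RDKit when that
package is installed.
"""

from __future__ import annotations

from typing import Callable, Optional

from . import elements
from .model import Molecule

#: A provider maps a molecule to (inchi, inchikey), or None if it cannot.
InchiProvider = Callable[[Molecule], Optional[tuple[str, str]]]

_provider: InchiProvider | None = None


def set_inchi_provider(provider: InchiProvider | None) -> None:
    global _provider
    _provider = provider


def get_inchi_provider() -> InchiProvider | None:
    return _provider


def annotate(mol: Molecule) -> Molecule:
    """Fill in inchi/inchikey from the registered provider, if any."""
    if _provider is None or (mol.inchi and mol.inchikey):
        return mol
    result = _provider(mol)
    if result is not None:
        mol.inchi, mol.inchikey = result
    return mol


def rdkit_provider() -> InchiProvider:
    """Build a provider backed by RDKit (raises ImportError if absent)."""
    from rdkit import Chem

    def provide(mol: Molecule) -> tuple[str, str] | None:
        rw = Chem.RWMol()
        for z in mol.atomic_numbers:
            rw.AddAtom(Chem.Atom(elements.symbol(z)))
        for b in mol.bonds:
            rw.AddBond(b.a, b.b, Chem.BondType.values.get(b.order, Chem.BondType.SINGLE))
        try:
            m = rw.GetMol()
            Chem.SanitizeMol(m)
            inchi = Chem.MolToInchi(m)
            if not inchi:
                return None
            return inchi, Chem.InchiToInchiKey(inchi)
        except Exception:
            return None

    return provide
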