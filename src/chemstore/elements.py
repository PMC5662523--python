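"""Periodic-table data: symbols and conventional atomic weights.

Weights are the IUPAC 2021 conventional (abridged) standard atomic weights,
rounded to three decimal places where a conventional value is published; for
elements with no stable isotope the mass number of the longest-lived isotope
is used. Embedding a static table keeps masses reproducible and the package
dependency-free.
"""

from __future__ import annotations

SYMBOLS: tuple[str, ...] = (
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar", "K", "Ca",
    "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Ga", "Ge", "As", "Se", "Br", "Kr", "Rb", "Sr", "Y", "Zr",
    "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd", "In", "Sn",
    "Sb", "Te", "I", "Xe", "Cs", "Ba", "La", "Ce", "Pr", "Nd",
    "Pm", "Sm", "Eu", "Gd", "Tb", "Dy", "Ho", "Er", "Tm", "Yb",
    "Lu", "Hf", "Ta", "W", "Re", "Os", "Ir", "Pt", "Au", "Hg",
    "Tl", "Pb", "Bi", "Po", "At", "Rn", "Fr", "Ra", "Ac", "Th",
    "Pa", "U", "Np", "Pu", "Am", "Cm", "Bk", "Cf", "Es", "Fm",
    "Md", "No", "Lr", "Rf", "Db", "Sg", "Bh", "Hs", "Mt", "Ds",
    "Rg", "Cn", "Nh", "Fl", "Mc", "Lv", "Ts", "Og",
)

ATOMIC_WEIGHTS: tuple[float, ...] = (
    1.008, 4.003, 6.94, 9.012, 10.81, 12.011, 14.007, 15.999, 18.998, 20.180,
    22.990, 24.305, 26.982, 28.085, 30.974, 32.06, 35.45, 39.95, 39.098, 40.078,
    44.956, 47.867, 50.942, 51.996, 54.938, 55.845, 58.933, 58.693, 63.546, 65.38,
    69.723, 72.630, 74.922, 78.971, 79.904, 83.798, 85.468, 87.62, 88.906, 91.224,
    92.906, 95.95, 97.0, 101.07, 102.906, 106.42, 107.868, 112.414, 114.818, 118.710,
    121.760, 127.60, 126.904, 131.293, 132.905, 137.327, 138.905, 140.116, 140.908, 144.242,
    145.0, 150.36, 151.964, 157.25, 158.925, 162.500, 164.930, 167.259, 168.934, 173.045,
    174.967, 178.486, 180.948, 183.84, 186.207, 190.23, 192.217, 195.084, 196.967, 200.592,
    204.38, 207.2, 208.980, 209.0, 210.0, 222.0, 223.0, 226.0, 227.0, 232.038,
    231.036, 238.029, 237.0, 244.0, 243.0, 247.0, 247.0, 251.0, 252.0, 257.0,
    258.0, 259.0, 262.0, 267.0, 270.0, 269.0, 270.0, 277.0, 278.0, 281.0,
    282.0, 285.0, 286.0, 289.0, 290.0, 293.0, 294.0, 294.0,
)

MAX_ATOMIC_NUMBER = len(SYMBOLS)  # 118

_SYMBOL_TO_NUMBER = {s: i + 1 for i, s in enumerate(SYMBOLS)}


def symbol(atomic_number: int) -> str:
    """Element symbol for an atomic number in [1, 118]."""
    if not 1 <= atomic_number <= MAX_ATOMIC_NUMBER:
        raise ValueError(f"atomic number out of range [1, 118]: {atomic_number}")
    return SYMBOLS[atomic_number - 1]


def atomic_number(sym: str) -> int:
    """Atomic number for an element symbol (case-normalized, e.g. 'cl' -> 17)."""
    key = sym.strip().capitalize()
    try:
        return _SYMBOL_TO_NUMBER[key]
    except KeyError:
        raise ValueError(f"unknown element symbol: {sym!r}") from None


def atomic_weight(atomic_number: int) -> float:
    """Conventional standard atomic weight in amu."""
    if not 1 <= atomic_number <= MAX_ATOMIC_NUMBER:
        raise ValueError(f"atomic number out of range [1, 118]: {atomic_number}")
    return ATOMIC_WEIGHTS[atomic_number - 1]
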