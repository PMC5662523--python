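"""Format conversion: dispatcher, ChemLog→Chemical JSON mapping, vibrational
animation frames, and Gaussian-cube serialization of volumetric data.

Supported formats: ``xyz``, ``cml``, ``cjson`` (read/write) and ``chemlog``
(read-only conversion source; calculation 0 is used). XYZ carries no bonds,
so any conversion path through it is lossy — the dispatcher reports this.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any

from . import chemlog as chemlog_mod
from . import cjson as cjson_mod
from . import cml as cml_mod
from . import xyz as xyz_mod
from .model import BOHR_TO_ANGSTROM, Molecule, VibrationalData, VolumetricData

READABLE_FORMATS = ("xyz", "cml", "cjson", "chemlog")
WRITABLE_FORMATS = ("xyz", "cml", "cjson")

#: Formats that cannot carry bond information.
LOSSY_FORMATS = frozenset({"xyz"})


class UnsupportedConversionError(ValueError):
    def __init__(self, in_format: str, out_format: str):
        pairs = ", ".join(
            f"{f}->{g}" for f in READABLE_FORMATS for g in WRITABLE_FORMATS
        )
        super().__init__(
            f"unsupported conversion {in_format!r} -> {out_format!r}; "
            f"supported pairs: {pairs}"
        )


def normalize_format(name: str) -> str:
    """Case-insensitive format name from the closed set."""
    norm = name.strip().lower()
    if norm not in READABLE_FORMATS:
        raise ValueError(
            f"unknown format {name!r}; expected one of {', '.join(READABLE_FORMATS)}"
        )
    return norm


@dataclass
class ConversionResult:
    """Converted text plus a lossiness flag for bond-dropping paths."""

    text: str
    lossy: bool
    warnings: list[str]


def read_molecule(text: str, in_format: str) -> Molecule:
    fmt = normalize_format(in_format)
    if fmt == "xyz":
        return xyz_mod.read_xyz(text)
    if fmt == "cml":
        return cml_mod.read_cml(text)
    if fmt == "cjson":
        mol, _, _ = cjson_mod.parse_cjson(text)
        return mol
    doc = chemlog_mod.parse_chemlog(text)
    return chemlog_mod.extract_molecule(doc, 0)


def write_molecule(mol: Molecule, out_format: str) -> str:
    fmt = normalize_format(out_format)
    if fmt == "xyz":
        return xyz_mod.write_xyz(mol)
    if fmt == "cml":
        return cml_mod.write_cml(mol)
    if fmt == "cjson":
        return cjson_mod.write_cjson(mol)
    raise UnsupportedConversionError("molecule", out_format)


def convert(text: str, in_format: str, out_format: str) -> ConversionResult:
    """Convert between molecular file formats through the core model."""
    fmt_in = normalize_format(in_format)
    fmt_out = normalize_format(out_format)
    if fmt_out not in WRITABLE_FORMATS:
        raise UnsupportedConversionError(fmt_in, fmt_out)
    mol = read_molecule(text, fmt_in)
    warnings = []
    lossy = bool(mol.bonds) and (fmt_out in LOSSY_FORMATS or fmt_in in LOSSY_FORMATS)
    if fmt_out in LOSSY_FORMATS and mol.bonds:
        warnings.append(f"bond information dropped: {fmt_out} carries no bonds")
    return ConversionResult(
        text=write_molecule(mol, fmt_out), lossy=lossy, warnings=warnings
    )


def chemlog_to_cjson(
    doc: chemlog_mod.ChemLogDocument, calc_index: int
) -> dict[str, Any]:
    """Map one ChemLog calculation into a Chemical JSON document dict.

    Carries the molecule arrays, vibrational results when present, and
    provenance (code, theory) as metadata.
    """
    mol = chemlog_mod.extract_molecule(doc, calc_index)
    calc = doc.calculations[calc_index]
    vib = vibrations_from_results(calc.results, mol.atom_count)
    cj = cjson_mod.build_cjson(mol, vib=vib)
    provenance: dict[str, Any] = {}
    code = doc.simulation.get("code")
    if code:
        provenance["code"] = code
    if calc.theory:
        provenance["theory"] = calc.theory
    if provenance:
        cj["provenance"] = provenance
    return cj


def vibrations_from_results(
    results: dict[str, Any], atom_count: int
) -> VibrationalData | None:
    """Extract vibrational arrays from a ChemLog calculationResults block."""
    freqs = results.get("vibrationalFrequencies")
    if not freqs:
        return None
    modes = results.get("vibrationalModes") or []
    intens = results.get("vibrationalIntensities")
    vib = VibrationalData(
        frequencies=[float(f) for f in freqs.get("value", [])],
        modes=[[float(x) for x in m] for m in modes],
        intensities=(
            [float(x) for x in intens.get("value", [])] if intens else None
        ),
    )
    return vib


def vibration_frames(
    mol: Molecule,
    vib: VibrationalData,
    mode_index: int,
    amplitude: float = 0.5,
    n_frames: int = 20,
) -> list[list[float]]:
    """Coordinate frames for a looping animation of one normal mode.

    Frame ``k`` displaces the equilibrium geometry by
    ``amplitude * sin(2*pi*k / n_frames)`` along the mode's displacement
    vector (max-norm normalized to 1 before scaling, so ``amplitude`` is the
    peak per-coordinate excursion in angstrom). Frame 0 is the equilibrium
    geometry and the sequence loops.
    """
    if not 0 <= mode_index < len(vib.frequencies):
        raise IndexError(
            f"mode index {mode_index} out of range [0, {len(vib.frequencies)})"
        )
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    vib.validate_for(mol)
    mode = vib.modes[mode_index]
    peak = max((abs(x) for x in mode), default=0.0)
    direction = [x / peak for x in mode] if peak > 0 else [0.0] * len(mode)
    frames = []
    for k in range(n_frames):
        factor = amplitude * math.sin(2.0 * math.pi * k / n_frames)
        frames.append([r + factor * d for r, d in zip(mol.coords_3d, direction)])
    return frames


def write_cube(mol: Molecule, vol: VolumetricData) -> str:
    """Serialize volumetric data in the Gaussian cube text layout.

    Cube files use atomic units; coordinates and grid vectors are converted
    from angstrom to bohr. Values are written six per line, z fastest.
    """
    to_bohr = 1.0 / BOHR_TO_ANGSTROM
    nx, ny, nz = vol.dims
    lines = [
        vol.label or "cube",
        "generated by chemstore",
        _cube_row(mol.atom_count, (c * to_bohr for c in vol.origin)),
        _cube_row(nx, (vol.spacing[0] * to_bohr, 0.0, 0.0)),
        _cube_row(ny, (0.0, vol.spacing[1] * to_bohr, 0.0)),
        _cube_row(nz, (0.0, 0.0, vol.spacing[2] * to_bohr)),
    ]
    for i, z in enumerate(mol.atomic_numbers):
        x, y, zc = mol.atom_position(i)
        lines.append(
            f"{z:5d}{float(z):12.6f}{x * to_bohr:12.6f}{y * to_bohr:12.6f}{zc * to_bohr:12.6f}"
        )
    for start in range(0, len(vol.values), 6):
        lines.append(
            "".join(f"{v:13.5E}" for v in vol.values[start : start + 6])
        )
    return "\n".join(lines) + "\n"


def _cube_row(count: int, vec: Any) -> str:
    x, y, z = vec
    return f"{count:5d}{x:12.6f}{y:12.6f}{z:12.6f}"
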