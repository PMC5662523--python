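"""NWChem-style log ingestion: plain-text quantum-chemistry output → ChemLog.

Computational chemistry codes chain several tasks in one run and append each
task's output to a single log. The parser walks the log once, collecting
geometry blocks ("Output coordinates ..."), module sections, final-energy
lines and frequency tables, and emits one ChemLog calculation per task in
order. A geometry repeated across tasks is emitted once with an id-tag and
referenced thereafter.

The parser is table-driven: energy labels and module headers live in module
constants so other codes' labels can be registered. It firmly targets
NWChem-style output here.

:func:`generate_log` writes synthetic logs from a :class:`LogFixtureSpec`,
making the pipeline testable with no external data; a seed jitters only
whitespace, never token content.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field
from typing import Any

from . import elements
from .chemlog import ChemLogDocument, build_document
from .model import Molecule, Quantity, VibrationalData


class IngestError(ValueError):
    pass


#: Energy-line labels recognized, label -> theory tag. Extensible.
ENERGY_LABELS: dict[str, str] = {
    "Total SCF energy": "scf",
    "Total DFT energy": "dft",
}

#: Module headers that open a new task section, header -> (theory, task type).
MODULE_HEADERS: dict[str, tuple[str, str]] = {
    "NWChem SCF Module": ("scf", "energy"),
    "NWChem DFT Module": ("dft", "energy"),
    "NWChem Nuclear Hessian and Frequency Analysis": ("", "frequency"),
}

_GEOMETRY_RE = re.compile(r"Output coordinates in (angstroms|a\.u\.)")
_ATOM_ROW_RE = re.compile(
    r"^\s*(\d+)\s+(\S+)\s+(-?[\d.]+)\s+(-?[\d.]+)\s+(-?[\d.]+)\s+(-?[\d.]+)\s*$"
)


@dataclass
class LogTask:
    """One task in a synthetic log run."""

    kind: str  # scf | dft | frequency
    theory: str = ""
    basis: str = "sto-3g"
    energy: Quantity | None = None
    vibrations: VibrationalData | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("scf", "dft", "frequency"):
            raise ValueError(f"unknown task kind {self.kind!r}")
        if not self.theory:
            self.theory = self.kind if self.kind != "frequency" else "scf"
        if self.kind == "frequency" and self.vibrations is None:
            raise ValueError("frequency task requires vibrational data")


@dataclass
class LogFixtureSpec:
    """Recipe for a synthetic NWChem-style log."""

    molecule: Molecule
    tasks: list[LogTask]
    geometry_units: str = "angstrom"  # angstrom | bohr
    seed: int = 0
    code_version: str = "7.0.2"

    def __post_init__(self) -> None:
        if not self.tasks:
            raise ValueError("at least one task required")
        if self.geometry_units not in ("angstrom", "bohr"):
            raise ValueError(f"geometry units must be angstrom or bohr")
        for t in self.tasks:
            if t.vibrations is not None:
                t.vibrations.validate_for(self.molecule)


# -- generation -----------------------------------------------------------


def generate_log(spec: LogFixtureSpec) -> str:
    """Emit an NWChem-style plain-text log for the fixture spec.

    The seed drives cosmetic whitespace jitter only; the token stream is
    seed-independent.
    """
    rng = random.Random(spec.seed)

    def pad(lo: int = 1, hi: int = 4) -> str:
        return " " * rng.randint(lo, hi)

    lines: list[str] = []
    lines.append("")
    lines.append(f"{pad(8, 12)}Northwest Computational Chemistry Package (NWChem) {spec.code_version}")
    lines.append(f"{pad(8, 12)}{'-' * 52}")
    lines.append("")

    for task in spec.tasks:
        lines.extend(_geometry_block(spec, rng))
        header = {
            "scf": "NWChem SCF Module",
            "dft": "NWChem DFT Module",
            "frequency": "NWChem Nuclear Hessian and Frequency Analysis",
        }[task.kind]
        lines.append(f"{pad(10, 16)}{header}")
        lines.append(f"{pad(10, 16)}{'-' * len(header)}")
        lines.append("")
        lines.append(f"{pad(1, 3)}basis name:{pad()}{task.basis}")
        lines.append("")
        if task.energy is not None:
            label = "Total DFT energy" if task.theory == "dft" else "Total SCF energy"
            lines.append(f"{pad(1, 8)}{label} ={pad(4, 10)}{task.energy.value:.8f}")
            lines.append("")
        if task.vibrations is not None:
            lines.extend(_frequency_block(task.vibrations, rng))
    lines.append("")
    return "\n".join(lines) + "\n"


def _geometry_block(spec: LogFixtureSpec, rng: random.Random) -> list[str]:
    from .model import BOHR_TO_ANGSTROM

    mol = spec.molecule
    unit_word = "angstroms" if spec.geometry_units == "angstrom" else "a.u."
    scale = 1.0 if spec.geometry_units == "angstrom" else 1.0 / BOHR_TO_ANGSTROM
    lines = [
        f" Output coordinates in {unit_word} (scale by 1.0 to keep units)",
        "",
        "  No.       Tag          Charge          X              Y              Z",
        " ---- ---------------- ---------- -------------- -------------- --------------",
    ]
    for i, z in enumerate(mol.atomic_numbers):
        x, y, zc = mol.atom_position(i)
        pad = " " * rng.randint(0, 2)
        lines.append(
            f"{i + 1:5d} {elements.symbol(z):<16s}{pad} {float(z):9.4f}"
            f" {x * scale:14.8f} {y * scale:14.8f} {zc * scale:14.8f}"
        )
    lines.append("")
    return lines


def _frequency_block(vib: VibrationalData, rng: random.Random) -> list[str]:
    n_coords = len(vib.modes[0]) if vib.modes else 0
    lines = [" Normal Mode Eigenvectors in Cartesian Coordinates", ""]
    for start in range(0, len(vib.frequencies), 6):
        stop = min(start + 6, len(vib.frequencies))
        idx = range(start, stop)
        lines.append(
            "           Frequency"
            + "".join(f"{vib.frequencies[m]:12.2f}" for m in idx)
        )
        if vib.intensities is not None:
            lines.append(
                "        IR Intensity"
                + "".join(f"{vib.intensities[m]:12.4f}" for m in idx)
            )
        for c in range(n_coords):
            pad = " " * rng.randint(0, 2)
            lines.append(
                f"{c + 1:8d}{pad}    "
                + "".join(f"{vib.modes[m][c]:12.6f}" for m in idx)
            )
        lines.append("")
    return lines


# -- ingestion ------------------------------------------------------------


def parse_nwchem_log(text: str) -> ChemLogDocument:
    """Parse NWChem-style log text into a ChemLog document.

    One calculation per detected task section, in order. Geometry is stored
    as per-atom objects carrying the units the log declared (no silent
    conversion); energies become hartree quantities; frequencies cm-1.
    """
    lines = text.splitlines()
    version = _find_version(lines)
    geometries = []  # (units, Molecule) in document order
    tasks: list[dict[str, Any]] = []
    current: dict[str, Any] | None = None

    i = 0
    while i < len(lines):
        line = lines[i]
        geo_match = _GEOMETRY_RE.search(line)
        if geo_match:
            units = "angstrom" if geo_match.group(1) == "angstroms" else "bohr"
            mol, i = _parse_geometry(lines, i + 1)
            geometries.append((units, mol))
            continue
        header = _match_module_header(line)
        if header is not None:
            theory, task_type = header
            if not geometries:
                raise IngestError(
                    f"module section at line {i + 1} before any geometry block"
                )
            current = {
                "theory": theory,
                "task": task_type,
                "geometry_index": len(geometries) - 1,
                "basis": "",
                "energy": None,
                "vibrations": None,
            }
            tasks.append(current)
            i += 1
            continue
        m = re.match(r"\s*basis name:\s*(\S+)", line)
        if m and current is not None:
            current["basis"] = m.group(1)
            i += 1
            continue
        energy = _match_energy_line(line, i)
        if energy is not None:
            if current is None:
                raise IngestError(f"energy line outside any task section at line {i + 1}")
            label_theory, value = energy
            current["energy"] = Quantity(value, "hartree")
            if not current["theory"]:
                current["theory"] = label_theory
            i += 1
            continue
        if "Normal Mode Eigenvectors" in line:
            if current is None:
                raise IngestError(f"frequency table outside any task at line {i + 1}")
            current["vibrations"], i = _parse_frequency_table(lines, i + 1)
            continue
        i += 1

    if not geometries:
        raise IngestError("no geometry block found in log")
    if not tasks:
        raise IngestError("no task sections found in log")
    return _assemble_document(version, geometries, tasks)


def _find_version(lines: list[str]) -> str:
    for line in lines:
        m = re.search(r"\(NWChem\)\s+(\S+)", line)
        if m:
            return m.group(1)
    return ""


def _match_module_header(line: str) -> tuple[str, str] | None:
    for header, info in MODULE_HEADERS.items():
        if header in line:
            return info
    return None


def _match_energy_line(line: str, lineno: int) -> tuple[str, float] | None:
    for label, theory in ENERGY_LABELS.items():
        if label in line:
            m = re.search(re.escape(label) + r"\s*=\s*(\S+)", line)
            if not m:
                raise IngestError(f"unparsable energy line at line {lineno + 1}: {line!r}")
            try:
                return theory, float(m.group(1))
            except ValueError:
                raise IngestError(
                    f"unparsable energy value at line {lineno + 1}: {m.group(1)!r}"
                ) from None
    return None


def _parse_geometry(lines: list[str], start: int) -> tuple[Molecule, int]:
    numbers: list[int] = []
    coords: list[float] = []
    i = start
    seen_rows = False
    while i < len(lines):
        row = _ATOM_ROW_RE.match(lines[i])
        if row:
            seen_rows = True
            try:
                numbers.append(elements.atomic_number(row.group(2)))
            except ValueError as exc:
                raise IngestError(f"line {i + 1}: {exc}") from None
            coords.extend(float(row.group(g)) for g in (4, 5, 6))
        elif seen_rows:
            break
        i += 1
    if not numbers:
        raise IngestError(f"geometry block at line {start} contains no atom rows")
    return Molecule(atomic_numbers=numbers, coords_3d=coords), i


def _parse_frequency_table(
    lines: list[str], start: int
) -> tuple[VibrationalData, int]:
    freqs: list[float] = []
    intensities: list[float] = []
    columns: list[list[float]] = []  # current block's mode columns
    modes: list[list[float]] = []
    i = start

    def flush() -> None:
        modes.extend(columns)
        columns.clear()

    while i < len(lines):
        line = lines[i]
        stripped = line.strip()
        if stripped.startswith("Frequency"):
            flush()
            vals = [float(v) for v in stripped.split()[1:]]
            freqs.extend(vals)
            columns.extend([] for _ in vals)
        elif stripped.startswith("IR Intensity"):
            intensities.extend(float(v) for v in stripped.split()[2:])
        elif re.match(r"^\s*\d+\s+-?[\d.]", line):
            vals = stripped.split()[1:]
            for col, v in zip(columns, vals):
                col.append(float(v))
        elif stripped == "":
            pass
        else:
            break
        i += 1
    flush()
    vib = VibrationalData(
        frequencies=freqs,
        modes=modes,
        intensities=intensities if intensities else None,
    )
    return vib, i


def _assemble_document(
    version: str,
    geometries: list[tuple[str, Molecule]],
    tasks: list[dict[str, Any]],
) -> ChemLogDocument:
    # deduplicate geometries by (units, elements, coords); first mention gets
    # the inline block, later tasks reference its id-tag
    geo_to_block: dict[int, Any] = {}
    keys: dict[tuple, dict[str, Any]] = {}
    for gi, (units, mol) in enumerate(geometries):
        key = (units, tuple(mol.atomic_numbers), tuple(mol.coords_3d))
        block = keys.get(key)
        if block is None:
            # values pass through unchanged, carrying the units the log declared
            mol_id = f"Molecule.{len(keys) + 1}"
            atoms = []
            for i, z in enumerate(mol.atomic_numbers):
                atoms.append(
                    {
                        "id": f"Atom.{i + 1}.Mol.{len(keys) + 1}",
                        "element": elements.symbol(z),
                        "coordinates": {
                            "value": list(mol.coords_3d[3 * i : 3 * i + 3]),
                            "units": units,
                        },
                    }
                )
            block = {"id": mol_id, "atoms": atoms}
            keys[key] = block
        geo_to_block[gi] = block

    calculations: list[dict[str, Any]] = []
    for ti, task in enumerate(tasks):
        setup: dict[str, Any] = {
            "id": f"Setup.{ti + 1}",
            "theory": task["theory"],
            "task": task["task"],
        }
        if task["basis"]:
            setup["basisSet"] = {"id": f"BasisSet.{ti + 1}", "name": task["basis"]}
        results: dict[str, Any] = {}
        if task["energy"] is not None:
            results["totalEnergy"] = {
                "value": task["energy"].value,
                "units": task["energy"].units,
            }
        vib = task["vibrations"]
        if vib is not None:
            results["vibrationalFrequencies"] = {
                "value": list(vib.frequencies),
                "units": "cm-1",
            }
            if vib.intensities is not None:
                results["vibrationalIntensities"] = {
                    "value": list(vib.intensities),
                    "units": "km/mol",
                }
            if vib.modes:
                results["vibrationalModes"] = [list(m) for m in vib.modes]
        calculations.append(
            {
                "calculationSetup": setup,
                "molecule": geo_to_block[task["geometry_index"]],
                "calculationResults": results,
            }
        )
    simulation = {"code": "NWChem"}
    if version:
        simulation["version"] = version
    return build_document(simulation, calculations)
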