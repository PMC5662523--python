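"""XYZ/CML codecs, the conversion dispatcher, animation frames, cube output."""

import json
import math

import pytest

from chemstore.chemlog import parse_chemlog, write_chemlog
from chemstore.cjson import parse_cjson
from chemstore.converters import (
    ConversionResult,
    UnsupportedConversionError,
    chemlog_to_cjson,
    convert,
    normalize_format,
    read_molecule,
    vibration_frames,
    write_cube,
    write_molecule,
)
from chemstore.fixtures import random_vibrations
from chemstore.cml import CmlParseError, read_cml, write_cml
from chemstore.model import VolumetricData, molecules_equal
from chemstore.nwchem import LogFixtureSpec, LogTask, generate_log, parse_nwchem_log
from chemstore.model import Quantity
from chemstore.xyz import XyzParseError, read_xyz, write_xyz


class TestXyz:
    def test_water_serialization(self, water):
        text = write_xyz(water)
        lines = text.splitlines()
        assert lines[0] == "3"
        assert lines[1] == "water"
        assert len(lines) == 5
        assert lines[2].split()[0] == "O"

    def test_round_trip(self, random_molecules):
        for mol in random_molecules:
            back = read_xyz(write_xyz(mol))
            assert back.atomic_numbers == mol.atomic_numbers
            assert all(
                abs(a - b) <= 1e-6 for a, b in zip(back.coords_3d, mol.coords_3d)
            )

    def test_count_mismatch(self):
        with pytest.raises(XyzParseError, match="4 atoms"):
            read_xyz("4\nwater\nO 0 0 0\nH 1 0 0\nH 0 1 0\n")

    def test_unknown_element(self):
        with pytest.raises(XyzParseError, match="Xx"):
            read_xyz("1\n\nXx 0 0 0\n")


class TestCml:
    def test_water_document_shape(self, water):
        text = write_cml(water)
        assert text.count("<atom ") == 3
        assert text.count('order="1"') == 2
        assert 'atomRefs2="a1 a2"' in text

    def test_round_trip_preserves_bonds(self, random_molecules):
        for mol in random_molecules:
            back = read_cml(write_cml(mol))
            assert molecules_equal(mol, back, coord_tol=0.0)

    def test_unknown_atom_ref(self):
        text = (
            '<molecule><atomArray>'
            '<atom id="a1" elementType="O" x3="0" y3="0" z3="0"/>'
            '<atom id="a2" elementType="H" x3="1" y3="0" z3="0"/>'
            '<atom id="a3" elementType="H" x3="0" y3="1" z3="0"/>'
            '</atomArray><bondArray><bond atomRefs2="a1 a9" order="1"/>'
            "</bondArray></molecule>"
        )
        with pytest.raises(CmlParseError, match="a9"):
            read_cml(text)

    def test_malformed_xml(self):
        with pytest.raises(CmlParseError, match="XML"):
            read_cml("<molecule><atomArray>")


class TestConvertDispatcher:
    def test_xyz_to_cjson_mass_recomputable(self, water):
        result = convert(write_xyz(water), "xyz", "cjson")
        mol, _, _ = parse_cjson(result.text)
        assert mol.atom_count == 3
        assert mol.molecular_mass() == pytest.approx(18.015)

    def test_identity_conversion(self, water):
        text = write_molecule(water, "cjson")
        result = convert(text, "cjson", "cjson")
        assert molecules_equal(*[parse_cjson(t)[0] for t in (text, result.text)])

    def test_chemlog_not_a_target(self, water):
        with pytest.raises(UnsupportedConversionError, match="supported pairs"):
            convert(write_xyz(water), "xyz", "chemlog")

    def test_format_names_case_insensitive(self):
        assert normalize_format(" CJSON ") == "cjson"
        with pytest.raises(ValueError, match="unknown format"):
            normalize_format("sdf")

    @pytest.mark.parametrize("fmt_in", ["xyz", "cml", "cjson"])
    @pytest.mark.parametrize("fmt_out", ["xyz", "cml", "cjson"])
    def test_double_conversion_lattice(self, fmt_in, fmt_out, random_molecules):
        for mol in random_molecules[:30]:
            start = write_molecule(mol, fmt_in)
            there = convert(start, fmt_in, fmt_out)
            back = convert(there.text, fmt_out, fmt_in)
            final = read_molecule(back.text, fmt_in)
            assert final.atomic_numbers == mol.atomic_numbers
            assert all(
                abs(a - b) <= 1e-6 for a, b in zip(final.coords_3d, mol.coords_3d)
            )
            if "xyz" not in (fmt_in, fmt_out):
                assert molecules_equal(mol, final, coord_tol=1e-6)

    def test_lossy_flag_only_through_xyz(self, water):
        to_xyz = convert(write_molecule(water, "cjson"), "cjson", "xyz")
        assert to_xyz.lossy and to_xyz.warnings
        to_cml = convert(write_molecule(water, "cjson"), "cjson", "cml")
        assert not to_cml.lossy and not to_cml.warnings

    def test_chemlog_source_uses_first_calculation(self, water):
        spec = LogFixtureSpec(
            molecule=water,
            tasks=[LogTask(kind="scf", energy=Quantity(-74.96, "hartree"))],
        )
        doc = parse_nwchem_log(generate_log(spec))
        result = convert(write_chemlog(doc), "chemlog", "xyz")
        back = read_xyz(result.text)
        assert back.atomic_numbers == water.atomic_numbers


class TestChemlogToCjson:
    def _doc_with_frequencies(self, water):
        vib = random_vibrations(water, seed=9, n_modes=3)
        spec = LogFixtureSpec(
            molecule=water,
            tasks=[
                LogTask(
                    kind="frequency",
                    energy=Quantity(-74.96, "hartree"),
                    vibrations=vib,
                )
            ],
        )
        return parse_nwchem_log(generate_log(spec))

    def test_frequency_count_conserved(self, water):
        cj = chemlog_to_cjson(self._doc_with_frequencies(water), 0)
        assert len(cj["vibrations"]["frequencies"]) == 3
        assert len(cj["vibrations"]["eigenVectors"]) == 3

    def test_no_vibrations_no_section(self, water):
        spec = LogFixtureSpec(
            molecule=water,
            tasks=[LogTask(kind="scf", energy=Quantity(-74.96, "hartree"))],
        )
        cj = chemlog_to_cjson(parse_nwchem_log(generate_log(spec)), 0)
        assert "vibrations" not in cj

    def test_coordinates_match_extract_molecule(self, water):
        doc = self._doc_with_frequencies(water)
        cj = chemlog_to_cjson(doc, 0)
        from chemstore.chemlog import extract_molecule

        mol = extract_molecule(doc, 0)
        assert all(
            abs(a - b) <= 1e-9
            for a, b in zip(cj["atoms"]["coords"]["3d"], mol.coords_3d)
        )

    def test_provenance_carried(self, water):
        cj = chemlog_to_cjson(self._doc_with_frequencies(water), 0)
        assert cj["provenance"]["code"] == "NWChem"


class TestVibrationFrames:
    def test_zero_amplitude_identity(self, water):
        vib = random_vibrations(water, seed=1)
        frames = vibration_frames(water, vib, 0, amplitude=0.0, n_frames=8)
        assert all(frame == water.coords_3d for frame in frames)

    def test_quarter_period_factors_exact(self, water):
        vib = random_vibrations(water, seed=2)
        amp = 0.3
        frames = vibration_frames(water, vib, 1, amplitude=amp, n_frames=4)
        mode = vib.modes[1]
        peak = max(abs(x) for x in mode)
        direction = [x / peak for x in mode]
        expected_factors = [0.0, amp, 0.0, -amp]
        for frame, factor in zip(frames, expected_factors):
            for c, r, d in zip(frame, water.coords_3d, direction):
                assert c - r == pytest.approx(factor * d, abs=1e-12)

    def test_sine_antisymmetry(self, water):
        vib = random_vibrations(water, seed=3)
        n = 10
        frames = vibration_frames(water, vib, 0, amplitude=0.5, n_frames=n)
        for k in range(1, n):
            d1 = [c - r for c, r in zip(frames[k], water.coords_3d)]
            d2 = [c - r for c, r in zip(frames[n - k], water.coords_3d)]
            assert all(a == pytest.approx(-b, abs=1e-12) for a, b in zip(d1, d2))

    def test_frame_zero_is_equilibrium(self, water):
        vib = random_vibrations(water, seed=4)
        frames = vibration_frames(water, vib, 0, amplitude=0.7, n_frames=13)
        assert frames[0] == water.coords_3d

    def test_bad_mode_index(self, water):
        vib = random_vibrations(water, seed=5)
        with pytest.raises(IndexError):
            vibration_frames(water, vib, len(vib.frequencies), 0.5, 4)


class TestCube:
    def test_layout(self, water):
        vol = VolumetricData(
            origin=(0.0, 0.0, 0.0),
            spacing=(0.5, 0.5, 0.5),
            dims=(2, 3, 4),
            values=[0.1 * i for i in range(24)],
            label="homo",
        )
        text = write_cube(water, vol)
        lines = text.splitlines()
        assert lines[0] == "homo"
        assert lines[2].split()[0] == "3"  # atom count
        assert lines[3].split()[0] == "2"  # nx
        assert len(lines) == 6 + 3 + 4  # header + atoms + 24 values, 6/line
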