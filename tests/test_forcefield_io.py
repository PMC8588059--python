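import numpy as np
import pytest

from glycofit.forcefield_io import (
    Conformer,
    ConformerSet,
    ParameterSet,
    glucose_parameters,
    parameters_from_dict,
    parameters_to_dict,
    read_coordinates,
    read_frcmod,
    read_manifest,
    read_prep_charges,
    write_frcmod,
    write_manifest,
    write_prep,
)

FRCMOD = """test parameters
MASS
Cg  12.010

BOND
Cg-Cg   310.000   1.5200

ANGLE
Cg-Cg-Cg   45.000   113.500

DIHE
Cg-Cg-Cg-Cg    1     0.4500     0.000    -2.
Cg-Cg-Cg-Cg    1     0.2000   180.000     3.

NONBON
  Cg    1.9080    0.1094
"""


class TestFrcmod:
    def test_negative_periodicity_merges_fourier_terms(self):
        ps = read_frcmod(FRCMOD)
        terms = ps.torsion_terms[("Cg", "Cg", "Cg", "Cg")]
        assert terms == [(2, 0.45, 0.0), (3, 0.2, 180.0)]

    def test_round_trip_idempotent_after_normalization(self):
        once = write_frcmod(read_frcmod(FRCMOD))
        twice = write_frcmod(read_frcmod(once))
        assert once == twice

    def test_full_glucose_set_round_trips(self, start_params):
        back = read_frcmod(write_frcmod(start_params))
        assert back.bond_terms == start_params.bond_terms
        assert back.angle_terms == start_params.angle_terms
        for t, terms in start_params.torsion_terms.items():
            assert [(n, pytest.approx(v), pytest.approx(g)) for n, v, g in back.torsion_terms[t]] == terms
        assert back.lj_terms == start_params.lj_terms

    def test_divider_applied_on_read(self):
        text = "t\nDIHE\nCg-Cg-Cg-Cg    2     0.9000     0.000     3.\n"
        ps = read_frcmod(text)
        assert ps.torsion_terms[("Cg", "Cg", "Cg", "Cg")] == [(3, 0.45, 0.0)]

    def test_empty_dihe_section_is_fine(self):
        ps = read_frcmod("t\nDIHE\n\nNONBON\n  Cg 1.9 0.1\n")
        assert ps.torsion_terms == {}

    def test_unknown_section_raises_with_line_number(self):
        with pytest.raises(ValueError, match="line 2"):
            read_frcmod("t\nsomething unexpected\n")

    def test_duplicate_term_last_wins_with_warning(self):
        text = "t\nBOND\nCg-Cg 300.0 1.5\nCg-Cg 310.0 1.52\n"
        with pytest.warns(UserWarning, match="duplicate bond"):
            ps = read_frcmod(text)
        assert ps.bond_terms[("Cg", "Cg")] == (310.0, 1.52)


class TestPrep:
    def test_charge_table_round_trip(self, topology, start_params):
        text = write_prep(topology, start_params.charges)
        charges, types = read_prep_charges(text)
        assert charges["C1"] == pytest.approx(start_params.charges["C1"], abs=1e-4)
        assert types["O5"] == "Os"
        assert len(charges) == 24


class TestCoordinates:
    def test_xyz_round_trip(self, tmp_path, topology, chair_coords):
        from glycofit.forcefield_io import write_xyz

        p = tmp_path / "glc.xyz"
        write_xyz(str(p), chair_coords, topology)
        back = read_coordinates(str(p), topology)
        np.testing.assert_allclose(back, chair_coords, atol=1e-7)

    def test_atom_count_mismatch_names_file(self, tmp_path, topology):
        p = tmp_path / "short.xyz"
        p.write_text("2\ncomment\nC 0 0 0\nC 1 0 0\n")
        with pytest.raises(ValueError, match="short.xyz"):
            read_coordinates(str(p), topology)

    def test_pdb_fixed_width_and_label_reorder(self, tmp_path, topology, chair_coords):
        lines = []
        order = list(range(topology.n_atoms))
        order[0], order[1] = order[1], order[0]  # swap first two atoms
        for serial, i in enumerate(order, start=1):
            a = topology.atoms[i]
            x, y, z = chair_coords[i]
            lines.append(
                f"ATOM  {serial:5d} {a.label:<4s}BGC A   1    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {a.element:>2s}"
            )
        p = tmp_path / "glc.pdb"
        p.write_text("\n".join(lines) + "\nEND\n")
        with pytest.warns(UserWarning, match="reordered"):
            back = read_coordinates(str(p), topology)
        np.testing.assert_allclose(back, chair_coords, atol=2e-3)  # PDB precision


class TestManifest:
    def test_reference_is_minimum_energy_row(self, topology, chair_coords):
        cs = ConformerSet(
            [
                Conformer("a", chair_coords, -5.0),
                Conformer("b", chair_coords, 0.0),
                Conformer("c", chair_coords, 2.0),
            ],
            topology,
        )
        assert cs.reference_index == 0

    def test_reference_tie_takes_lowest_row(self, topology, chair_coords):
        cs = ConformerSet(
            [Conformer("a", chair_coords, 1.0), Conformer("b", chair_coords, 1.0)], topology
        )
        assert cs.reference_index == 0

    def test_round_trip_preserves_everything(self, tmp_path, small_dataset):
        path = write_manifest(small_dataset, str(tmp_path))
        back = read_manifest(path, small_dataset.topology)
        assert back.ids == small_dataset.ids
        assert back.reference_index == small_dataset.reference_index
        np.testing.assert_allclose(
            back.coordinates_array(), small_dataset.coordinates_array(), atol=1e-7
        )
        np.testing.assert_allclose(back.energies(), small_dataset.energies(), atol=1e-9)
        np.testing.assert_allclose(back[0].charges, small_dataset[0].charges, atol=1e-9)

    def test_missing_coordinate_file_raises(self, tmp_path, topology):
        man = tmp_path / "manifest.csv"
        man.write_text("id,xyz,qm_energy\ns0,structures/nope.xyz,1.0\n")
        with pytest.raises(FileNotFoundError):
            read_manifest(str(man), topology)


class TestParameterSet:
    def test_yaml_dict_round_trip(self, start_params):
        back = parameters_from_dict(parameters_to_dict(start_params))
        assert back.torsion_terms == start_params.torsion_terms
        assert back.charges == start_params.charges
        assert back.scee == start_params.scee

    def test_phase_wrapped_to_circle(self):
        ps = ParameterSet(torsion_terms={("a", "b", "c", "d"): [(1, 1.0, -90.0)]})
        assert ps.torsion_terms[("a", "b", "c", "d")] == [(1, 1.0, 270.0)]

    def test_periodicity_outside_range_rejected(self):
        with pytest.raises(ValueError, match="periodicity"):
            ParameterSet(torsion_terms={("a", "b", "c", "d"): [(7, 1.0, 0.0)]})

    def test_missing_term_named_in_error(self, topology):
        ps = glucose_parameters()
        del ps.angle_terms[("Cg", "Os", "Cg")]
        with pytest.raises(KeyError, match="Cg-Os-Cg"):
            ps.validate_against(topology)

    def test_lorentz_berthelot_combination(self, start_params):
        a, b = start_params.lj_ab("Cg", "Cg")
        rmin, eps = 2 * 1.9080, 0.1094
        assert a == pytest.approx(eps * rmin**12)
        assert b == pytest.approx(2 * eps * rmin**6)
        assert start_params.lj_ab("Ho", "Ho") == (0.0, 0.0)
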