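"""Masking, the cut-by-model pipeline, run reports, errors and CLI."""

import json

import numpy as np
import pytest
from click.testing import CliRunner
from lxml import etree

from xtalkit.cell_symmetry import Grid_sampling, Spacegroup, grid_from_resolution
from xtalkit.cli import main as cli_main
from xtalkit.crystal_maps import Xmap, read_map_file, write_map_file
from xtalkit.density_tools import (RunReport, convert_report, cut_by_model,
                                   mask_by_model, read_report, write_report)
from xtalkit.errors import (InvalidArgument, OutOfRange, UnknownError, guard,
                            translate_error)
from xtalkit.model_hierarchy import make_atom_list, write_pdb
from xtalkit.reflection_data import calc_sf_direct, fft_synthesis, generate_hkl_list
from xtalkit.synthetic import make_toy_model, toy_minimol


@pytest.fixture
def p1_scene(tmp_path):
    """A band-limited P1 map rendered from a 2-atom model, on disk."""
    from xtalkit.cell_symmetry import make_cell
    cell = make_cell(16, 16, 16)
    sg = Spacegroup.from_name("P1")
    grid = grid_from_resolution(cell, 2.5, 1.5)
    atoms = make_toy_model(cell, 2, rng=7)
    mol = toy_minimol(cell, atoms, "P1")
    coeffs = calc_sf_direct(atoms, generate_hkl_list(cell, sg, 2.5), cell, sg)
    xmap = fft_synthesis(coeffs, grid)
    map_path, pdb_path = tmp_path / "in.mrc", tmp_path / "in.pdb"
    write_map_file(xmap, map_path)
    write_pdb(mol, pdb_path)
    return dict(cell=cell, sg=sg, grid=grid, atoms=atoms, xmap=xmap,
                map_path=map_path, pdb_path=pdb_path, tmp=tmp_path)


class TestMaskByModel:
    def test_huge_radius_keeps_map_unchanged(self, p1_scene):
        masked = mask_by_model(p1_scene["xmap"], p1_scene["atoms"], 100.0)
        assert np.array_equal(masked.values, p1_scene["xmap"].values)

    def test_tiny_radius_with_off_grid_atoms_zeroes_map(self, cubic_cell, p1):
        xmap = Xmap(cubic_cell, p1, Grid_sampling(8, 8, 8),
                    np.ones((8, 8, 8)))
        atoms = make_atom_list(["C"], [[0.6261, 0.677, 0.633]], [1.0], [0.0])
        masked = mask_by_model(xmap, atoms, 1e-6)
        assert np.all(masked.values == 0)

    def test_single_atom_count_matches_distance_oracle(self, cubic_cell, p1):
        xmap = Xmap(cubic_cell, p1, Grid_sampling(10, 10, 10),
                    np.ones((10, 10, 10)))
        atoms = make_atom_list(["C"], [[3.0, 3.0, 3.0]], [1.0], [0.0])
        radius = 1.5  # grid spacing is 1 A
        masked = mask_by_model(xmap, atoms, radius)
        survivors = int(np.count_nonzero(masked.values))
        count = 0
        for u in range(10):
            for v in range(10):
                for w in range(10):
                    # nearest periodic image distance on a cubic 10 A cell
                    d = np.abs(np.array([u, v, w]) - 3.0)
                    d = np.minimum(d, 10 - d)
                    if np.dot(d, d) <= radius * radius:
                        count += 1
        assert survivors == count

    def test_mask_never_increases_magnitude(self, p1_scene):
        masked = mask_by_model(p1_scene["xmap"], p1_scene["atoms"], 2.0)
        assert np.all(np.abs(masked.values) <= np.abs(p1_scene["xmap"].values) + 1e-15)

    def test_mask_is_symmetry_consistent(self):
        from xtalkit.cell_symmetry import make_cell
        cell = make_cell(18, 22, 16)
        sg = Spacegroup.from_name("P212121")
        grid = grid_from_resolution(cell, 3.0, 1.5, spacegroup=sg)
        atoms = make_toy_model(cell, 3, rng=9)
        from xtalkit.synthetic import random_symmetric_xmap
        xmap = random_symmetric_xmap(cell, sg, grid, rng=10)
        masked = mask_by_model(xmap, atoms, 2.5)
        masked2 = Xmap(cell, sg, grid, masked.values)
        masked2.symmetrize("mean")
        assert np.abs(masked.values - masked2.values).max() < 1e-12

    def test_bad_radius_rejected(self, p1_scene):
        with pytest.raises(ValueError):
            mask_by_model(p1_scene["xmap"], p1_scene["atoms"], 0.0)


class TestRunReport:
    @pytest.fixture
    def report(self):
        rep = RunReport("cut_by_model", user="jon",
                        date="Fri Feb 24 11:14:24 2017", ok=True,
                        parameters={"mapin": "emd_5148.mrc",
                                    "pdbin": "emd_5148_3ktt.pdb",
                                    "b_factor": "-10.0", "resolution": "2.5",
                                    "mask_radius": "2.5"})
        rep.add_input("emd_5148_3ktt.pdb", "PDB", True)
        rep.add_input("emd_5148.mrc", "xmap", True)
        rep.add_output("mapout_cut_density.mtz", "mini MTZ", True)
        return rep

    def test_xml_element_structure(self, report):
        root = report.to_xml_element()
        assert root.tag == "program"
        assert root.get("name") == "cut_by_model"
        assert root.get("ok") == "yes"
        assert len(root.findall("parameters")) == 1
        assert len(root.findall("input_file")) == 2
        assert len(root.findall("output_file")) == 1
        params = root.find("parameters")
        assert params.get("b_factor") == "-10.0"
        assert params.get("resolution") == "2.5"
        assert params.get("mask_radius") == "2.5"

    def test_json_attribute_keys_carry_dash_prefix(self, report):
        obj = report.to_json_dict()
        prog = obj["program"]
        assert prog["-name"] == "cut_by_model"
        assert prog["-user"] == "jon"
        assert prog["-ok"] == "yes"
        assert prog["parameters"]["-mask_radius"] == "2.5"
        assert prog["output_file"]["-type"] == "mini MTZ"
        assert isinstance(prog["input_file"], list) and len(prog["input_file"]) == 2

    def test_xml_json_xml_round_trip_is_structure_identical(self, report, tmp_path):
        xml_path = tmp_path / "report.xml"
        write_report(report, xml_path, "xml")
        json_path = convert_report(xml_path, "json")
        xml2_path = convert_report(json_path, "xml", tmp_path / "report2.xml")
        a = etree.tostring(etree.parse(str(xml_path)).getroot())
        b = etree.tostring(etree.parse(str(xml2_path)).getroot())
        assert a == b

    def test_json_round_trip(self, report, tmp_path):
        path = tmp_path / "report.json"
        write_report(report, path, "json")
        back = read_report(path)
        assert back.to_json_dict() == report.to_json_dict()

    def test_schema_validates_against_dtd(self, report):
        dtd = etree.DTD(
            __import__("io").StringIO("""
            <!ELEMENT program (parameters, input_file*, output_file*)>
            <!ATTLIST program name CDATA #REQUIRED user CDATA #REQUIRED
                      date CDATA #REQUIRED ok (yes|no) #REQUIRED>
            <!ELEMENT parameters EMPTY>
            <!ATTLIST parameters mapin CDATA #IMPLIED pdbin CDATA #IMPLIED
                      b_factor CDATA #IMPLIED resolution CDATA #IMPLIED
                      mask_radius CDATA #IMPLIED>
            <!ELEMENT input_file EMPTY>
            <!ATTLIST input_file name CDATA #REQUIRED type CDATA #REQUIRED
                      ok (yes|no) #REQUIRED>
            <!ELEMENT output_file EMPTY>
            <!ATTLIST output_file name CDATA #REQUIRED type CDATA #REQUIRED
                      ok (yes|no) #REQUIRED>
            """))
        assert dtd.validate(report.to_xml_element())

    def test_malformed_report_file_rejected(self, tmp_path):
        path = tmp_path / "junk.xml"
        path.write_text("<program name='x'")
        with pytest.raises(ValueError):
            read_report(path)


class TestErrorTaxonomy:
    def test_out_of_extent_is_index_error(self, cubic_cell):
        from xtalkit.crystal_maps import NXmap
        nx = NXmap.from_cell_grid(np.zeros((2, 2, 2)), cubic_cell,
                                  Grid_sampling(8, 8, 8))
        with pytest.raises(IndexError):
            nx.get((3, 0, 0))
        assert translate_error(OutOfRange("x")) is IndexError

    def test_malformed_symop_is_value_error(self):
        from xtalkit.cell_symmetry import parse_symop
        with pytest.raises(ValueError):
            parse_symop("-x,qq,z")
        assert translate_error(InvalidArgument("x")) is ValueError

    def test_fatal_is_runtime_error(self):
        from xtalkit.errors import MessageFatal
        assert translate_error(MessageFatal("x")) is RuntimeError

    def test_unexpected_fault_surfaces_as_catch_all(self):
        # session continues: the failure is catchable, classified
        with pytest.raises(UnknownError):
            with guard():
                raise ArithmeticError("injected")
        assert translate_error(ArithmeticError("x")) is UnknownError


class TestCutByModel:
    def test_report_echoes_printed_parameters(self, p1_scene):
        out, report = cut_by_model(p1_scene["map_path"], p1_scene["pdb_path"],
                                   -10.0, 2.5, 2.5,
                                   p1_scene["tmp"] / "cut", report_format="xml")
        assert report.ok
        assert report.parameters["b_factor"] == "-10.0"
        assert report.parameters["resolution"] == "2.5"
        assert report.parameters["mask_radius"] == "2.5"
        root = etree.parse(str(out["report"])).getroot()
        assert root.tag == "program"
        assert len(root.findall("input_file")) == 2
        assert {e.get("type") for e in root.findall("input_file")} == {"PDB", "xmap"}
        assert all(e.get("ok") == "yes" for e in root.iter() if e.get("ok"))

    def test_identity_limit_reproduces_input_map(self, p1_scene):
        out, report = cut_by_model(p1_scene["map_path"], p1_scene["pdb_path"],
                                   0.0, 2.5, 100.0, p1_scene["tmp"] / "ident")
        back = read_map_file(out["map"])
        original = read_map_file(p1_scene["map_path"])
        scale = np.abs(original.values).max()
        assert np.abs(back.values - original.values).max() < 1e-6 * max(scale, 1)

    def test_sharpening_increases_high_to_low_amplitude_ratio(self, p1_scene):
        from xtalkit.reflection_data import read_text
        ratios = []
        for i, b in enumerate((-10.0, -20.0)):
            out, _ = cut_by_model(p1_scene["map_path"], p1_scene["pdb_path"],
                                  b, 2.5, 100.0, p1_scene["tmp"] / f"sh{i}")
            data = read_text(out["coeffs_text"], p1_scene["cell"],
                             p1_scene["sg"], 2.5)
            s2 = data.invresolsq()
            hi, lo = s2 > np.median(s2), s2 <= np.median(s2)
            ratios.append(data.f[hi].mean() / data.f[lo].mean())
        assert ratios[1] > ratios[0]

    def test_pipeline_is_deterministic(self, p1_scene):
        out1, _ = cut_by_model(p1_scene["map_path"], p1_scene["pdb_path"],
                               -5.0, 3.0, 2.5, p1_scene["tmp"] / "d1")
        out2, _ = cut_by_model(p1_scene["map_path"], p1_scene["pdb_path"],
                               -5.0, 3.0, 2.5, p1_scene["tmp"] / "d2")
        assert (out1["coeffs_text"].read_text() == out2["coeffs_text"].read_text())
        m1 = out1["map"].read_bytes()
        m2 = out2["map"].read_bytes()
        assert m1[1024:] == m2[1024:]  # data block bitwise identical

    def test_failed_input_marked_not_ok(self, p1_scene):
        with pytest.raises(RuntimeError):
            cut_by_model(p1_scene["map_path"], p1_scene["tmp"] / "missing.pdb",
                         0.0, 2.5, 2.5, p1_scene["tmp"] / "fail")
        report = read_report(p1_scene["tmp"] / "fail_report.xml")
        assert not report.ok
        assert report.input_files[0]["ok"] is False

    def test_mtz_output_cross_reads(self, p1_scene):
        pytest.importorskip("gemmi")
        from xtalkit.reflection_data import read_mtz, read_text
        out, _ = cut_by_model(p1_scene["map_path"], p1_scene["pdb_path"],
                              -10.0, 2.5, 2.5, p1_scene["tmp"] / "mtz")
        assert "coeffs_mtz" in out
        mtz_data = read_mtz(out["coeffs_mtz"])
        txt_data = read_text(out["coeffs_text"], p1_scene["cell"],
                             p1_scene["sg"], 2.5)
        assert np.abs(np.sort(mtz_data.f) - np.sort(txt_data.f)).max() < 1e-4


class TestCli:
    def test_cut_by_model_command(self, p1_scene):
        runner = CliRunner()
        result = runner.invoke(cli_main, [
            "cut-by-model", "--mapin", str(p1_scene["map_path"]),
            "--pdbin", str(p1_scene["pdb_path"]), "--b-factor", "-10.0",
            "--resolution", "2.5", "--mask-radius", "2.5",
            "--out", str(p1_scene["tmp"] / "cli"), "--report", "json"])
        assert result.exit_code == 0, result.output
        report = json.loads((p1_scene["tmp"] / "cli_report.json").read_text())
        assert report["program"]["-ok"] == "yes"

    def test_error_path_exits_nonzero_with_category(self, p1_scene):
        runner = CliRunner()
        result = runner.invoke(cli_main, [
            "cut-by-model", "--mapin", str(p1_scene["tmp"] / "absent.mrc"),
            "--pdbin", str(p1_scene["pdb_path"]), "--resolution", "2.5",
            "--out", str(p1_scene["tmp"] / "x")])
        assert result.exit_code != 0
        assert "RuntimeError" in result.output

    def test_convert_report_command(self, p1_scene, tmp_path):
        rep = RunReport("cut_by_model", user="jon", parameters={"b_factor": "-10.0"})
        rep.add_input("a.pdb", "PDB")
        xml_path = tmp_path / "r.xml"
        write_report(rep, xml_path, "xml")
        runner = CliRunner()
        result = runner.invoke(cli_main, ["convert-report", str(xml_path),
                                          "--to", "json"])
        assert result.exit_code == 0, result.output
        assert (tmp_path / "r.json").exists()
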