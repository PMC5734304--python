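"""Reflection lists, structure factors, FFT duality and scaling."""

import math

import numpy as np
import pytest

from xtalkit.cell_symmetry import Grid_sampling, Spacegroup, grid_from_resolution
from xtalkit.model_hierarchy import make_atom_list
from xtalkit.reflection_data import (HKL, HKL_data_F_Phi, calc_sf_direct,
                                     export_array, fft_analysis, fft_synthesis,
                                     generate_hkl_list, import_array,
                                     patterson_coeffs, read_text, scale_coeffs,
                                     write_mmcif_sf, write_text)
from xtalkit.reflection_data import _expand_to_sphere
from xtalkit.synthetic import make_toy_model, render_gaussian_map


@pytest.fixture
def random_p1_data(cubic_cell, p1, rng):
    data = HKL_data_F_Phi(cubic_cell, p1, 4.0)
    data.f = rng.uniform(1, 10, len(data))
    data.phi = rng.uniform(-180, 180, len(data))
    return data


class TestGenerateHklList:
    def test_p1_count_matches_brute_force_sphere(self, cubic_cell, p1):
        got = {tuple(h) for h in generate_hkl_list(cubic_cell, p1, 5.0)}
        expected = set()
        for h in range(-3, 4):
            for k in range(-3, 4):
                for l in range(-3, 4):
                    if (h, k, l) == (0, 0, 0):
                        continue
                    if (h * h + k * k + l * l) / 100.0 > 0.04 + 1e-12:
                        continue
                    if h > 0 or (h == 0 and k > 0) or (h == 0 and k == 0 and l > 0):
                        expected.add((h, k, l))
        assert got == expected

    def test_low_resolution_gives_empty_list(self, cubic_cell, p1):
        assert generate_hkl_list(cubic_cell, p1, 25.0) == []

    def test_p21_screw_absences(self, ortho_cell):
        # 2_1 along b: (0,k,0) with odd k are absent; the oracle is the
        # operator phase restriction h.R = h with non-integral h.t
        sg = Spacegroup.from_name("P21")
        got = generate_hkl_list(ortho_cell, sg, 3.0)
        axial = [(h, k, l) for h, k, l in (tuple(x) for x in got)
                 if h == 0 and l == 0]
        assert axial  # even orders present
        assert all(k % 2 == 0 for _, k, _ in axial)
        op = sg[1]
        for h in (np.array([0, 1, 0]), np.array([0, 3, 0])):
            assert np.array_equal(h @ op.rot, h)
            assert (h @ op.trn) % 1 != pytest.approx(0.0, abs=1e-9)

    def test_deterministic_sorted_order(self, cubic_cell, p1):
        hkls = [tuple(h) for h in generate_hkl_list(cubic_cell, p1, 4.0)]
        assert hkls == sorted(hkls)

    def test_symmetry_unique_under_point_group(self, ortho_cell, p212121):
        hkls = generate_hkl_list(ortho_cell, p212121, 3.0)
        seen = {tuple(h) for h in hkls}
        for h in hkls:
            arr = np.array(tuple(h))
            for op in p212121:
                for img in (arr @ op.rot, -(arr @ op.rot)):
                    t = tuple(img)
                    if t in seen and t != tuple(h):
                        pytest.fail(f"{tuple(h)} and {t} are symmetry mates")


class TestArrayContract:
    def test_export_import_identity(self, random_p1_data):
        arr = export_array(random_p1_data)
        clone = random_p1_data.copy()
        import_array(clone, arr)
        assert np.array_equal(export_array(clone), arr)

    def test_export_is_detached_copy(self, random_p1_data):
        arr = export_array(random_p1_data)
        arr[:, 0] = -1.0
        assert random_p1_data.f.min() > 0

    def test_column_order_f_then_phi(self, cubic_cell, p1):
        data = HKL_data_F_Phi(cubic_cell, p1, 5.0, [(1, 0, 0)], [7.0], [33.0])
        arr = export_array(data)
        assert arr.shape == (1, 2)
        assert arr[0, 0] == 7.0 and arr[0, 1] == 33.0

    def test_shape_mismatch_rejected(self, random_p1_data):
        with pytest.raises(ValueError):
            import_array(random_p1_data, np.zeros((len(random_p1_data), 3)))


class TestPatterson:
    def test_squares_amplitudes_and_zeroes_phases(self, cubic_cell, p1):
        data = HKL_data_F_Phi(cubic_cell, p1, 5.0, [(1, 0, 0)], [2.0], [45.0])
        pat = patterson_coeffs(data)
        assert pat.f[0] == 4.0 and pat.phi[0] == 0.0
        assert np.array_equal(pat.hkl, data.hkl)

    def test_all_zero_data_stays_zero(self, cubic_cell, p1):
        data = HKL_data_F_Phi(cubic_cell, p1, 5.0, [(1, 0, 0)], [0.0], [10.0])
        pat = patterson_coeffs(data)
        assert pat.f[0] == 0.0

    def test_patterson_map_is_centrosymmetric(self, random_p1_data):
        pat = patterson_coeffs(random_p1_data)
        xmap = fft_synthesis(pat, Grid_sampling(12, 12, 12))
        n = xmap.grid.nuvw
        idx = np.indices(xmap.values.shape)
        inverted = tuple(np.mod(-idx, n.reshape(3, 1, 1, 1)))
        assert np.abs(xmap.values - xmap.values[inverted]).max() < 1e-8


class TestCalcSfDirect:
    def test_point_scatterer_at_origin(self, cubic_cell, p1):
        atoms = make_atom_list(["C"], [[0, 0, 0]], [1.0], [0.0])
        hkls = generate_hkl_list(cubic_cell, p1, 4.0)
        data = calc_sf_direct(atoms, hkls, cubic_cell, p1)
        assert np.allclose(data.f, 6.0)  # carbon: 6 electrons, B = 0
        assert np.allclose(data.phi, 0.0, atol=1e-9)

    def test_shift_theorem_on_h00(self, cubic_cell, p1):
        atoms = make_atom_list(["C"], [[5.0, 0, 0]], [1.0], [0.0])  # frac (1/2,0,0)
        data = calc_sf_direct(atoms, [HKL(1, 0, 0), HKL(2, 0, 0), HKL(3, 0, 0)],
                              cubic_cell, p1)
        phases = np.mod(data.phi + 180.0, 360.0) - 180.0
        assert phases[0] == pytest.approx(180.0, abs=1e-9) or \
            phases[0] == pytest.approx(-180.0, abs=1e-9)
        assert phases[1] == pytest.approx(0.0, abs=1e-9)
        assert abs(phases[2]) == pytest.approx(180.0, abs=1e-9)

    def test_two_atom_structure_matches_complex_sum_oracle(self, ortho_cell, p1):
        atoms = make_atom_list(["C", "O"], [[2.0, 3.0, 4.0], [5.0, 6.0, 2.5]],
                               [1.0, 0.8], [0.02, 0.05])
        hkls = generate_hkl_list(ortho_cell, p1, 3.0)[:50]
        data = calc_sf_direct(atoms, hkls, ortho_cell, p1)
        # independent per-reflection complex sum
        frac = ortho_cell.fractionalize(atoms.coords)
        for row, f_got, phi_got in zip(data.hkl, data.f, data.phi):
            s2 = float(ortho_cell.invresolsq(row))
            fc = 0j
            for (x, occ, u, z) in zip(frac, [1.0, 0.8], [0.02, 0.05], [6, 8]):
                b = 8 * math.pi**2 * u
                fc += z * occ * math.exp(-b * s2 / 4) * np.exp(2j * math.pi * np.dot(row, x))
            assert abs(abs(fc) - f_got) <= 1e-10 * max(abs(fc), 1e-30)
            if abs(fc) > 1e-12:
                dphi = (math.degrees(np.angle(fc)) - phi_got + 180) % 360 - 180
                assert abs(dphi) < 1e-8

    def test_systematic_absences_vanish_for_symmetric_structure(self, ortho_cell):
        sg = Spacegroup.from_name("P21")
        atoms = make_atom_list(["C"], [[2.0, 3.0, 4.0]], [1.0], [0.02])
        axial = [HKL(0, 1, 0), HKL(0, 3, 0), HKL(0, 5, 0)]
        present = [HKL(0, 2, 0), HKL(1, 1, 1)]
        data = calc_sf_direct(atoms, axial + present, ortho_cell, sg)
        assert data.f[:3].max() < 1e-8 * data.f.max()

    def test_unknown_element_rejected(self, cubic_cell, p1):
        atoms = make_atom_list(["Qq"], [[0, 0, 0]], [1.0], [0.0],
                               allow_unknown_atoms=True)
        with pytest.raises(ValueError):
            calc_sf_direct(atoms, [HKL(1, 0, 0)], cubic_cell, p1)


class TestFftDuality:
    def test_single_reflection_gives_cosine_wave(self, cubic_cell, p1):
        data = HKL_data_F_Phi(cubic_cell, p1, 5.0, [(1, 0, 0)], [1.0], [0.0])
        xmap = fft_synthesis(data, Grid_sampling(8, 8, 8))
        u = np.arange(8) / 8.0
        expected = (2.0 / cubic_cell.volume) * np.cos(2 * np.pi * u)
        assert np.abs(xmap.values[:, 0, 0] - expected).max() < 1e-12
        assert xmap.values[:, 0, 0].argmax() == 0

    def test_analysis_synthesis_round_trip(self, random_p1_data):
        grid = Grid_sampling(12, 12, 12)
        back = fft_analysis(fft_synthesis(random_p1_data, grid), 4.0)
        assert np.array_equal(back.hkl, random_p1_data.hkl)
        assert np.abs(back.f - random_p1_data.f).max() < 1e-8
        dphi = (back.phi - random_p1_data.phi + 180) % 360 - 180
        assert np.abs(dphi).max() < 1e-6

    def test_round_trip_in_p212121(self, p212121, rng):
        from conftest import random_cell
        cell = random_cell(np.random.default_rng(8))
        cell = type(cell)(cell.a, cell.b, cell.c)  # orthorhombic metric
        data = HKL_data_F_Phi(cell, p212121, 3.5)
        data.f = rng.uniform(1, 5, len(data))
        data.phi = rng.uniform(-180, 180, len(data))
        grid = grid_from_resolution(cell, 3.5, 1.5, spacegroup=p212121)
        back = fft_analysis(fft_synthesis(data, grid), 3.5)
        assert np.abs(back.f - data.f).max() < 1e-8

    def test_dual_route_amplitudes_agree(self, ortho_cell, p212121):
        # route 1: reciprocal-space direct summation
        # route 2: real-space Gaussian render + FFT analysis
        atoms = make_toy_model(ortho_cell, n_atoms=5, rng=3, u_iso=0.3)
        grid = grid_from_resolution(ortho_cell, 3.0, 3.0, spacegroup=p212121)
        rendered = render_gaussian_map(atoms, ortho_cell, p212121, grid)
        via_fft = fft_analysis(rendered, 3.0)
        via_sum = calc_sf_direct(atoms, [HKL(*row) for row in via_fft.hkl],
                                 ortho_cell, p212121)
        r_factor = np.sum(np.abs(via_sum.f - via_fft.f)) / np.sum(via_sum.f)
        assert r_factor < 0.01

    def test_too_coarse_grid_rejected(self, random_p1_data):
        with pytest.raises(ValueError):
            fft_synthesis(random_p1_data, Grid_sampling(4, 4, 4))

    def test_parseval(self, random_p1_data):
        grid = Grid_sampling(16, 16, 16)
        xmap = fft_synthesis(random_p1_data, grid)
        sum_f2 = sum(abs(fc) ** 2 for fc in _expand_to_sphere(random_p1_data).values())
        v = random_p1_data.cell.volume
        grid_sum = (xmap.values ** 2).sum() * v ** 2 / grid.size
        assert sum_f2 == pytest.approx(grid_sum, rel=1e-10)

    def test_nan_records_are_skipped(self, cubic_cell, p1):
        data = HKL_data_F_Phi(cubic_cell, p1, 5.0, [(1, 0, 0), (0, 1, 0)],
                              [1.0, np.nan], [0.0, 0.0])
        xmap = fft_synthesis(data, Grid_sampling(8, 8, 8))
        back = fft_analysis(xmap, 5.0)
        idx = {tuple(h): i for i, h in enumerate(back.hkl)}
        assert back.f[idx[(1, 0, 0)]] == pytest.approx(1.0, abs=1e-10)
        assert back.f[idx[(0, 1, 0)]] == pytest.approx(0.0, abs=1e-10)

    def test_transforms_are_pure(self, random_p1_data):
        grid = Grid_sampling(12, 12, 12)
        a = fft_synthesis(random_p1_data, grid)
        b = fft_synthesis(random_p1_data, grid)
        assert np.array_equal(a.values, b.values)


class TestScaleCoeffs:
    def test_zero_b_factor_is_identity(self, random_p1_data):
        out = scale_coeffs(random_p1_data, 0.0)
        assert np.array_equal(out.f, random_p1_data.f)

    def test_plus_then_minus_b_round_trip(self, random_p1_data):
        out = scale_coeffs(scale_coeffs(random_p1_data, 30.0), -30.0)
        assert np.abs(out.f - random_p1_data.f).max() < 1e-12

    def test_closed_form_at_two_angstroms(self, cubic_cell, p1):
        # |s| = 0.5 at d = 2 A: F scales by exp(10 / 16)
        data = HKL_data_F_Phi(cubic_cell, p1, 2.0, [(5, 0, 0)], [1.0], [0.0])
        out = scale_coeffs(data, -10.0)
        assert out.f[0] == pytest.approx(math.exp(0.625), rel=1e-12)

    def test_resolution_truncation(self, random_p1_data):
        out = scale_coeffs(random_p1_data, 0.0, d_min=6.0)
        assert len(out) < len(random_p1_data)
        assert np.all(out.invresolsq() <= 1 / 36 + 1e-9)


class TestTextAndCifExport:
    def test_text_round_trip(self, tmp_path, random_p1_data):
        path = tmp_path / "refl.tsv"
        write_text(random_p1_data, path)
        back = read_text(path, random_p1_data.cell, random_p1_data.spacegroup, 4.0)
        assert np.array_equal(back.hkl, random_p1_data.hkl)
        assert np.abs(back.f - random_p1_data.f).max() < 1e-4

    def test_mmcif_parsed_by_external_reader(self, tmp_path, random_p1_data):
        gemmi = pytest.importorskip("gemmi")
        path = tmp_path / "refl.cif"
        write_mmcif_sf(random_p1_data, path)
        doc = gemmi.cif.read(str(path))
        block = doc.sole_block()
        h = [int(x) for x in block.find_loop("_refln.index_h")]
        f = [float(x) for x in block.find_loop("_refln.F_calc")]
        assert h == list(random_p1_data.hkl[:, 0])
        assert np.abs(np.array(f) - random_p1_data.f).max() < 1e-4
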