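"""Image simulation: structures, membrane frames, surface maps, dilation."""

import numpy as np
import pytest

from secafm import (
    MembraneFrame,
    TipModel,
    Topograph,
    dilate_with_tip,
    gen_sphere_cluster,
    load_structure,
    resolve_membrane,
    sim_protrusion_metrics,
    surface_height_map,
)

PDB_ATOM = (
    "ATOM      1  CA  ALA A   1    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
    "           C  \n"
)
PDB_DUM = (
    "HETATM{serial:5d}  {el}   DUM X{resid:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
    "  1.00  0.00           {el}  \n"
)


def brute_force_surface(model, plane_z, x0, y0, nrow, ncol, pixel_A):
    """Per-pixel max over all spheres — the geometric oracle."""
    px, py, pz = model.coords.T
    z = pz - plane_z
    out = np.zeros((nrow, ncol))
    for i in range(nrow):
        for j in range(ncol):
            d2 = (px - (x0 + j * pixel_A)) ** 2 + (py - (y0 + i * pixel_A)) ** 2
            ok = d2 <= model.radii**2
            if ok.any():
                out[i, j] = max(
                    0.0, np.max(z[ok] + np.sqrt(model.radii[ok] ** 2 - d2[ok]))
                )
    return out


def brute_force_dilation(surface: Topograph, tip: TipModel) -> np.ndarray:
    """O(N^2 M^2) double-loop dilation oracle."""
    h = surface.heights
    nrow, ncol = h.shape
    pixel_A = surface.pixel_nm * 10.0
    ii, jj = np.mgrid[0:nrow, 0:ncol]
    out = np.empty_like(h)
    for i in range(nrow):
        for j in range(ncol):
            r = np.hypot(ii - i, jj - j) * pixel_A
            out[i, j] = np.max(h - tip.profile_A(r))
    return out


class TestLoadStructure:
    def test_single_carbon_pdb(self, tmp_path):
        p = tmp_path / "one.pdb"
        p.write_text(PDB_ATOM.format(x=1.0, y=2.0, z=3.0) + "END\n")
        m = load_structure(p)
        assert m.n_atoms == 1
        assert m.radii[0] == pytest.approx(1.70)
        assert np.allclose(m.coords[0], [1.0, 2.0, 3.0])

    def test_empty_file_is_an_error(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("")
        with pytest.raises(Exception):
            load_structure(p)

    def test_unknown_element_falls_back_with_warning(self, tmp_path):
        p = tmp_path / "odd.pdb"
        line = PDB_ATOM.format(x=0.0, y=0.0, z=0.0).replace(" C  \n", " Q  \n")
        p.write_text(line + "END\n")
        with pytest.warns(UserWarning, match="fallback"):
            m = load_structure(p)
        assert m.radii[0] == pytest.approx(1.70)


class TestMembraneFrame:
    def test_explicit_planes_echoed(self):
        m = gen_sphere_cluster(3, seed=0)
        f = resolve_membrane(m, mode="explicit", normal=[0, 0, 2.0],
                             periplasmic_offset_A=20.0,
                             cytoplasmic_offset_A=-20.0)
        assert f.thickness_A == pytest.approx(40.0)
        assert np.allclose(f.normal, [0, 0, 1])

    def test_dum_layers_give_bilayer_thickness(self, tmp_path):
        lines = []
        serial = 1
        for z in (19.8, 20.2, 20.0):
            lines.append(PDB_DUM.format(serial=serial, el="N", resid=serial,
                                        x=serial * 5.0, y=0.0, z=z))
            serial += 1
        for z in (-20.1, -19.9, -20.0):
            lines.append(PDB_DUM.format(serial=serial, el="O", resid=serial,
                                        x=serial * 5.0, y=0.0, z=z))
            serial += 1
        lines.append(PDB_ATOM.format(x=0.0, y=0.0, z=25.0))
        p = tmp_path / "opm.pdb"
        p.write_text("".join(lines) + "END\n")
        model = load_structure(p)
        frame = resolve_membrane(model)
        assert 25.0 <= frame.thickness_A <= 45.0
        assert frame.periplasmic_offset_A == pytest.approx(20.0, abs=0.5)

    def test_missing_dum_atoms_instructs_explicit_mode(self):
        m = gen_sphere_cluster(3, seed=0)
        with pytest.raises(ValueError, match="explicit"):
            resolve_membrane(m, mode="dum_atoms")


class TestSurfaceHeightMap:
    @pytest.mark.parametrize("center_z,expected", [(0.0, 2.0), (10.0, 12.0)])
    def test_single_sphere_geometry(self, center_z, expected):
        from secafm.afmsim import AtomModel

        model = AtomModel(np.array([[0.0, 0.0, center_z]]), np.array([2.0]),
                          ["C"])
        frame = MembraneFrame([0, 0, 1], 0.0, -40.0)
        topo = surface_height_map(model, frame, "periplasmic", pixel_nm=0.2)
        assert topo.heights.max() == pytest.approx(expected)

    def test_matches_brute_force_oracle(self):
        model = gen_sphere_cluster(25, box_nm=6.0, seed=2)
        frame = MembraneFrame([0, 0, 1], 20.0, -20.0)
        topo = surface_height_map(model, frame, "periplasmic", pixel_nm=0.2,
                                  margin_nm=1.0)
        # reconstruct the grid origin the implementation used
        tops = model.coords[:, 2] + model.radii - 20.0
        act = tops > 0
        u = np.array([0.0, 1.0, 0.0])   # cross(z, x)
        v = np.array([-1.0, 0.0, 0.0])  # cross(z, u)
        px, py = model.coords @ u, model.coords @ v
        x0 = px[act].min() - 10.0
        y0 = py[act].min() - 10.0
        coords = np.column_stack([px, py, model.coords[:, 2]])
        from secafm.afmsim import AtomModel

        mirror = AtomModel(coords, model.radii, model.elements)
        oracle = brute_force_surface(mirror, 20.0, x0, y0, *topo.shape, 2.0)
        assert np.abs(topo.heights - oracle).max() < 1e-9

    def test_no_atoms_above_plane_warns_and_zeroes(self):
        model = gen_sphere_cluster(5, box_nm=3.0, seed=3)
        frame = MembraneFrame([0, 0, 1], 500.0, -500.0)
        with pytest.warns(UserWarning, match="no atom"):
            topo = surface_height_map(model, frame, "periplasmic")
        assert np.all(topo.heights == 0.0)


class TestTipModel:
    def test_profile_zero_at_apex_and_monotone(self):
        tip = TipModel()
        r = np.linspace(0.0, 400.0, 500)
        prof = tip.profile_A(r)
        assert prof[0] == 0.0
        assert np.all(np.diff(prof) >= -1e-12)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            TipModel(r_inner_nm=9.0, r_outer_nm=8.0)
        with pytest.raises(ValueError):
            TipModel(half_angle_deg=0.0)


class TestDilation:
    def test_flat_surface_unchanged(self):
        flat = Topograph(np.full((20, 20), 5.0), pixel_nm=1.0)
        out = dilate_with_tip(flat, TipModel())
        assert np.allclose(out.heights, 5.0)

    def test_matches_brute_force_and_preserves_max(self):
        rng = np.random.default_rng(1)
        surf = Topograph(rng.uniform(0.0, 60.0, (32, 32)), pixel_nm=0.5)
        tip = TipModel()
        fast = dilate_with_tip(surf, tip).heights
        slow = brute_force_dilation(surf, tip)
        assert np.abs(fast - slow).max() == 0.0
        assert fast.max() == surf.heights.max()

    def test_monotone_and_extensive(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0.0, 30.0, (24, 24))
        b = a + rng.uniform(0.0, 10.0, (24, 24))
        tip = TipModel()
        da = dilate_with_tip(Topograph(a, 0.5), tip).heights
        db = dilate_with_tip(Topograph(b, 0.5), tip).heights
        assert np.all(da >= a)  # extensive
        assert np.all(db >= da)  # monotone
        # dilated volume >= pre-dilation volume
        assert da.clip(0).sum() >= a.clip(0).sum()

    def test_undersampled_tip_warns(self):
        surf = Topograph(np.zeros((8, 8)), pixel_nm=5.0)
        surf.heights[4, 4] = 10.0
        with pytest.warns(UserWarning, match="undersampled"):
            dilate_with_tip(surf, TipModel())


class TestProtrusionMetrics:
    def test_zero_image(self):
        assert sim_protrusion_metrics(Topograph(np.zeros((5, 5)), 1.0)) == (0.0, 0.0)

    def test_single_pixel(self):
        h = np.zeros((5, 5))
        h[2, 2] = 7.0
        max_h, vol = sim_protrusion_metrics(Topograph(h, 2.0))
        assert max_h == 7.0
        assert vol == pytest.approx(7.0 * 400.0)  # 2 nm pixel = 400 Å^2

    def test_connected_only_ignores_secondary_blobs(self):
        h = np.zeros((9, 9))
        h[1:3, 1:3] = 5.0   # small satellite
        h[6:8, 6:8] = 20.0  # dominant protrusion
        max_h, vol = sim_protrusion_metrics(Topograph(h, 1.0))
        assert max_h == 20.0
        assert vol == pytest.approx(4 * 20.0 * 100.0)

    def test_rotation_about_normal_leaves_metrics_invariant(self):
        model = gen_sphere_cluster(20, box_nm=5.0, seed=6)
        frame = MembraneFrame([0, 0, 1], 10.0, -30.0)
        tip = TipModel()

        def metrics(m):
            surf = surface_height_map(m, frame, "periplasmic", pixel_nm=0.2)
            return sim_protrusion_metrics(dilate_with_tip(surf, tip))

        theta = np.deg2rad(90.0)
        rot = np.array([[np.cos(theta), -np.sin(theta), 0.0],
                        [np.sin(theta), np.cos(theta), 0.0],
                        [0.0, 0.0, 1.0]])
        h0, v0 = metrics(model)
        h1, v1 = metrics(model.transformed(rot))
        assert h1 == pytest.approx(h0, abs=0.3)  # pixel discretisation only
        assert v1 == pytest.approx(v0, rel=0.02)
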