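"""Contour extraction, resampling, lattice topology and STL export."""

import numpy as np
import pytest

from thyromesh.io import MaskVolume
from thyromesh.mesh import (
    Contour,
    MeshParams,
    build_mesh,
    cylinder_mesh,
    export_stl,
    extract_contours,
    resample_contour,
    sphere_mesh,
)
from thyromesh.phantom import Nodule


def _circle_contour(radius, n=200, z=0.0, slice_index=0, center=(0.0, 0.0)):
    ang = 2 * np.pi * np.arange(n) / n
    pts = np.stack([center[0] + radius * np.sin(ang), center[1] + radius * np.cos(ang)], axis=1)
    return Contour(slice_index, z, pts)


class TestExtractContours:
    def test_filled_square_area_via_shoelace(self):
        vox = np.zeros((1, 20, 20), dtype=np.uint8)
        vox[0, 5:15, 5:15] = 1  # 10x10 px at 1 mm spacing -> ~100 mm^2
        mask = MaskVolume(vox, 1.0, 1.0)
        contours = extract_contours(mask)
        assert len(contours) == 1
        assert contours[0].area() == pytest.approx(100.0, rel=0.05)

    def test_empty_mask_has_no_contours(self):
        assert extract_contours(MaskVolume(np.zeros((3, 8, 8), np.uint8), 1, 1)) == []

    def test_two_disjoint_blobs_two_polylines(self):
        vox = np.zeros((1, 24, 24), dtype=np.uint8)
        vox[0, 2:8, 2:8] = 1
        vox[0, 14:20, 14:20] = 1
        assert len(extract_contours(MaskVolume(vox, 1, 1))) == 2

    def test_boundary_touching_mask_still_closes(self):
        vox = np.zeros((1, 8, 8), dtype=np.uint8)
        vox[0, 0:8, 0:8] = 1  # fills the slice entirely
        contours = extract_contours(MaskVolume(vox, 1, 1))
        assert len(contours) == 1

    def test_z_uses_slice_thickness_centered(self):
        vox = np.zeros((5, 8, 8), dtype=np.uint8)
        vox[4, 2:6, 2:6] = 1
        ct = extract_contours(MaskVolume(vox, 1.0, 2.5))[0]
        assert ct.z_mm == pytest.approx((4 - 2) * 2.5)


class TestResampleContour:
    def test_circle_circumference_30_spacing_3_gives_10_nodes(self):
        circ = _circle_contour(30 / (2 * np.pi), n=500)
        nodes = resample_contour(circ.points, 3.0)
        assert len(nodes) == 10

    def test_minimum_three_nodes(self):
        circ = _circle_contour(1.0, n=100)
        nodes = resample_contour(circ.points, 1000.0)
        assert len(nodes) == 3

    def test_first_node_at_start_vertex(self):
        circ = _circle_contour(5.0)
        nodes = resample_contour(circ.points, 2.0)
        assert np.allclose(nodes[0], circ.points[0])

    def test_arc_spacing_within_10pct_on_random_smooth_contours(self, rng):
        for _ in range(20):
            # smooth star-shaped contour with random radial harmonics
            n = 400
            ang = 2 * np.pi * np.arange(n) / n
            r = 10 + 2 * np.sin(3 * ang + rng.uniform(0, np.pi)) + rng.uniform(0, 1)
            pts = np.stack([r * np.sin(ang), r * np.cos(ang)], axis=1)
            nodes = resample_contour(pts, 3.0)
            closed = np.vstack([nodes, nodes[:1]])
            gaps = np.linalg.norm(np.diff(closed, axis=0), axis=1)
            target = gaps.mean()
            assert np.all(np.abs(gaps - target) <= 0.1 * target + 1e-9)

    def test_node_count_tracks_perimeter(self):
        from hypothesis import given, settings
        import hypothesis.strategies as st

        @given(st.floats(1.0, 50.0), st.floats(0.5, 10.0))
        @settings(max_examples=50, derandomize=True)
        def check(radius, spacing):
            pts = _circle_contour(radius, n=600).points
            closed = np.vstack([pts, pts[:1]])
            perimeter = float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum())
            nodes = resample_contour(pts, spacing)
            assert len(nodes) >= 3
            assert len(nodes) == max(3, int(round(perimeter / spacing)))

        check()

    def test_degenerate_polyline_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            resample_contour(np.zeros((4, 2)), 1.0)


class TestBuildMesh:
    def test_single_ring_topology(self):
        circ = _circle_contour(30 / (2 * np.pi), n=500)
        model = build_mesh([circ], params=MeshParams(link_slices=False))
        assert len(model.spheres) == 10
        assert len(model.cylinders) == 10

    def test_two_stacked_rings_with_linking(self):
        c1 = _circle_contour(30 / (2 * np.pi), n=500, z=0.0, slice_index=0)
        c2 = _circle_contour(30 / (2 * np.pi), n=500, z=2.5, slice_index=1)
        model = build_mesh([c1, c2], params=MeshParams(link_slices=True))
        assert len(model.spheres) == 20
        assert len(model.cylinders) == 20 + 10  # ring edges + inter-slice links

    def test_ring_nodes_have_degree_two_within_ring(self):
        circ = _circle_contour(8.0, n=300)
        model = build_mesh([circ], params=MeshParams(link_slices=False))
        degree = {}
        for a, b, _, _ in model.cylinders:
            for p in (tuple(np.round(a, 6)), tuple(np.round(b, 6))):
                degree[p] = degree.get(p, 0) + 1
        assert set(degree.values()) == {2}

    def test_nodule_only_model_is_tumor_material(self):
        model = build_mesh([], [Nodule((0.0, 0.0, 0.0), 4.0)], MeshParams())
        assert model.materials() == ["tumor"]
        assert len(model.spheres) > 0

    def test_empty_input_raises(self):
        with pytest.raises(ValueError, match="at least one"):
            build_mesh([], [], MeshParams())

    def test_cylinder_endpoints_coincide_with_sphere_centers(self):
        c1 = _circle_contour(6.0, n=300, z=0.0, slice_index=0)
        c2 = _circle_contour(5.0, n=300, z=2.5, slice_index=1)
        model = build_mesh([c1, c2], [Nodule((0.0, 0.0, 0.0), 3.0)], MeshParams())
        centers = {
            m: {tuple(np.round(c, 6)) for c, _, mm in model.spheres if mm == m}
            for m in model.materials()
        }
        for a, b, _, mat in model.cylinders:
            assert tuple(np.round(a, 6)) in centers[mat]
            assert tuple(np.round(b, 6)) in centers[mat]


def _euler_characteristic(verts, faces):
    """V - E + F on the deduplicated triangle mesh."""
    key = np.round(verts, 9)
    _, inv = np.unique(key, axis=0, return_inverse=True)
    f = inv[faces]
    edges = set()
    for tri in f:
        for i in range(3):
            e = tuple(sorted((tri[i], tri[(i + 1) % 3])))
            edges.add(e)
    v = len(np.unique(f))
    return v - len(edges) + len(f)


class TestTessellation:
    @pytest.mark.parametrize("res", [6, 12, 16])
    def test_sphere_facet_count_and_closure(self, res):
        verts, faces = sphere_mesh((1.0, -2.0, 3.0), 1.2, res)
        assert len(faces) == 2 * res * (res - 1)
        assert _euler_characteristic(verts, faces) == 2

    @pytest.mark.parametrize("res", [6, 16])
    def test_cylinder_facet_count_and_closure(self, res):
        verts, faces = cylinder_mesh((0, 0, 0), (1, 2, 3), 0.8, res)
        assert len(faces) == 4 * res
        assert _euler_characteristic(verts, faces) == 2

    def test_sphere_vertices_on_surface(self):
        verts, _ = sphere_mesh((0, 0, 0), 2.0, 10)
        assert np.allclose(np.linalg.norm(verts, axis=1), 2.0)


class TestExportStl:
    def test_round_trip_matches_primitive_geometry(self, tmp_path):
        trimesh = pytest.importorskip("trimesh")
        model = build_mesh([], [Nodule((0.0, 0.0, 0.0), 4.0)], MeshParams(solid_nodules=True))
        params = MeshParams(resolution=16, solid_nodules=True)
        files = export_stl(model, params, tmp_path / "one")
        loaded = trimesh.load(files["tumor"])
        assert len(loaded.faces) == 2 * 16 * (16 - 1)
        verts, _ = sphere_mesh((0.0, 0.0, 0.0), 4.0, 16)
        want = np.unique(np.round(verts, 4), axis=0)
        got = np.unique(np.round(loaded.vertices, 4), axis=0)
        assert want.shape == got.shape
        # vertex-to-vertex agreement within 1e-4 mm
        d = np.abs(want[:, None, :] - got[None, :, :]).sum(axis=2).min(axis=1)
        assert d.max() <= 3e-4

    def test_two_material_files_written(self, tmp_path):
        circ = _circle_contour(8.0, n=300)
        model = build_mesh([circ], [Nodule((0.0, 0.0, 0.0), 3.0)], MeshParams())
        files = export_stl(model, MeshParams(), tmp_path / "thy")
        assert set(files) == {"gland", "tumor"}
        assert (tmp_path / "thy_gland.stl").exists()
        assert (tmp_path / "thy_summary.json").exists()

    def test_missing_material_warns_and_omits(self, tmp_path):
        circ = _circle_contour(8.0, n=300)
        model = build_mesh([circ], [], MeshParams())
        with pytest.warns(UserWarning, match="tumor"):
            files = export_stl(model, MeshParams(), tmp_path / "g")
        assert set(files) == {"gland"}

    def test_scaling_scales_coordinates_exactly(self, tmp_path):
        trimesh = pytest.importorskip("trimesh")
        circ = _circle_contour(8.0, n=300)
        model = build_mesh([circ], [], MeshParams())
        f1 = export_stl(model, MeshParams(scale=1.0), tmp_path / "s1")
        f2 = export_stl(model, MeshParams(scale=2.0), tmp_path / "s2")
        v1 = trimesh.load(f1["gland"]).vertices
        v2 = trimesh.load(f2["gland"]).vertices
        assert np.allclose(np.sort(v2.ravel()), np.sort(2 * v1.ravel()), atol=1e-5)

    def test_empty_model_raises(self, tmp_path):
        from thyromesh.mesh import MeshModel

        with pytest.raises(ValueError, match="empty"):
            export_stl(MeshModel(), MeshParams(), tmp_path / "x")


class TestLifeSizeFidelity:
    def test_gland_bounds_match_phantom_bounds(self, default_phantom):
        """STL-model bounding box tracks the mask's physical bounding box
        within one node spacing + sphere radius."""
        _, _, mask, _ = default_phantom
        params = MeshParams()
        contours = extract_contours(mask)
        model = build_mesh(contours, [], params)
        lo, hi = model.bounds("gland")
        occ = np.argwhere(mask.voxels)
        ns, nr, nc = mask.shape
        z = (occ[:, 0] - (ns - 1) / 2) * mask.slice_thickness_mm
        y = (occ[:, 1] - (nr - 1) / 2) * mask.pixel_spacing_mm
        x = (occ[:, 2] - (nc - 1) / 2) * mask.pixel_spacing_mm
        mask_lo = np.array([x.min(), y.min(), z.min()])
        mask_hi = np.array([x.max(), y.max(), z.max()])
        tol = params.sphere_radius_mm + max(mask.pixel_spacing_mm, mask.slice_thickness_mm)
        assert np.all(np.abs(lo - mask_lo) <= tol)
        assert np.all(np.abs(hi - mask_hi) <= tol)
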