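import numpy as np
import pytest
from conftest import brute_force_sr
from hypothesis import given, settings
from hypothesis import strategies as st

from reefrugosity.errors import (
    DegenerateGeometryError,
    ParameterError,
    UndefinedStatisticError,
)
from reefrugosity.rugosity import (
    QuadratGrid,
    ReferencePlane,
    compute_sr,
    fit_reference_plane,
    multiscale_sr,
    partition_quadrats,
    projected_face_area,
    resample_link_size,
)
from reefrugosity.surface_model import (
    HeightField,
    RigidTransform,
    SurfaceMesh,
    apply_transform,
    heightfield_to_mesh,
)
from reefrugosity.synthetic_data import SurfaceSpec, gen_surface


def flat_mesh(extent=4.0, cell=0.5):
    n = int(extent / cell) + 1
    return heightfield_to_mesh(HeightField(np.zeros((n, n)), cell_size=cell))


class TestFitReferencePlane:
    def test_horizontal_mesh(self):
        plane = fit_reference_plane(flat_mesh())
        np.testing.assert_allclose(plane.normal, [0, 0, 1], atol=1e-12)

    def test_exact_tilted_plane_recovered(self):
        # surface z = x has normal proportional to (-1, 0, 1)
        hf = HeightField(np.tile(np.arange(5.0), (5, 1)), cell_size=1.0)
        plane = fit_reference_plane(heightfield_to_mesh(hf))
        np.testing.assert_allclose(plane.normal, [-1 / np.sqrt(2), 0, 1 / np.sqrt(2)], atol=1e-9)

    def test_noisy_plane_within_half_degree(self, rng):
        n = 10_000
        xy = rng.uniform(0, 10, (n, 2))
        z = 0.2 * xy[:, 0] + 0.1 * xy[:, 1] + rng.normal(0, 0.01, n)
        mesh = SurfaceMesh(np.column_stack([xy, z]), np.empty((0, 3), dtype=int))
        plane = fit_reference_plane(mesh)
        truth = np.array([-0.2, -0.1, 1.0])
        truth /= np.linalg.norm(truth)
        angle = np.degrees(np.arccos(np.clip(abs(plane.normal @ truth), 0, 1)))
        assert angle < 0.5

    def test_collinear_vertices_raise(self):
        pts = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        mesh = SurfaceMesh(pts, np.empty((0, 3), dtype=int))
        with pytest.raises(DegenerateGeometryError):
            fit_reference_plane(mesh)

    def test_axes_orthonormal_and_x_aligned(self):
        plane = fit_reference_plane(flat_mesh())
        u, v = plane.axes
        assert abs(u @ v) < 1e-12
        assert abs(u @ plane.normal) < 1e-12
        np.testing.assert_allclose(u, [1, 0, 0], atol=1e-12)


class TestProjectedFaceArea:
    plane = ReferencePlane.from_point_normal([0, 0, 0], [0, 0, 1])

    @pytest.mark.parametrize(
        "tri,expected_frac",
        [
            ([[0, 0, 0], [1, 0, 0], [0, 1, 0]], 1.0),        # parallel
            ([[0, 0, 0], [1, 0, 0], [0, 0, 1]], 0.0),        # perpendicular
            ([[0, 0, 0], [1, 0, 0], [0, 1, np.sqrt(3)]], 0.5),  # 60 degrees
        ],
    )
    def test_cosine_projection(self, tri, expected_frac):
        tri = np.asarray(tri, dtype=float)
        area = 0.5 * np.linalg.norm(np.cross(tri[1] - tri[0], tri[2] - tri[0]))
        assert projected_face_area(tri, self.plane) == pytest.approx(
            expected_frac * area, abs=1e-12
        )

    def test_zero_area_face(self):
        tri = [[0, 0, 0], [1, 1, 1], [2, 2, 2]]
        assert projected_face_area(tri, self.plane) == 0.0


class TestPartitionQuadrats:
    def test_four_quadrats_full(self):
        mesh = flat_mesh(extent=4.0, cell=0.5)
        plane = ReferencePlane.from_point_normal([0, 0, 0], [0, 0, 1])
        grid = QuadratGrid((0.0, 0.0), 2, 2, 2.0)
        part = partition_quadrats(mesh, plane, grid)
        qids = part["quadrat_id"].to_numpy()
        assert set(qids) == {0, 1, 2, 3}
        areas = {
            q: mesh.face_areas()[qids == q].sum() for q in range(4)
        }
        for q in range(4):
            assert areas[q] == pytest.approx(4.0, abs=1e-9)
            assert part.attrs["excluded"][q] is False

    def test_boundary_tie_goes_to_lower_quadrat(self):
        grid = QuadratGrid((0.0, 0.0), 1, 2, 2.0)
        # centroid exactly on the internal boundary u = 2
        assert grid.locate([[2.0, 1.0]])[0] == 0
        assert grid.locate([[2.0 + 1e-9, 1.0]])[0] == 1

    def test_circular_site_rim_quadrats_excluded(self):
        # 12 m circular plot on a 2 m grid: corner quadrats of the bounding
        # square overlap the circle by less than half and must be flagged
        cell = 0.1
        n = int(12 / cell) + 1
        x = np.arange(n) * cell
        xx, yy = np.meshgrid(x, x)
        inside = (xx - 6.0) ** 2 + (yy - 6.0) ** 2 <= 6.0**2
        z = np.where(inside, 0.0, np.nan)
        mesh = heightfield_to_mesh(HeightField(z, cell_size=cell))
        plane = ReferencePlane.from_point_normal([0, 0, 0], [0, 0, 1])
        grid = QuadratGrid((0.0, 0.0), 6, 6, 2.0)
        part = partition_quadrats(mesh, plane, grid, min_fill=0.5)
        excluded = part.attrs["excluded"]
        # analytic circle-square overlap: corner quadrat [0,2]x[0,2] overlaps
        # the r=6 circle centred at (6,6) on ~0.63 m^2 < 2 m^2 -> excluded
        assert excluded[0] is True
        # central quadrat fully inside
        assert excluded[grid.quadrat_id(2, 2)] is False


class TestComputeSR:
    def test_flat_quadrat_is_one(self):
        mesh = flat_mesh()
        plane = fit_reference_plane(mesh)
        assert compute_sr(mesh, plane).sr == pytest.approx(1.0, abs=1e-12)

    def test_sawtooth_closed_form_and_oracle(self):
        hf, true_sr = gen_surface(
            SurfaceSpec("sawtooth", extent=2.0, cell_size=0.05, slope=1.0, wavelength=0.1)
        )
        mesh = heightfield_to_mesh(hf)
        plane = ReferencePlane.from_point_normal([0, 0, 0], [0, 0, 1])
        qr = compute_sr(mesh, plane)
        assert qr.sr == pytest.approx(np.sqrt(2.0), rel=1e-9)
        total, proj = brute_force_sr(mesh, [0, 0, 1])
        assert qr.sr == pytest.approx(total / proj, rel=1e-12)

    def test_hemisphere_closed_form(self):
        # hemisphere r=0.5 on a flat 2x2 quadrat: SR = (4 + pi r^2) / 4
        r, cell = 0.5, 0.005
        n = int(2.0 / cell) + 1
        x = np.arange(n) * cell
        xx, yy = np.meshgrid(x, x)
        d2 = (xx - 1.0) ** 2 + (yy - 1.0) ** 2
        z = np.sqrt(np.maximum(r**2 - d2, 0.0))
        mesh = heightfield_to_mesh(HeightField(z, cell_size=cell))
        plane = ReferencePlane.from_point_normal([0, 0, 0], [0, 0, 1])
        expected = (4.0 + np.pi * r**2) / 4.0
        assert compute_sr(mesh, plane).sr == pytest.approx(expected, rel=2e-3)

    def test_vertical_faces_raise(self):
        mesh = SurfaceMesh(
            [[0, 0, 0], [1, 0, 0], [0, 0, 1]], [[0, 1, 2]]
        )
        plane = ReferencePlane.from_point_normal([0, 0, 0], [0, 0, 1])
        with pytest.raises(UndefinedStatisticError):
            compute_sr(mesh, plane)

    def test_sr_total_projected_consistency(self, rng):
        hf = HeightField(rng.normal(0, 0.1, (15, 15)), cell_size=0.2)
        mesh = heightfield_to_mesh(hf)
        plane = fit_reference_plane(mesh)
        qr = compute_sr(mesh, plane)
        assert qr.sr * qr.projected_area == pytest.approx(qr.total_area, rel=1e-12)
        assert qr.sr >= 1.0


class TestRigidInvariance:
    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(0, 10_000))
    def test_sr_invariant_under_rigid_transform(self, seed):
        rng = np.random.default_rng(seed)
        hf = HeightField(rng.normal(0, 0.2, (10, 10)), cell_size=0.5)
        mesh = heightfield_to_mesh(hf)
        sr0 = compute_sr(mesh, fit_reference_plane(mesh)).sr
        angles = rng.uniform(0, 2 * np.pi, 3)

        def rot(axis, a):
            c, s = np.cos(a), np.sin(a)
            m = np.eye(3)
            i, j = [(1, 2), (0, 2), (0, 1)][axis]
            m[i, i] = c; m[j, j] = c; m[i, j] = -s; m[j, i] = s
            return m

        r = rot(0, angles[0]) @ rot(1, angles[1] * 0.2) @ rot(2, angles[2])
        moved = apply_transform(mesh, RigidTransform(r, rng.normal(0, 5, 3)))
        sr1 = compute_sr(moved, fit_reference_plane(moved)).sr
        assert sr1 == pytest.approx(sr0, rel=1e-9)


class TestResampleLinkSize:
    def test_native_resolution_identity(self, rng):
        hf = HeightField(rng.normal(0, 0.1, (9, 9)), cell_size=0.025)
        out = resample_link_size(hf, 0.025)
        np.testing.assert_array_equal(out.elevations, hf.elevations)

    def test_flat_field_stays_flat(self):
        hf = HeightField(np.zeros((41, 41)), cell_size=0.025)
        out = resample_link_size(hf, 0.1)
        assert np.nanstd(out.elevations) == 0.0
        mesh = heightfield_to_mesh(out)
        plane = ReferencePlane.from_point_normal([0, 0, 0], [0, 0, 1])
        assert compute_sr(mesh, plane).sr == pytest.approx(1.0, abs=1e-12)

    def test_below_native_raises(self):
        hf = HeightField(np.zeros((4, 4)), cell_size=0.05)
        with pytest.raises(ParameterError):
            resample_link_size(hf, 0.025)

    def test_sinusoid_sr_decreases_with_link_size(self):
        hf, _ = gen_surface(
            SurfaceSpec("sinusoid", extent=4.0, cell_size=0.025,
                        amplitude=0.10, wavelength=0.5)
        )
        plane = ReferencePlane.from_point_normal([0, 0, 0], [0, 0, 1])
        srs = []
        for link in (0.025, 0.05, 0.10, 0.15, 0.20, 0.25):
            mesh = heightfield_to_mesh(resample_link_size(hf, link))
            srs.append(compute_sr(mesh, plane).sr)
        assert all(a > b for a, b in zip(srs, srs[1:]))
        assert srs[0] > 1.05  # the fine scale actually sees the relief


class TestMultiscaleSR:
    def test_flat_site_all_ones(self):
        hf = HeightField(np.zeros((161, 161)), cell_size=0.025)
        table = multiscale_sr(hf, link_sizes=(0.025, 0.1, 0.25))
        assert len(table) > 0
        np.testing.assert_allclose(table["SR"], 1.0, atol=1e-9)

    def test_tilted_plane_decoupled_from_slope(self):
        hf, _ = gen_surface(
            SurfaceSpec("tilted_plane", extent=4.0, cell_size=0.025, slope=0.4)
        )
        table = multiscale_sr(hf, link_sizes=(0.025, 0.1, 0.25))
        np.testing.assert_allclose(table["SR"], 1.0, atol=1e-9)

    def test_single_quadrat_matches_direct_compute(self):
        hf, _ = gen_surface(
            SurfaceSpec("sinusoid", extent=2.0, cell_size=0.025,
                        amplitude=0.05, wavelength=0.4)
        )
        plane = ReferencePlane.from_point_normal([0, 0, 0], [0, 0, 1])
        grid = QuadratGrid((0.0, 0.0), 1, 1, 2.0)
        table = multiscale_sr(hf, plane=plane, grid=grid, link_sizes=(0.025,))
        mesh = heightfield_to_mesh(hf)
        direct = compute_sr(mesh, plane)
        assert len(table) == 1
        assert table["SR"].iloc[0] == pytest.approx(direct.sr, rel=1e-9)
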