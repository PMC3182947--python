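import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from lvgpm.errors import DegenerateGeometryError, GeometryError
from lvgpm.geometry import (LVSurfaceModel, MitralValvePlane, SlicePlane,
                            ellipsoid_model, enclosed_volume, fit_plane,
                            intersect_surface_with_plane,
                            truncated_ellipsoid_volume, voxelized_volume)


def base_plane(z, toward_apex=(0, 0, -1.0)):
    return MitralValvePlane(origin=np.array([0.0, 0.0, z]),
                            normal=np.asarray(toward_apex, dtype=float),
                            source_points=np.zeros((0, 3)))


def polygon_area(uv):
    x, y = uv[:, 0], uv[:, 1]
    return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


# ---------------------------------------------------------------------------
# fit_plane
# ---------------------------------------------------------------------------

class TestFitPlane:
    def test_exact_coplanar(self):
        mv = fit_plane([[0, 0, 2], [3, 0, 2], [0, 4, 2], [1, 1, 2]])
        assert abs(abs(mv.normal[2]) - 1.0) < 1e-12
        assert mv.rms_residual < 1e-12

    def test_symmetric_perturbation(self):
        eps = 1e-6
        pts = [[1, 0, eps], [-1, 0, eps], [0, 1, -eps], [0, -1, -eps]]
        mv = fit_plane(pts)
        assert np.linalg.norm(mv.origin) < 1e-12
        assert mv.rms_residual < 2 * eps

    def test_matches_brute_force_grid(self):
        """TLS residual equals a (refined) spherical-grid minimum."""
        rng = np.random.default_rng(42)
        pts = rng.normal(size=(4, 3))
        mv = fit_plane(pts)
        centroid = pts.mean(axis=0)
        rel = pts - centroid

        def grid_min(th_grid, ph_grid):
            TH, PH = np.meshgrid(th_grid, ph_grid, indexing="ij")
            n = np.stack([np.sin(TH) * np.cos(PH), np.sin(TH) * np.sin(PH),
                          np.cos(TH)], axis=-1)
            res = np.sum((rel @ n.reshape(-1, 3).T) ** 2, axis=0)
            i = int(np.argmin(res))
            return res[i], TH.ravel()[i], PH.ravel()[i]

        step = np.deg2rad(1.0)
        r0, th0, ph0 = grid_min(np.arange(0, np.pi, step),
                                np.arange(0, 2 * np.pi, step))
        # refine around the coarse optimum
        fine = np.deg2rad(0.002)
        r1, _, _ = grid_min(th0 + np.linspace(-step, step, 201),
                            ph0 + np.linspace(-step, step, 201))
        svd_res = np.sum((rel @ mv.normal) ** 2)
        assert svd_res <= r1 + 1e-12
        assert abs(svd_res - r1) <= 1e-6 * max(svd_res, 1e-12) + 1e-9

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateGeometryError, match="collinear"):
            fit_plane([[0, 0, 0], [1, 1, 1], [2, 2, 2], [3, 3, 3]])
        with pytest.raises(DegenerateGeometryError, match="distinct"):
            fit_plane([[0, 0, 0], [0, 0, 0], [1, 0, 0], [1, 0, 0]])
        # 2 coincident of 4 leaves 3 distinct points: still fits
        mv = fit_plane([[0, 0, 1], [0, 0, 1], [1, 0, 1], [0, 1, 1]])
        assert mv.rms_residual < 1e-12

    def test_rigid_equivariance(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(5, 3))
        mv = fit_plane(pts)
        R = Rotation.from_rotvec([0.3, -0.5, 0.9]).as_matrix()
        t = np.array([2.0, -1.0, 4.0])
        mv2 = fit_plane(pts @ R.T + t)
        assert np.allclose(mv2.origin, R @ mv.origin + t, atol=1e-9)
        assert min(np.linalg.norm(mv2.normal - R @ mv.normal),
                   np.linalg.norm(mv2.normal + R @ mv.normal)) < 1e-9


# ---------------------------------------------------------------------------
# surface evaluation
# ---------------------------------------------------------------------------

class TestSurfacePoint:
    def test_sphere_constant_radius(self):
        m = ellipsoid_model(2.0, 2.0, 2.0)
        mu = np.linspace(0.05, 0.95, 11)
        th = np.linspace(0, 2 * np.pi, 11)
        pts = m.surface_point("endo", mu, th)
        assert np.allclose(np.linalg.norm(pts, axis=1), 2.0, atol=1e-9)

    def test_ellipsoid_equator_on_u_axis(self):
        m = ellipsoid_model(2.5, 2.5, 4.5)
        p = m.surface_point("endo", 0.5, 0.0)
        assert np.allclose(p, [2.5, 0.0, 0.0], atol=1e-9)

    def test_smoothness_bounded_second_derivatives(self):
        m = ellipsoid_model(2.5, 2.5, 4.5)
        h = 1e-4
        mu, th = 0.37, 1.2
        f = [m.surface_point("endo", mu + k * h, th) for k in (-1, 0, 1)]
        d2 = (f[0] - 2 * f[1] + f[2]) / h ** 2
        assert np.all(np.abs(d2) < 1e3)

    def test_domain_error(self):
        m = ellipsoid_model(2.0, 2.0, 2.0)
        with pytest.raises(ValueError, match="mu"):
            m.surface_point("endo", 1.4, 0.0)

    def test_stretched_roundtrip(self):
        m = ellipsoid_model(1.9, 1.9, 4.2, center=(1.0, -2.0, 0.5))
        mu = np.linspace(0.1, 0.9, 7)
        th = np.linspace(0.3, 5.9, 7)
        pts = m.surface_point("endo", mu, th)
        mu2, th2, r2 = m.to_stretched(pts)
        lam = m.radial_field("endo", mu2, th2)
        assert np.allclose(mu2, mu, atol=1e-9)
        assert np.allclose(th2, th, atol=1e-9)
        assert np.allclose(r2, lam, atol=1e-9)


# ---------------------------------------------------------------------------
# enclosed volume
# ---------------------------------------------------------------------------

class TestEnclosedVolume:
    def test_hemisphere(self):
        m = ellipsoid_model(2.0, 2.0, 2.0)
        v = enclosed_volume(m, "endo", base_plane(0.0))
        assert v == pytest.approx(2.0 / 3.0 * np.pi * 8.0, rel=1e-6)

    @pytest.mark.parametrize("h", [-1.0, 0.0, 1.5, 3.0])
    def test_truncated_ellipsoid_closed_form(self, h):
        a, b, c = 2.5, 2.5, 4.5
        m = ellipsoid_model(a, b, c)
        v = enclosed_volume(m, "endo", base_plane(h), quadrature_order=8)
        assert v == pytest.approx(truncated_ellipsoid_volume(a, b, c, h),
                                  rel=1e-4)

    def test_voxel_oracle_cross_check(self):
        a, b, c, h = 2.5, 2.5, 4.5, 1.5
        m = ellipsoid_model(a, b, c)
        v = voxelized_volume(m, "endo", base_plane(h), voxel_mm=0.05)
        assert v == pytest.approx(truncated_ellipsoid_volume(a, b, c, h),
                                  rel=5e-3)

    def test_wall_shell_difference(self):
        """1 mm-wall ellipsoid shell volume vs difference of closed forms."""
        a, b, c, h, w = 2.5, 2.5, 4.5, 1.5, 1.0
        m = ellipsoid_model(a, b, c, wall=w)
        shell = (enclosed_volume(m, "epi", base_plane(h))
                 - enclosed_volume(m, "endo", base_plane(h)))
        expected = (truncated_ellipsoid_volume(a + w, b + w, c + w, h)
                    - truncated_ellipsoid_volume(a, b, c, h))
        assert shell == pytest.approx(expected, rel=1e-3)

    def test_quadrature_convergence(self):
        m = ellipsoid_model(2.5, 2.5, 4.5)
        ref = truncated_ellipsoid_volume(2.5, 2.5, 4.5, 1.5)
        errs = [abs(enclosed_volume(m, "endo", base_plane(1.5), q) - ref)
                for q in (2, 4, 8)]
        assert errs[1] < errs[0] and errs[2] <= errs[1] + 1e-10

    def test_scaling_cubes_volume(self):
        m = ellipsoid_model(2.0, 2.0, 3.6)
        v1 = enclosed_volume(m, "endo", base_plane(1.0))
        s = 1.7
        m2 = m.scaled(s)
        v2 = enclosed_volume(m2, "endo", base_plane(s * 1.0))
        assert v2 == pytest.approx(s ** 3 * v1, rel=1e-6)

    def test_plane_missing_surface_errors(self):
        m = ellipsoid_model(2.0, 2.0, 2.0)
        with pytest.raises(GeometryError):
            enclosed_volume(m, "endo", base_plane(5.0))

    def test_epi_field_dominates_endo_on_random_models(self):
        """Coefficient-wise epi >= endo implies the field inequality."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            ce = rng.uniform(1.0, 3.0, (4, 8))
            cp = ce + rng.uniform(0.1, 1.0, (4, 8))
            ce[0, :], ce[-1, :] = ce[0, 0], ce[-1, 0]
            cp[0, :], cp[-1, :] = cp[0, 0], cp[-1, 0]
            m = LVSurfaceModel(axis_origin=np.zeros(3),
                               axis_direction=np.array([0, 0, -1.0]),
                               transverse_u=np.array([1.0, 0, 0]),
                               transverse_v=np.array([0, -1.0, 0]),
                               elongation=rng.uniform(1.2, 2.2),
                               coeffs_endo=ce, coeffs_epi=cp,
                               basis_order=(4, 8))
            m.check_valid()

    def test_epi_volume_exceeds_endo_volume(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            ce = rng.uniform(1.5, 2.5, (4, 8))
            ce[0, :], ce[-1, :] = ce[0, 0], ce[-1, 0]
            cp = ce + 0.5
            m = LVSurfaceModel(axis_origin=np.zeros(3),
                               axis_direction=np.array([0, 0, -1.0]),
                               transverse_u=np.array([1.0, 0, 0]),
                               transverse_v=np.array([0, -1.0, 0]),
                               elongation=1.8, coeffs_endo=ce,
                               coeffs_epi=cp, basis_order=(4, 8))
            b = base_plane(0.5)
            assert enclosed_volume(m, "epi", b) > enclosed_volume(m, "endo", b)


# ---------------------------------------------------------------------------
# surface/plane intersection
# ---------------------------------------------------------------------------

def sax_plane(z, label="SAX", idx=1):
    return SlicePlane(origin=np.array([0.0, 0.0, z]),
                      normal=np.array([0.0, 0.0, 1.0]),
                      axis_u=np.array([1.0, 0.0, 0.0]),
                      axis_v=np.array([0.0, 1.0, 0.0]),
                      slice_label=label, sax_index=idx)


class TestIntersection:
    def test_sphere_center_cut_is_circle(self):
        m = ellipsoid_model(2.0, 2.0, 2.0)
        areas = []
        for n in (50, 200, 800):
            ct = intersect_surface_with_plane(m, "endo", sax_plane(0.0), n)
            r = np.linalg.norm(ct.uv, axis=1)
            assert np.allclose(r, 2.0, atol=1e-9)
            areas.append(polygon_area(ct.uv))
        errs = np.abs(np.array(areas) - 4 * np.pi)
        assert errs[2] < errs[1] < errs[0]
        assert errs[2] < 1e-3

    def test_points_on_surface_and_in_plane(self):
        m = ellipsoid_model(2.5, 2.5, 4.5)
        ct = intersect_surface_with_plane(m, "endo", sax_plane(1.2), 100)
        mu, th, r = m.to_stretched(ct.xyz)
        lam = m.radial_field("endo", mu, th)
        assert np.max(np.abs(r - lam)) < 1e-6
        assert np.max(np.abs(ct.xyz[:, 2] - 1.2)) < 1e-9
        # counter-clockwise in (u, v)
        x, y = ct.uv[:, 0], ct.uv[:, 1]
        assert np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y) > 0

    def test_tangent_plane_degenerate(self):
        m = ellipsoid_model(2.0, 2.0, 2.0)
        ct = intersect_surface_with_plane(m, "endo", sax_plane(2.0 + 1e-9))
        assert ct.degenerate
        assert ct.is_empty

    def test_missing_plane_empty_not_exception(self):
        m = ellipsoid_model(2.0, 2.0, 2.0)
        ct = intersect_surface_with_plane(m, "endo", sax_plane(5.0))
        assert ct.is_empty and ct.degenerate

    def test_oblique_cut_matches_conic_area(self):
        """Central oblique section area: pi*a*b*c / sqrt(a^2nx^2+...)."""
        a, b, c = 2.5, 2.5, 4.5
        m = ellipsoid_model(a, b, c)
        ang = np.deg2rad(30)
        n = np.array([0.0, np.sin(ang), np.cos(ang)])
        u = np.array([1.0, 0.0, 0.0])
        pl = SlicePlane(origin=np.zeros(3), normal=n, axis_u=u,
                        axis_v=np.cross(n, u), slice_label="SAX")
        ct = intersect_surface_with_plane(m, "endo", pl, 200)
        expected = np.pi * a * b * c / np.sqrt(
            (a * n[0]) ** 2 + (b * n[1]) ** 2 + (c * n[2]) ** 2)
        assert polygon_area(ct.uv) == pytest.approx(expected, rel=5e-3)

    def test_long_axis_plane_meridian_contour(self):
        a, c = 2.5, 4.5
        m = ellipsoid_model(a, a, c)
        axis = np.array([0.0, 0.0, -1.0])
        pl = SlicePlane(origin=np.zeros(3), normal=np.array([0, 1.0, 0]),
                        axis_u=axis, axis_v=np.array([1.0, 0, 0]),
                        slice_label="LAX_2CH")
        ct = intersect_surface_with_plane(m, "endo", pl, 200)
        assert np.max(np.abs(ct.xyz[:, 1])) < 1e-9
        assert polygon_area(ct.uv) == pytest.approx(np.pi * a * c, rel=2e-3)

    def test_side_cut_level_set_path(self):
        """A plane clipping only a local bulge yields a closed loop."""
        from lvgpm._basis import TensorSplineBasis

        basis = TensorSplineBasis(12, 16)

        def lam(mu, th):
            bump = np.exp(-((mu - 0.4) / 0.1) ** 2
                          - (np.mod(th - 1.0 + np.pi, 2 * np.pi)
                             - np.pi) ** 2 / 0.3 ** 2)
            return 2.0 + 1.2 * bump

        ce = basis.interpolate(lam)
        m = LVSurfaceModel(axis_origin=np.zeros(3),
                           axis_direction=np.array([0, 0, -1.0]),
                           transverse_u=np.array([1.0, 0, 0]),
                           transverse_v=np.array([0, -1.0, 0]),
                           elongation=1.0, coeffs_endo=ce, coeffs_epi=ce,
                           basis_order=(12, 16))
        # plane just outside the base sphere, cutting only the bump
        n = np.array([np.cos(1.0), -np.sin(1.0), 0.0])
        u = np.array([0.0, 0.0, 1.0])
        pl = SlicePlane(origin=2.35 * n, normal=n, axis_u=u,
                        axis_v=np.cross(n, u), slice_label="SAX")
        ct = intersect_surface_with_plane(m, "endo", pl, 200)
        assert len(ct) > 10
        mu, th, r = m.to_stretched(ct.xyz)
        assert np.max(np.abs(r - m.radial_field("endo", mu, th))) < 1e-6
        assert np.max(np.abs((ct.xyz - pl.origin) @ n)) < 1e-8
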