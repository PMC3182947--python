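import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from lvgpm.errors import UnderdeterminedFitError
from lvgpm.geometry import SlicePlane, ellipsoid_model, enclosed_volume
from lvgpm.gpm_fitter import (FitConfig, FitDiagnostics, GuidePointSet,
                              build_initial_model, contours_to_guidepoints,
                              fit_surfaces, gpm_function)
from lvgpm.phantom import MitralValvePlane


@pytest.fixture(scope="module")
def fitted_control(control_study):
    """Full-slice fit of the noise-free control study (shared, expensive)."""
    # request the session fixture through the module fixture's signature
    init = build_initial_model(control_study)
    gps = contours_to_guidepoints(control_study)
    diag = FitDiagnostics()
    models = fit_surfaces(gps, init, FitConfig(), diag)
    return init, gps, models, diag


class TestGuidePoints:
    def test_identity_plane_mapping(self):
        pl = SlicePlane(origin=np.zeros(3), normal=np.array([0, 0, 1.0]),
                        axis_u=np.array([1.0, 0, 0]),
                        axis_v=np.array([0, 1.0, 0]))
        assert np.allclose(pl.to_3d([[1.0, 2.0]]), [[1.0, 2.0, 0.0]])

    def test_plane_roundtrip_identity(self):
        rng = np.random.default_rng(2)
        n = rng.normal(size=3)
        n /= np.linalg.norm(n)
        u = np.cross(n, [0, 0, 1.0])
        u /= np.linalg.norm(u)
        pl = SlicePlane(origin=rng.normal(size=3), normal=n, axis_u=u,
                        axis_v=np.cross(n, u))
        uv = rng.normal(size=(10, 2))
        assert np.allclose(pl.to_plane_coords(pl.to_3d(uv)), uv, atol=1e-12)

    def test_point_count_matches_study_contents(self, control_study):
        """Counting oracle: all contour points minus LAX points above MV."""
        gps = contours_to_guidepoints(control_study)
        from lvgpm.geometry import fit_plane
        sax_apex = control_study.sax_slices()[-1].plane.origin
        expected = 0
        for s in control_study.slices:
            for f in range(control_study.n_frames):
                for contour in (s.endo[f], s.epi[f]):
                    if s.label == "SAX":
                        expected += len(contour)
                    elif len(contour):
                        mvp = fit_plane(control_study.mv_points[f],
                                        orient_toward=sax_apex)
                        xyz = s.plane.to_3d(contour)
                        expected += int(
                            (mvp.signed_distance(xyz) >= 0).sum())
        assert len(gps.points) == expected

    def test_unknown_slice_id_errors(self, control_study):
        from lvgpm.errors import ConfigurationError
        with pytest.raises(ConfigurationError):
            contours_to_guidepoints(control_study, included_slices=[99])


class TestFitSurfaces:
    def test_self_consistency_in_span(self):
        """Noise-free data from an in-span model is recovered."""
        rng = np.random.default_rng(0)
        truth = ellipsoid_model(2.0, 2.0, 3.8, basis_order=(6, 12), wall=1.0)
        mu = rng.uniform(0.03, 0.8, 900)
        th = rng.uniform(0, 2 * np.pi, 900)
        pts = np.vstack([truth.surface_point("endo", mu, th),
                         truth.surface_point("epi", mu, th)])
        gps = GuidePointSet(points=pts,
                            surface=np.r_[np.zeros(900), np.ones(900)
                                          ].astype(int),
                            frame=np.zeros(1800, dtype=int),
                            weight=np.ones(1800),
                            source_slice=["synth"] * 1800)
        cfg = FitConfig(smoothing_weights=(1e-8, 1e-8))
        fit = fit_surfaces(gps, truth, cfg)[0]
        M, T = np.meshgrid(np.linspace(0.02, 0.8, 40),
                           np.linspace(0, 2 * np.pi, 40), indexing="ij")
        for surf in ("endo", "epi"):
            err = np.abs(fit.radial_field(surf, M, T)
                         - truth.radial_field(surf, M, T))
            assert err.max() < 1e-3
        base = MitralValvePlane(origin=np.array([0, 0, 1.8]),
                                normal=np.array([0, 0, -1.0]),
                                source_points=np.zeros((0, 3)))
        assert enclosed_volume(fit, "endo", base) == pytest.approx(
            enclosed_volume(truth, "endo", base), rel=1e-3)

    def test_objective_non_increasing(self):
        """Across outer iterations the penalized objective never rises."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            truth = ellipsoid_model(2.0, 2.0, 3.6, basis_order=(6, 12),
                                    wall=0.9)
            n = 300
            mu = rng.uniform(0.05, 0.8, n)
            th = rng.uniform(0, 2 * np.pi, n)
            pts = truth.surface_point("endo", mu, th) \
                + rng.normal(0, 0.05, (n, 3))
            gps = GuidePointSet(points=np.vstack([pts, pts * 1.3]),
                                surface=np.r_[np.zeros(n),
                                              np.ones(n)].astype(int),
                                frame=np.zeros(2 * n, dtype=int),
                                weight=np.ones(2 * n),
                                source_slice=["s"] * (2 * n))
            diag = FitDiagnostics()
            fit_surfaces(gps, truth, FitConfig(), diag)
            for trace in diag.objective_traces:
                assert all(b <= a + 1e-9 * max(abs(a), 1.0)
                           for a, b in zip(trace, trace[1:]))

    def test_strong_smoothing_flattens_field(self):
        """Very large curvature penalty shrinks the radial variance of a
        regionally bumpy surface fitted from a spherical start."""
        rng = np.random.default_rng(4)
        sphere = ellipsoid_model(2.0, 2.0, 2.0, basis_order=(6, 12))
        n = 600
        mu = rng.uniform(0.05, 0.8, n)
        th = rng.uniform(0, 2 * np.pi, n)
        bump = 1.0 * np.exp(-((mu - 0.4) / 0.15) ** 2
                            - ((np.mod(th - 1.0 + np.pi, 2 * np.pi)
                                - np.pi) / 0.5) ** 2)
        d, _, _ = sphere.direction_field(mu, th)
        pts = sphere.axis_origin + (2.0 + bump)[:, None] * d
        gps = GuidePointSet(points=np.vstack([pts, pts * 1.2]),
                            surface=np.r_[np.zeros(n),
                                          np.ones(n)].astype(int),
                            frame=np.zeros(2 * n, dtype=int),
                            weight=np.ones(2 * n),
                            source_slice=["s"] * (2 * n))
        M, T = np.meshgrid(np.linspace(0.05, 0.8, 30),
                           np.linspace(0, 2 * np.pi, 30), indexing="ij")
        variances = []
        for a2 in (0.005, 1e5):
            m = fit_surfaces(gps, sphere, FitConfig(
                smoothing_weights=(0.005, a2)))[0]
            variances.append(np.var(m.radial_field("endo", M, T)))
        assert variances[1] < variances[0]

    def test_missing_surface_data_errors_with_frame(self):
        truth = ellipsoid_model(2.0, 2.0, 3.6, basis_order=(6, 12))
        pts = truth.surface_point("endo", np.full(50, 0.4),
                                  np.linspace(0, 6, 50))
        gps = GuidePointSet(points=pts, surface=np.zeros(50, dtype=int),
                            frame=np.full(50, 3), weight=np.ones(50),
                            source_slice=["s"] * 50)
        with pytest.raises(UnderdeterminedFitError, match="frame 3"):
            fit_surfaces(gps, truth, FitConfig())


class TestGpmFunction:
    def test_truth_models_pass_through(self, control_truth, control_study):
        """Truth surfaces piped through reporting reproduce the truth."""
        rep = gpm_function(control_truth.frames, control_study,
                           method_label="truth", mass_frames="edes")
        assert rep.edv_ul == pytest.approx(control_truth.true_edv, rel=2e-3)
        assert rep.esv_ul == pytest.approx(control_truth.true_esv, rel=2e-3)
        assert rep.lvm_mg == pytest.approx(control_truth.true_mass, rel=5e-3)

    def test_full_slice_fit_recovers_truth(self, control_truth,
                                           fitted_control, control_study):
        _, _, models, diag = fitted_control
        rep = gpm_function(models, control_study, method_label="gpm_full")
        assert rep.edv_ul == pytest.approx(control_truth.true_edv, rel=0.03)
        assert rep.ef_fraction == pytest.approx(control_truth.true_ef,
                                                abs=0.04)
        assert max(diag.residual_rms_mm) < 0.1

    def test_rotation_equivariance(self, control_study):
        """Rigidly moving the study leaves fitted volumes unchanged."""
        R = Rotation.from_rotvec([0.4, -0.2, 0.7]).as_matrix()
        t = np.array([5.0, -3.0, 2.0])
        moved = control_study.transformed(R, t)
        vols = []
        for st in (control_study, moved):
            init = build_initial_model(st)
            gps = contours_to_guidepoints(st)
            sel = gps.frame == 0
            gps0 = GuidePointSet(points=gps.points[sel],
                                 surface=gps.surface[sel],
                                 frame=gps.frame[sel],
                                 weight=gps.weight[sel],
                                 source_slice=["s"] * int(sel.sum()))
            m = fit_surfaces(gps0, init, FitConfig())[0]
            from lvgpm.geometry import fit_plane
            apex = m.axis_origin + 10 * m.axis_direction
            mvp = fit_plane(st.mv_points[0], orient_toward=apex)
            vols.append(enclosed_volume(m, "endo", mvp))
        assert vols[1] == pytest.approx(vols[0], rel=1e-6)
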