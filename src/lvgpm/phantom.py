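"""Parametric beating mouse-LV phantoms with analytic ground truth.

The phantom is a truncated-ellipsoid left ventricle (apex closed, cavity
truncated basally by a fixed mitral-valve plane) that contracts over the
cycle with a raised-cosine time course. Contraction reduces the endocardial
short semi-axes by ``contraction_fraction`` at end-systole with a modest
accompanying long-axis shortening (0.4 x the short-axis fraction, the
typical longitudinal/radial ratio of a healthy ventricle). The epicardium
follows the endocardium so that local wall volume is conserved ray-by-ray:
the closed-shell myocardial volume is frame-invariant, while the portion
below the fixed valve plane varies a few percent over the cycle (wall
material crosses the plane), which is why mass averages ED and ES.

An optional infarct remodels the wall inside a smooth raised-cosine
(mu, theta) window: radial bulge (cavity dilation), wall thinning, and —
when ``akinetic`` — frozen endocardial motion, emulating a chronic
left-coronary-artery-territory infarct.

Default preset geometries are sized from the truncated-ellipsoid closed
form to the group means reported for C57Bl/6 mice: control EDV ~64 ul,
mass ~105 mg, EF ~63%; infarcted EDV ~162 ul, mass ~113 mg, EF ~20% with
an akinetic area of 35-48% of the myocardium.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.optimize import brentq

from ._basis import TensorSplineBasis
from .errors import ConfigurationError, GeometryError
from .geometry import (LVSurfaceModel, MitralValvePlane, SlicePlane,
                       enclosed_volume, intersect_surface_with_plane)
from .study import LAX_2CH, LAX_4CH, SAX, CineStudy, StudySlice

MYOCARDIAL_DENSITY_MG_PER_UL = 1.05
LONG_AXIS_SHORTENING_RATIO = 0.4    # long-axis fraction per unit short-axis
TRUTH_BASIS_ORDER = (32, 48)
AKINESIA_THRESHOLD_MM = 0.1


class InfarctSpec(BaseModel):
    model_config = ConfigDict(frozen=True)

    center_theta: float = 0.0
    center_mu: float = Field(0.40, gt=0.0, lt=1.0)
    angular_halfwidth: float = Field(..., gt=0.0, lt=np.pi)
    mu_halfwidth: float = Field(..., gt=0.0, lt=0.5)
    wall_thinning_fraction: float = Field(0.5, ge=0.0, lt=1.0)
    bulge_mm: float = Field(0.0, ge=0.0)
    akinetic: bool = True

    @model_validator(mode="after")
    def _inside_domain(self):
        if not (self.mu_halfwidth < self.center_mu
                and self.center_mu + self.mu_halfwidth < 1.0):
            raise ValueError("infarct mu window must lie strictly inside "
                             "(0, 1): fields center_mu, mu_halfwidth")
        return self


class PhantomSpec(BaseModel):
    model_config = ConfigDict(frozen=True)

    endo_semi_axes_ed: tuple[float, float, float]
    wall_thickness_ed: float = Field(..., gt=0.0)
    base_truncation_fraction: float = Field(0.55, gt=0.0, lt=1.0)
    n_frames: int = Field(20, ge=2)
    contraction_fraction: float = Field(..., gt=0.0, lt=1.0)
    infarct: Optional[InfarctSpec] = None
    noise_sd_mm: float = Field(0.0, ge=0.0)
    rng_seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if min(self.endo_semi_axes_ed) <= 0:
            raise ValueError("all semi-axes must be positive: "
                             "field endo_semi_axes_ed")
        if self.infarct is not None:
            residual = self.wall_thickness_ed * \
                (1.0 - self.infarct.wall_thinning_fraction)
            if residual <= 0.05:
                raise ValueError("wall thickness after thinning must exceed "
                                 "0.05 mm: fields wall_thickness_ed, "
                                 "infarct.wall_thinning_fraction")
            if self.infarct.center_mu + self.infarct.mu_halfwidth > \
                    self.basal_mu_limit():
                raise ValueError(
                    "infarct window reaches the basal truncation plane; the "
                    "scar must stay apical of the mitral-valve plane: fields "
                    "infarct.center_mu, infarct.mu_halfwidth, "
                    "base_truncation_fraction")
        return self

    def basal_mu_limit(self) -> float:
        """Most basal mu the infarct window may reach.

        On a bulged meridian the basal plane cuts at
        cos(phi) = -btf * a / (a + bulge); the window must end a margin
        below that so the aneurysm never crosses the basal plane.
        """
        a = self.endo_semi_axes_ed[0]
        bulge = self.infarct.bulge_mm if self.infarct else 0.0
        mu_cut = np.arccos(-self.base_truncation_fraction * a
                           / (a + bulge)) / np.pi
        return mu_cut - 0.02


# ---------------------------------------------------------------------------
# analytic radial fields
# ---------------------------------------------------------------------------

def _raised_cosine_window(x: np.ndarray, halfwidth: float) -> np.ndarray:
    """1 on the window core, cosine taper to 0 at +-halfwidth.

    The border zone occupies the outer 30% of the halfwidth, giving the
    sharp scar boundary seen in chronic transmural infarcts.
    """
    ax = np.abs(x)
    core = 0.7 * halfwidth
    out = np.zeros_like(ax)
    out[ax <= core] = 1.0
    taper = (ax > core) & (ax < halfwidth)
    out[taper] = 0.5 * (1.0 + np.cos(np.pi * (ax[taper] - core)
                                     / (halfwidth - core)))
    return out


def _angdiff(theta: np.ndarray, center: float) -> np.ndarray:
    return np.mod(theta - center + np.pi, 2.0 * np.pi) - np.pi


class _PhantomFields:
    """Analytic per-frame radial fields of a phantom, in the stretched frame."""

    def __init__(self, spec: PhantomSpec):
        self.spec = spec
        a, b, c = spec.endo_semi_axes_ed
        self.kappa = c / a
        self.w = spec.wall_thickness_ed

    def _lam_ellipsoid(self, mu, theta, axes):
        aa, bb, cc = axes
        phi = np.pi * np.asarray(mu)
        sp, cp = np.sin(phi), np.cos(phi)
        inv = ((sp * np.cos(theta) / aa) ** 2
               + (sp * np.sin(theta) / bb) ** 2
               + (self.kappa * cp / cc) ** 2)
        return 1.0 / np.sqrt(inv)

    def infarct_window(self, mu, theta) -> np.ndarray:
        inf = self.spec.infarct
        if inf is None:
            return np.zeros(np.broadcast(np.asarray(mu),
                                         np.asarray(theta)).shape)
        wmu = _raised_cosine_window(np.asarray(mu) - inf.center_mu,
                                    inf.mu_halfwidth)
        wth = _raised_cosine_window(_angdiff(np.asarray(theta),
                                             inf.center_theta),
                                    inf.angular_halfwidth)
        return wmu * wth

    def beta(self, frame: int) -> float:
        t = frame / self.spec.n_frames
        return self.spec.contraction_fraction * 0.5 * (1 - np.cos(2 * np.pi * t))

    def _axes_at(self, beta: float):
        a, b, c = self.spec.endo_semi_axes_ed
        return (a * (1 - beta), b * (1 - beta),
                c * (1 - LONG_AXIS_SHORTENING_RATIO * beta))

    def endo_ed(self, mu, theta):
        lam = self._lam_ellipsoid(mu, theta, self.spec.endo_semi_axes_ed)
        inf = self.spec.infarct
        if inf is not None and inf.bulge_mm > 0:
            lam = lam + inf.bulge_mm * self.infarct_window(mu, theta)
        return lam

    def epi_ed(self, mu, theta):
        a, b, c = self.spec.endo_semi_axes_ed
        w = self.w
        base = self._lam_ellipsoid(mu, theta, self.spec.endo_semi_axes_ed)
        outer = self._lam_ellipsoid(mu, theta, (a + w, b + w, c + w))
        wall = outer - base
        inf = self.spec.infarct
        if inf is None:
            return base + wall
        I = self.infarct_window(mu, theta)
        return (base + inf.bulge_mm * I
                + wall * (1.0 - inf.wall_thinning_fraction * I))

    def endo_frame(self, frame: int):
        b = self.beta(frame)

        def f(mu, theta):
            lam_ed = self.endo_ed(mu, theta)
            lam_full = self._lam_ellipsoid(mu, theta, self._axes_at(b))
            inf = self.spec.infarct
            if inf is not None and inf.akinetic:
                I = self.infarct_window(mu, theta)
                # inside the akinetic window motion is frozen at ED
                return lam_ed + (1.0 - I) * (lam_full
                                             - self._lam_ellipsoid(
                                                 mu, theta,
                                                 self.spec.endo_semi_axes_ed))
            bulge = (inf.bulge_mm * self.infarct_window(mu, theta)
                     if inf is not None else 0.0)
            return lam_full + bulge
        return f

    def epi_frame(self, frame: int):
        endo_f = self.endo_frame(frame)

        def f(mu, theta):
            le = endo_f(mu, theta)
            le0 = self.endo_ed(mu, theta)
            lp0 = self.epi_ed(mu, theta)
            # ray-wise wall-volume conservation in the stretched frame
            return np.cbrt(le ** 3 + lp0 ** 3 - le0 ** 3)
        return f


# ---------------------------------------------------------------------------
# truth model
# ---------------------------------------------------------------------------

@dataclass
class TruthModel:
    spec: PhantomSpec
    frames: list[LVSurfaceModel]
    base_plane: MitralValvePlane
    cavity_volumes_ul: np.ndarray
    ed_frame: int
    es_frame: int
    true_edv: float
    true_esv: float
    true_mass: float
    true_ef: float
    true_infarct_fraction: float        # percent of mid-wall area akinetic

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def true_sv(self) -> float:
        return self.true_edv - self.true_esv


def _base_plane_for(spec: PhantomSpec) -> MitralValvePlane:
    _, _, c = spec.endo_semi_axes_ed
    h = spec.base_truncation_fraction * c
    return MitralValvePlane(origin=np.array([0.0, 0.0, h]),
                            normal=np.array([0.0, 0.0, -1.0]),
                            source_points=np.zeros((0, 3)))


def analytic_akinetic_fraction(spec: PhantomSpec,
                               tau_mm: float = AKINESIA_THRESHOLD_MM,
                               n_mu: int = 384, n_theta: int = 512) -> float:
    """Akinetic mid-wall area fraction (%) from the analytic fields.

    Independent of the spline truth surfaces: works directly on the
    closed-form ED/ES radial fields and a finite-difference area element.
    """
    f = _PhantomFields(spec)
    es = spec.n_frames // 2
    endo_ed = f.endo_ed
    endo_es = f.endo_frame(es)
    epi_ed = f.epi_ed
    k = f.kappa

    mu = (np.arange(n_mu) + 0.5) / n_mu
    th = np.arange(n_theta) * 2 * np.pi / n_theta
    M, T = np.meshgrid(mu, th, indexing="ij")

    lam_mid = 0.5 * (endo_ed(M, T) + epi_ed(M, T))
    phi = np.pi * M
    sp, cp = np.sin(phi), np.cos(phi)
    dnorm = np.sqrt(sp ** 2 + (k * cp) ** 2)

    # area element of the mid-wall radial surface by central differences
    h = 1e-4

    def midwall_point(mm, tt):
        lam = 0.5 * (endo_ed(mm, tt) + epi_ed(mm, tt))
        ph = np.pi * mm
        return np.stack([lam * np.sin(ph) * np.cos(tt),
                         lam * np.sin(ph) * np.sin(tt),
                         -lam * k * np.cos(ph)], axis=-1)

    Smu = (midwall_point(M + h, T) - midwall_point(M - h, T)) / (2 * h)
    Sth = (midwall_point(M, T + h) - midwall_point(M, T - h)) / (2 * h)
    dA = np.linalg.norm(np.cross(Smu, Sth), axis=-1)

    # restrict to below the basal plane (z <= h_base on the mid-wall)
    _, _, c = spec.endo_semi_axes_ed
    zmid = -lam_mid * k * cp
    below = zmid <= spec.base_truncation_fraction * c

    excursion = np.abs(endo_es(M, T) - endo_ed(M, T)) * dnorm
    akinetic = (excursion < tau_mm) & below
    denom = dA[below].sum()
    return 100.0 * dA[akinetic].sum() / denom


def calibrate_infarct_extent(spec: PhantomSpec, target_fraction_pct: float
                             ) -> PhantomSpec:
    """Scale the infarct window so the akinetic area hits the target (%).

    Both halfwidths are scaled by a common factor found by root bisection on
    the analytic akinetic-fraction computation.
    """
    if spec.infarct is None:
        raise ConfigurationError("spec has no infarct to calibrate")
    base = spec.infarct
    mu_cap = min(base.center_mu, spec.basal_mu_limit() - base.center_mu) \
        - 1e-3

    def scaled_infarct(scale: float) -> InfarctSpec:
        return base.model_copy(update={
            "angular_halfwidth": min(base.angular_halfwidth * scale,
                                     np.pi - 1e-3),
            "mu_halfwidth": min(base.mu_halfwidth * scale, mu_cap)})

    def frac(scale: float) -> float:
        s = spec.model_copy(update={"infarct": scaled_infarct(scale)})
        return analytic_akinetic_fraction(s, n_mu=192, n_theta=256)

    lo, hi = 0.3, 2.5
    flo, fhi = frac(lo), frac(hi)
    if not flo < target_fraction_pct < fhi:
        raise ConfigurationError(
            f"target akinetic fraction {target_fraction_pct}% outside the "
            f"reachable range [{flo:.1f}, {fhi:.1f}]%")
    scale = brentq(lambda s: frac(s) - target_fraction_pct, lo, hi,
                   xtol=1e-3)
    return spec.model_copy(update={"infarct": scaled_infarct(scale)})


def make_phantom(spec: PhantomSpec) -> TruthModel:
    """Build the per-frame truth surfaces and analytic truth quantities.

    Frame 0 is end-diastole; end-systole is the frame of minimal cavity
    volume (mid-cycle for the raised-cosine time course).
    """
    fields = _PhantomFields(spec)
    basis = TensorSplineBasis(*TRUTH_BASIS_ORDER)
    axis = np.array([0.0, 0.0, -1.0])
    u1 = np.array([1.0, 0.0, 0.0])
    u2 = np.cross(axis, u1)

    frames = []
    for f in range(spec.n_frames):
        ce = basis.interpolate(fields.endo_frame(f))
        cp = basis.interpolate(fields.epi_frame(f))
        m = LVSurfaceModel(axis_origin=np.zeros(3), axis_direction=axis,
                           transverse_u=u1, transverse_v=u2,
                           elongation=fields.kappa,
                           coeffs_endo=ce, coeffs_epi=cp,
                           basis_order=TRUTH_BASIS_ORDER, _basis=basis)
        frames.append(m)

    base = _base_plane_for(spec)
    cav = np.array([enclosed_volume(m, "endo", base) for m in frames])
    ed, es = 0, int(np.argmin(cav))
    myo_ed = enclosed_volume(frames[ed], "epi", base) - cav[ed]
    myo_es = enclosed_volume(frames[es], "epi", base) - cav[es]
    mass = MYOCARDIAL_DENSITY_MG_PER_UL * 0.5 * (myo_ed + myo_es)

    infarct_pct = 0.0
    if spec.infarct is not None and spec.infarct.akinetic:
        infarct_pct = analytic_akinetic_fraction(spec)

    edv, esv = float(cav[ed]), float(cav[es])
    return TruthModel(spec=spec, frames=frames, base_plane=base,
                      cavity_volumes_ul=cav, ed_frame=ed, es_frame=es,
                      true_edv=edv, true_esv=esv, true_mass=float(mass),
                      true_ef=(edv - esv) / edv,
                      true_infarct_fraction=float(infarct_pct))


# ---------------------------------------------------------------------------
# simulated acquisition
# ---------------------------------------------------------------------------

def acquire_study(truth: TruthModel, slice_thickness_mm: float = 1.0,
                  pixel_size_mm: float = 0.05, n_contour_points: int = 80,
                  noise_sd_mm: float | None = None,
                  rng_seed: int | None = None) -> CineStudy:
    """Simulate SAX-stack + 2 LAX cine acquisition from a truth phantom.

    SAX planes are placed perpendicular to the long axis at the given
    spacing, the first plane half a slice below the basal (mitral-valve)
    plane, continuing until a plane no longer intersects the end-diastolic
    endocardium. Contours are surface/plane intersections with i.i.d.
    isotropic in-plane Gaussian noise; the 4 mitral-valve landmarks are the
    intersections of the basal ring with the two LAX planes.
    """
    spec = truth.spec
    if noise_sd_mm is None:
        noise_sd_mm = spec.noise_sd_mm
    if rng_seed is None:
        rng_seed = spec.rng_seed
    rng = np.random.default_rng(rng_seed)

    model0 = truth.frames[0]
    axis = model0.axis_direction
    u1, u2 = model0.transverse_u, model0.transverse_v
    base_origin = truth.base_plane.origin
    n_frames = spec.n_frames

    def noisy(uv: np.ndarray) -> np.ndarray:
        if noise_sd_mm == 0 or uv.size == 0:
            return uv
        return uv + rng.normal(0.0, noise_sd_mm, size=uv.shape)

    slices: list[StudySlice] = []
    # --- SAX stack ---------------------------------------------------------
    k = 0
    while True:
        origin = base_origin + (k + 0.5) * slice_thickness_mm * axis
        plane = SlicePlane(origin=origin, normal=axis, axis_u=u1, axis_v=u2,
                           slice_label=SAX, sax_index=k + 1)
        probe = intersect_surface_with_plane(model0, "endo", plane,
                                             n_contour_points)
        if probe.is_empty:
            break
        endo_frames, epi_frames = [], []
        for f in range(n_frames):
            ce = intersect_surface_with_plane(truth.frames[f], "endo", plane,
                                              n_contour_points)
            cp = intersect_surface_with_plane(truth.frames[f], "epi", plane,
                                              n_contour_points)
            endo_frames.append(noisy(ce.uv))
            epi_frames.append(noisy(cp.uv))
        slices.append(StudySlice(plane=plane, endo=endo_frames,
                                 epi=epi_frames))
        k += 1
        if k > 64:
            raise ConfigurationError("runaway SAX stack; check geometry")
    if k < 2:
        raise ConfigurationError(
            f"stack would contain {k} SAX slice(s); need at least 2")

    # --- LAX planes (contain the long axis) --------------------------------
    lax_defs = [(LAX_2CH, u2), (LAX_4CH, u1)]
    base_normal = truth.base_plane.normal
    for label, nrm in lax_defs:
        # in-plane frame: (axis-aligned, transverse)
        in_u = axis.copy()
        in_v = np.cross(nrm, in_u)
        plane = SlicePlane(origin=model0.axis_origin.copy(), normal=nrm,
                           axis_u=in_u, axis_v=in_v, slice_label=label)
        endo_frames, epi_frames = [], []
        for f in range(n_frames):
            fr = truth.frames[f]
            ce = intersect_surface_with_plane(fr, "endo", plane,
                                              2 * n_contour_points)
            cp = intersect_surface_with_plane(fr, "epi", plane,
                                              2 * n_contour_points)
            keep_e = (ce.xyz - base_origin) @ base_normal >= 0
            keep_p = (cp.xyz - base_origin) @ base_normal >= 0
            endo_frames.append(noisy(ce.uv[keep_e]))
            epi_frames.append(noisy(cp.uv[keep_p]))
        slices.append(StudySlice(plane=plane, endo=endo_frames,
                                 epi=epi_frames))

    # --- mitral-valve landmarks --------------------------------------------
    # the basal endocardial ring meets each LAX plane on two meridians
    mv = np.zeros((n_frames, 4, 3))
    lax_planes = {s.label: s.plane for s in slices if s.label != SAX}
    for f in range(n_frames):
        pts = []
        for label in (LAX_2CH, LAX_4CH):
            pl = lax_planes[label]
            nu = float(pl.normal @ u1)
            nv = float(pl.normal @ u2)
            theta0 = np.arctan2(nv, nu)
            for sgn in (+1, -1):
                th = np.mod(theta0 + sgn * np.pi / 2, 2 * np.pi)
                p = _ring_point(truth.frames[f], truth.base_plane, th)
                if noise_sd_mm > 0:
                    uv = pl.to_plane_coords(p)[0]
                    uv = uv + rng.normal(0.0, noise_sd_mm, size=2)
                    p = pl.to_3d(uv)[0]
                pts.append(p)
        mv[f] = np.array(pts)

    return CineStudy(slices=slices, mv_points=mv, n_frames=n_frames,
                     slice_thickness_mm=slice_thickness_mm,
                     pixel_size_mm=pixel_size_mm,
                     metadata={"rng_seed": int(rng_seed),
                               "noise_sd_mm": float(noise_sd_mm),
                               "group": "infarct" if spec.infarct else
                               "control"})


def _ring_point(model: LVSurfaceModel, base: MitralValvePlane, theta: float
                ) -> np.ndarray:
    """Point where the meridian ``theta`` of the endocardium crosses the base."""
    mu_grid = np.linspace(0.0, 1.0, 257)
    pts = model.surface_point("endo", mu_grid, np.full_like(mu_grid, theta))
    g = (pts - base.origin) @ base.normal
    idx = np.nonzero(np.sign(g[:-1]) * np.sign(g[1:]) < 0)[0]
    if len(idx) == 0:
        raise GeometryError("basal plane does not cross the endocardium "
                            f"on meridian theta={theta:.3f}")
    lo, hi = mu_grid[idx[0]], mu_grid[idx[0] + 1]
    glo = g[idx[0]]
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        gm = float((model.surface_point("endo", np.array([mid]),
                                        np.array([theta]))[0]
                    - base.origin) @ base.normal)
        if np.sign(gm) == np.sign(glo):
            lo, glo = mid, gm
        else:
            hi = mid
    return model.surface_point("endo", np.array([0.5 * (lo + hi)]),
                               np.array([theta]))[0]


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def control_spec(seed: int = 0, noise_sd_mm: float = 0.025,
                 jitter: bool = True) -> PhantomSpec:
    """Healthy-mouse preset; per-seed biological scatter around group means."""
    rng = np.random.default_rng(seed)
    g = 1.0 + (0.05 * rng.standard_normal() if jitter else 0.0)
    wj = 1.0 + (0.05 * rng.standard_normal() if jitter else 0.0)
    cj = (0.015 * rng.standard_normal() if jitter else 0.0)
    return PhantomSpec(
        endo_semi_axes_ed=(1.952 * g, 1.952 * g, 4.605 * g),
        wall_thickness_ed=0.958 * wj,
        base_truncation_fraction=0.55,
        n_frames=20,
        contraction_fraction=min(max(0.358 + cj, 0.05), 0.9),
        infarct=None,
        noise_sd_mm=noise_sd_mm,
        rng_seed=seed)


def infarct_spec(seed: int = 0, noise_sd_mm: float = 0.025,
                 akinetic_fraction_pct: float | None = None,
                 jitter: bool = True) -> PhantomSpec:
    """Chronically infarcted preset (dilated, thin akinetic apical-anterior
    wall); the akinetic area is calibrated to the requested fraction, or
    drawn per seed from the 35-48% range when not given."""
    rng = np.random.default_rng(seed)
    g = 1.0 + (0.04 * rng.standard_normal() if jitter else 0.0)
    wj = 1.0 + (0.05 * rng.standard_normal() if jitter else 0.0)
    if akinetic_fraction_pct is None:
        akinetic_fraction_pct = float(rng.uniform(35.0, 48.0))
    spec = PhantomSpec(
        endo_semi_axes_ed=(2.304 * g, 2.304 * g, 4.338 * g),
        wall_thickness_ed=0.903 * wj,
        base_truncation_fraction=0.55,
        n_frames=20,
        contraction_fraction=0.266,
        # aneurysmal scar sits between the two LAX view planes
        # (anterolateral), with prominent regional dilation and 50% thinning
        infarct=InfarctSpec(center_theta=np.pi / 4, center_mu=0.29,
                            angular_halfwidth=1.5, mu_halfwidth=0.18,
                            wall_thinning_fraction=0.5, bulge_mm=1.5,
                            akinetic=True),
        noise_sd_mm=noise_sd_mm,
        rng_seed=seed)
    return calibrate_infarct_extent(spec, akinetic_fraction_pct)
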