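"""3D types and numerics shared by all pipeline stages.

Coordinate conventions
----------------------
Right-handed lab frame, lengths in mm, volumes in microlitres (= mm^3).
Each LV surface is a *radial field*: a point of the surface labelled
``(mu, theta)`` sits at

    S(mu, theta) = axis_origin + lambda(mu, theta) * d(mu, theta)
    d(mu, theta) = sin(phi) (cos(theta) u1 + sin(theta) u2)
                   + elongation * cos(phi) * axis_direction,   phi = pi * mu

so ``mu = 0`` is the apex pole, ``mu = 1`` the basal pole, and ``theta`` runs
circumferentially. ``elongation`` stretches the unit direction field along
the long axis: a *constant* radial field lambda = a is then an exact prolate
spheroid with short semi-axis ``a`` and long semi-axis ``a * elongation``
(a sphere for elongation = 1). The field itself is a tensor-product spline
(:mod:`lvgpm._basis`), which keeps surface fitting linear in the
coefficients while representing smoothly remodelled (e.g. infarcted)
ventricles.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from ._basis import TensorSplineBasis
from .errors import DegenerateGeometryError, GeometryError

SurfaceName = Literal["endo", "epi"]

_ORTHO_TOL = 1e-9


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise DegenerateGeometryError("zero-length vector cannot be normalized")
    return v / n


# ---------------------------------------------------------------------------
# planes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SlicePlane:
    """An imaging plane: origin plus an orthonormal in-plane frame.

    ``(u, v) -> origin + u * axis_u + v * axis_v`` is an isometry between
    plane coordinates and 3D. ``slice_label`` is one of SAX / LAX_2CH /
    LAX_4CH; ``sax_index`` counts base -> apex (1-based) for SAX slices.
    """

    origin: np.ndarray
    normal: np.ndarray
    axis_u: np.ndarray
    axis_v: np.ndarray
    slice_label: str = "SAX"
    sax_index: int | None = None

    def __post_init__(self):
        for name in ("origin", "normal", "axis_u", "axis_v"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=float))
        n, u, v = self.normal, self.axis_u, self.axis_v
        for a, b in ((n, u), (n, v), (u, v)):
            if abs(float(a @ b)) > 1e-8:
                raise DegenerateGeometryError(
                    "plane frame vectors are not orthogonal")
        for a in (n, u, v):
            if abs(np.linalg.norm(a) - 1.0) > 1e-8:
                raise DegenerateGeometryError(
                    "plane frame vectors are not unit length")

    def to_plane_coords(self, points: np.ndarray) -> np.ndarray:
        """Project 3D points (n, 3) to in-plane (u, v) coordinates (n, 2)."""
        rel = np.atleast_2d(points) - self.origin
        return np.stack([rel @ self.axis_u, rel @ self.axis_v], axis=-1)

    def to_3d(self, uv: np.ndarray) -> np.ndarray:
        uv = np.atleast_2d(uv)
        return (self.origin + uv[:, :1] * self.axis_u
                + uv[:, 1:2] * self.axis_v)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.origin) @ self.normal


def plane_basis_from_normal(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic in-plane orthonormal frame for a given normal."""
    n = _unit(np.asarray(normal, dtype=float))
    seed = np.array([1.0, 0.0, 0.0])
    if abs(n @ seed) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    u = _unit(seed - (seed @ n) * n)
    v = np.cross(n, u)
    return u, v


@dataclass(frozen=True)
class MitralValvePlane:
    """Total-least-squares plane through the mitral-valve landmarks.

    The normal is oriented toward the apex (``orient_toward``), so the
    ventricle lies on the positive side; this fixes the cap orientation for
    volume integration.
    """

    origin: np.ndarray
    normal: np.ndarray
    source_points: np.ndarray
    frame: int = 0
    rms_residual: float = 0.0

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.origin) @ self.normal


def fit_plane(points: Sequence, frame: int = 0,
              orient_toward: np.ndarray | None = None) -> MitralValvePlane:
    """Orthogonal-distance (total-least-squares) plane through >= 3 points.

    Coincident points are collapsed first; if fewer than 3 distinct,
    non-collinear points remain a :class:`DegenerateGeometryError` is raised
    naming the offending input.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise DegenerateGeometryError(f"expected (n, 3) points, got {pts.shape}")
    # drop duplicates (noisy landmarks may coincide)
    keep = np.ones(len(pts), dtype=bool)
    for i in range(len(pts)):
        if not keep[i]:
            continue
        d = np.linalg.norm(pts[i + 1:] - pts[i], axis=1)
        keep[i + 1:] &= d > 1e-9
    distinct = pts[keep]
    if len(distinct) < 3:
        raise DegenerateGeometryError(
            f"plane fit needs >= 3 distinct points, got {len(distinct)} "
            f"distinct out of {len(pts)}: {pts.tolist()}")
    centroid = distinct.mean(axis=0)
    rel = distinct - centroid
    _, s, vt = np.linalg.svd(rel, full_matrices=False)
    if s[1] < 1e-12 * max(s[0], 1.0):
        raise DegenerateGeometryError(
            f"points are collinear, plane undefined: {pts.tolist()}")
    normal = vt[2]
    if orient_toward is not None:
        if float((np.asarray(orient_toward) - centroid) @ normal) < 0:
            normal = -normal
    rms = float(np.sqrt(np.mean((rel @ normal) ** 2)))
    return MitralValvePlane(origin=centroid, normal=normal,
                            source_points=pts, frame=frame, rms_residual=rms)


# ---------------------------------------------------------------------------
# the LV surface model
# ---------------------------------------------------------------------------

@dataclass
class LVSurfaceModel:
    """Fitted endocardial + epicardial radial-field surface pair.

    ``coeffs_endo`` / ``coeffs_epi`` are (n_mu, n_theta) spline control
    grids of the radial field in the elongated frame (mm).
    """

    axis_origin: np.ndarray
    axis_direction: np.ndarray          # unit, points toward the apex
    transverse_u: np.ndarray
    transverse_v: np.ndarray
    elongation: float
    coeffs_endo: np.ndarray
    coeffs_epi: np.ndarray
    basis_order: tuple[int, int] = (4, 8)
    _basis: TensorSplineBasis | None = field(default=None, repr=False,
                                             compare=False)

    def __post_init__(self):
        self.axis_origin = np.asarray(self.axis_origin, dtype=float)
        self.axis_direction = _unit(np.asarray(self.axis_direction, float))
        self.transverse_u = _unit(np.asarray(self.transverse_u, float))
        self.transverse_v = _unit(np.asarray(self.transverse_v, float))
        self.coeffs_endo = np.asarray(self.coeffs_endo, dtype=float)
        self.coeffs_epi = np.asarray(self.coeffs_epi, dtype=float)
        if self.elongation <= 0:
            raise DegenerateGeometryError("elongation must be positive")
        shape = (self.basis_order[0], self.basis_order[1])
        for c in (self.coeffs_endo, self.coeffs_epi):
            if c.shape != shape:
                raise DegenerateGeometryError(
                    f"coefficient grid {c.shape} != basis order {shape}")

    @property
    def basis(self) -> TensorSplineBasis:
        if self._basis is None:
            self._basis = TensorSplineBasis(*self.basis_order)
        return self._basis

    def _coeffs(self, surface: SurfaceName) -> np.ndarray:
        if surface == "endo":
            return self.coeffs_endo
        if surface == "epi":
            return self.coeffs_epi
        raise ValueError(f"unknown surface {surface!r}")

    # -- evaluation ---------------------------------------------------------
    def radial_field(self, surface: SurfaceName, mu, theta,
                     dmu: int = 0, dtheta: int = 0) -> np.ndarray:
        return self.basis.evaluate(self._coeffs(surface), mu, theta, dmu, dtheta)

    def direction_field(self, mu, theta):
        """d(mu, theta) and its parameter derivatives d_mu, d_theta."""
        mu = np.atleast_1d(np.asarray(mu, dtype=float))
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        phi = np.pi * mu
        sp, cp = np.sin(phi), np.cos(phi)
        ct, st = np.cos(theta), np.sin(theta)
        u1, u2, a = self.transverse_u, self.transverse_v, self.axis_direction
        k = self.elongation
        trans = ct[..., None] * u1 + st[..., None] * u2
        trans_t = -st[..., None] * u1 + ct[..., None] * u2
        d = sp[..., None] * trans + (k * cp)[..., None] * a
        d_mu = np.pi * (cp[..., None] * trans - (k * sp)[..., None] * a)
        d_th = sp[..., None] * trans_t
        return d, d_mu, d_th

    def surface_point(self, surface: SurfaceName, mu, theta) -> np.ndarray:
        """Evaluate the surface at paired (mu, theta); mm, shape (..., 3)."""
        mu_a = np.asarray(mu, dtype=float)
        th_a = np.asarray(theta, dtype=float)
        if np.any(mu_a < -1e-12) or np.any(mu_a > 1 + 1e-12):
            raise ValueError("mu outside [0, 1]")
        lam = self.radial_field(surface, mu_a, th_a)
        d, _, _ = self.direction_field(mu_a, th_a)
        pts = self.axis_origin + lam[..., None] * d
        return pts if np.ndim(mu) else pts[0]

    def surface_derivatives(self, surface: SurfaceName, mu, theta):
        """S, S_mu, S_theta at paired parameter arrays."""
        lam = self.radial_field(surface, mu, theta)
        lam_m = self.radial_field(surface, mu, theta, dmu=1)
        lam_t = self.radial_field(surface, mu, theta, dtheta=1)
        d, d_m, d_t = self.direction_field(mu, theta)
        S = self.axis_origin + lam[..., None] * d
        S_m = lam_m[..., None] * d + lam[..., None] * d_m
        S_t = lam_t[..., None] * d + lam[..., None] * d_t
        return S, S_m, S_t

    def to_stretched(self, points: np.ndarray):
        """Invert the radial map: 3D points -> (mu, theta, radius).

        ``radius`` is the stretched-frame radial coordinate, i.e. the value
        lambda would need at (mu, theta) for the point to lie on the surface.
        """
        rel = np.atleast_2d(points) - self.axis_origin
        z = rel @ self.axis_direction
        u = rel @ self.transverse_u
        v = rel @ self.transverse_v
        zs = z / self.elongation
        rho = np.hypot(u, v)
        radius = np.hypot(rho, zs)
        phi = np.arctan2(rho, zs)
        mu = phi / np.pi
        theta = np.mod(np.arctan2(v, u), 2.0 * np.pi)
        return mu, theta, radius

    # -- invariants ---------------------------------------------------------
    def check_valid(self, grid: int = 64) -> None:
        """Raise GeometryError if the field is non-positive or crossing."""
        mu = np.linspace(0.0, 1.0, grid)
        th = np.linspace(0.0, 2.0 * np.pi, grid, endpoint=False)
        M, T = np.meshgrid(mu, th, indexing="ij")
        le = self.radial_field("endo", M, T)
        lp = self.radial_field("epi", M, T)
        if not np.all(np.isfinite(le)) or not np.all(np.isfinite(lp)):
            raise GeometryError("non-finite radial field")
        if le.min() <= 0:
            raise GeometryError("endocardial radial field not positive")
        if np.any(lp < le - 1e-9):
            raise GeometryError("epicardial surface crosses endocardial")

    def scaled(self, s: float) -> "LVSurfaceModel":
        """Uniformly scale the model about its axis origin."""
        return replace(self, coeffs_endo=self.coeffs_endo * s,
                       coeffs_epi=self.coeffs_epi * s, _basis=self._basis)


# ---------------------------------------------------------------------------
# surface / plane intersection
# ---------------------------------------------------------------------------

@dataclass
class PlaneContour:
    """Ordered closed contour of a surface/plane intersection."""

    uv: np.ndarray          # (n, 2) in-plane coordinates
    xyz: np.ndarray         # (n, 3)
    degenerate: bool = False

    def __len__(self):
        return len(self.uv)

    @property
    def is_empty(self) -> bool:
        return len(self.uv) == 0


def _signed_area(uv: np.ndarray) -> float:
    x, y = uv[:, 0], uv[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _ensure_ccw(uv: np.ndarray, xyz: np.ndarray):
    if len(uv) >= 3 and _signed_area(uv) < 0:
        return uv[::-1].copy(), xyz[::-1].copy()
    return uv, xyz


def _bisect_crossing(model: LVSurfaceModel, surface: SurfaceName,
                     theta: np.ndarray, g_of_mu, lo: np.ndarray,
                     hi: np.ndarray, iters: int = 60) -> np.ndarray:
    """Vectorized bisection for the mu root of g along each theta ray."""
    lo = lo.copy()
    hi = hi.copy()
    glo = g_of_mu(lo, theta)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        gm = g_of_mu(mid, theta)
        take_lo = np.sign(gm) == np.sign(glo)
        lo = np.where(take_lo, mid, lo)
        glo = np.where(take_lo, gm, glo)
        hi = np.where(take_lo, hi, mid)
    return 0.5 * (lo + hi)


def _first_crossing_brackets(g: np.ndarray, mu_grid: np.ndarray):
    """Per-theta bracket of the first sign change along mu, or None."""
    sign = np.sign(g)
    change = sign[:-1, :] * sign[1:, :] < 0
    n_changes = change.sum(axis=0)
    if np.all(n_changes == 0):
        return None, n_changes
    first = np.argmax(change, axis=0)
    lo = mu_grid[first]
    hi = mu_grid[first + 1]
    return (lo, hi), n_changes


def intersect_surface_with_plane(model: LVSurfaceModel, surface: SurfaceName,
                                 plane: SlicePlane, n_points: int = 200
                                 ) -> PlaneContour:
    """Intersection contour of a surface with an imaging plane.

    Returns an empty (degenerate) contour when the plane misses the surface;
    raises :class:`GeometryError` only for topologies the radial
    parameterization cannot order (multiple crossings per meridian).
    Contour points are ordered counter-clockwise in (u, v).
    """
    p0, n = plane.origin, plane.normal

    def g_of_mu(mu, theta):
        pts = model.surface_point(surface, mu, theta)
        return (pts - p0) @ n

    # scan on the output theta grid; doubles as the bracketing grid
    mu_grid = np.linspace(0.0, 1.0, 65)
    theta = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    Mq = np.repeat(mu_grid[:, None], len(theta), axis=1)
    Tq = np.repeat(theta[None, :], len(mu_grid), axis=0)
    G = (model.surface_point(surface, Mq, Tq) - p0) @ n

    lam_scale = float(np.abs(model.coeffs_endo).max() + 1e-9)
    if np.all(G > 1e-12 * lam_scale) or np.all(G < -1e-12 * lam_scale):
        return PlaneContour(np.zeros((0, 2)), np.zeros((0, 3)), degenerate=True)

    g_apex = float(G[0, 0])
    g_base = float(G[-1, 0])
    axis_dot = abs(float(n @ model.axis_direction))

    if np.sign(g_apex) != np.sign(g_base) and g_apex != 0 and g_base != 0:
        # plane separates the poles: exactly one crossing per meridian
        brackets, n_changes = _first_crossing_brackets(G, mu_grid)
        if brackets is None or np.any(n_changes == 0):
            return PlaneContour(np.zeros((0, 2)), np.zeros((0, 3)),
                                degenerate=True)
        if np.any(n_changes > 1):
            # non-monotone cut (e.g. across an aneurysmal bulge edge):
            # trace the level set instead of assuming one root per meridian
            return _level_set_contour(model, surface, plane, G, mu_grid,
                                      theta)
        mu_c = _bisect_crossing(model, surface, theta, g_of_mu, *brackets)
        xyz = model.surface_point(surface, mu_c, theta)
        uv = plane.to_plane_coords(xyz)
        uv, xyz = _ensure_ccw(uv, xyz)
        return PlaneContour(uv, xyz)

    nu = float(n @ model.transverse_u)
    nv = float(n @ model.transverse_v)
    off = float((model.axis_origin - p0) @ n)
    amp = np.hypot(nu, nv)
    if axis_dot < 0.2 and amp > 1e-12 and abs(off) <= 0.02 * amp * lam_scale:
        # long-axis plane containing (or almost containing) the LV axis:
        # the contour is a pair of opposite meridians through both poles
        theta0 = np.arctan2(nv, nu)
        # cos(theta - theta0) = -off / (lambda sin(phi) amp); for planes
        # through the axis off == 0 and the meridians are theta0 +/- pi/2
        half = n_points // 2
        mu_up = np.linspace(0.0, 1.0, half)
        th_a = np.full(half, np.mod(theta0 + np.pi / 2, 2 * np.pi))
        th_b = np.full(half, np.mod(theta0 - np.pi / 2, 2 * np.pi))
        xyz = np.vstack([model.surface_point(surface, mu_up, th_a),
                         model.surface_point(surface, mu_up[::-1], th_b)])
        if abs(off) > 1e-12:
            # project points exactly onto the plane (tiny axis offset)
            xyz = xyz - np.outer((xyz - p0) @ n, n)
        uv = plane.to_plane_coords(xyz)
        uv, xyz = _ensure_ccw(uv, xyz)
        return PlaneContour(uv, xyz)

    # side cut (e.g. a slice clipping only an apical bulge lobe):
    # trace the zero level set in parameter space and polish each vertex
    return _level_set_contour(model, surface, plane, G, mu_grid, theta)


def _level_set_contour(model: LVSurfaceModel, surface: SurfaceName,
                       plane: SlicePlane, G: np.ndarray, mu_grid: np.ndarray,
                       theta: np.ndarray) -> PlaneContour:
    """Marching-squares contour of the plane distance in (mu, theta) space."""
    from skimage import measure

    p0, n = plane.origin, plane.normal
    # wrap theta so loops crossing 0/2pi stay connected
    Gx = np.concatenate([G, G[:, :1]], axis=1)
    th_ext = np.concatenate([theta, [2.0 * np.pi]])
    ncol = Gx.shape[1] - 1
    raw = measure.find_contours(Gx, 0.0)
    loops = []
    for c in raw:
        if len(c) < 8:
            continue
        if np.allclose(c[0], c[-1], atol=1e-9):
            loops.append(c[:-1])              # interior closed loop
        elif ({round(c[0, 1]), round(c[-1, 1])} == {0, ncol}
              and abs(c[0, 0] - c[-1, 0]) < 1e-6):
            loops.append(c[:-1])              # loop closed through theta wrap
    if not loops:
        return PlaneContour(np.zeros((0, 2)), np.zeros((0, 3)),
                            degenerate=True)
    loop = max(loops, key=len)

    dmu = mu_grid[1] - mu_grid[0]
    dth = th_ext[1] - th_ext[0]
    mu_v = loop[:, 0] * dmu
    th_v = loop[:, 1] * dth
    # each marching-squares vertex lies on a grid edge: one index integral.
    # bisect the sign change along the fractional direction.
    row_frac = np.abs(loop[:, 0] - np.round(loop[:, 0])) > 1e-9
    for along_mu, sel in ((True, row_frac), (False, ~row_frac)):
        if not np.any(sel):
            continue
        if along_mu:
            lo = np.floor(loop[sel, 0]) * dmu
            hi = lo + dmu
            fixed = th_v[sel]

            def g(x, fx=None):
                pts = model.surface_point(surface, x, fixed)
                return (pts - p0) @ n
        else:
            lo = np.floor(loop[sel, 1]) * dth
            hi = lo + dth
            fixed = mu_v[sel]

            def g(x, fx=None):
                pts = model.surface_point(surface, fixed, x)
                return (pts - p0) @ n
        glo = g(lo)
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            gm = g(mid)
            take = np.sign(gm) == np.sign(glo)
            lo = np.where(take, mid, lo)
            glo = np.where(take, gm, glo)
            hi = np.where(take, hi, mid)
        root = 0.5 * (lo + hi)
        if along_mu:
            mu_v[sel] = root
        else:
            th_v[sel] = root
    xyz = model.surface_point(surface, np.clip(mu_v, 0.0, 1.0),
                              np.mod(th_v, 2.0 * np.pi))
    uv = plane.to_plane_coords(xyz)
    uv, xyz = _ensure_ccw(uv, xyz)
    return PlaneContour(uv, xyz, degenerate=len(uv) < 3)


# ---------------------------------------------------------------------------
# enclosed volume
# ---------------------------------------------------------------------------

def enclosed_volume(model: LVSurfaceModel, surface: SurfaceName,
                    base, quadrature_order: int = 8) -> float:
    """Volume (ul) bounded by the surface and the basal plane.

    Divergence-theorem quadrature: with the reference point taken *on* the
    base plane the planar cap contributes nothing, so only the curved part
    is integrated — Gauss-Legendre along mu (composite, ``quadrature_order``
    nodes per panel), trapezoid along the periodic theta direction.

    ``base`` is a :class:`MitralValvePlane` (or any object with ``origin``
    and ``normal``) whose normal points toward the apex.
    """
    if quadrature_order < 1:
        raise ValueError("quadrature_order must be >= 1")
    p0 = np.asarray(base.origin, dtype=float)
    n = _unit(np.asarray(base.normal, dtype=float))

    n_theta = max(128, 32 * quadrature_order)
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)

    def g_of_mu(mu, th):
        return (model.surface_point(surface, mu, th) - p0) @ n

    mu_grid = np.linspace(0.0, 1.0, 129)
    Mq = np.repeat(mu_grid[:, None], n_theta, axis=1)
    Tq = np.repeat(theta[None, :], len(mu_grid), axis=0)
    Gq = (model.surface_point(surface, Mq, Tq) - p0) @ n

    if Gq[0, 0] <= 0:
        raise GeometryError("base plane does not leave the apex on its "
                            "positive side (plane misses the surface?)")
    brackets, n_changes = _first_crossing_brackets(Gq, mu_grid)
    if brackets is None or np.any(n_changes == 0):
        raise GeometryError("base plane does not intersect the surface on "
                            "every meridian")
    if np.any(n_changes > 1):
        raise GeometryError("base plane cuts the surface more than once")
    mu_c = _bisect_crossing(model, surface, theta, g_of_mu, *brackets)

    # composite Gauss-Legendre on [0, mu_c(theta)] per meridian
    qx, qw = np.polynomial.legendre.leggauss(quadrature_order)
    n_panels = 4
    edges = np.linspace(0.0, 1.0, n_panels + 1)
    vol = 0.0
    dth = 2.0 * np.pi / n_theta
    for p in range(n_panels):
        a = edges[p] * mu_c
        b = edges[p + 1] * mu_c
        halfw = 0.5 * (b - a)
        mid = 0.5 * (a + b)
        for x, w in zip(qx, qw):
            mu = mid + halfw * x                     # (n_theta,)
            S, S_m, S_t = model.surface_derivatives(surface, mu, theta)
            integrand = np.einsum("pi,pi->p", S - p0, np.cross(S_m, S_t))
            vol += np.sum(w * halfw * integrand) * dth / 3.0
    if vol < 0:
        raise GeometryError("negative enclosed volume: check plane orientation")
    return float(vol)


def voxelized_volume(model: LVSurfaceModel, surface: SurfaceName, base,
                     voxel_mm: float = 0.02) -> float:
    """Independent voxel-counting volume oracle (ul).

    Counts voxel centers inside the radial surface and on the apex side of
    the base plane, slab by slab. The radial field is sampled through a
    dense bilinear lookup table, so this path shares no quadrature machinery
    with :func:`enclosed_volume`.
    """
    p0 = np.asarray(base.origin, dtype=float)
    n = _unit(np.asarray(base.normal, dtype=float))

    # lookup table of lambda on a fine parameter grid
    n_mu_t, n_th_t = 1025, 2048
    mu_t = np.linspace(0.0, 1.0, n_mu_t)
    th_t = np.linspace(0.0, 2.0 * np.pi, n_th_t, endpoint=False)
    Mt, Tt = np.meshgrid(mu_t, th_t, indexing="ij")
    table = model.radial_field(surface, Mt, Tt)

    lam_max = table.max()
    k = model.elongation
    O = model.axis_origin
    ax, u1, u2 = model.axis_direction, model.transverse_u, model.transverse_v
    # lab-frame bounding box
    half = lam_max * max(1.0, k) * 1.05
    lo = O - half
    hi = O + half
    xs = np.arange(lo[0] + voxel_mm / 2, hi[0], voxel_mm)
    ys = np.arange(lo[1] + voxel_mm / 2, hi[1], voxel_mm)
    zs = np.arange(lo[2] + voxel_mm / 2, hi[2], voxel_mm)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    count = 0
    dmu = mu_t[1] - mu_t[0]
    dth = th_t[1] - th_t[0]
    for z in zs:
        pts = np.stack([X.ravel(), Y.ravel(), np.full(X.size, z)], axis=-1)
        rel = pts - O
        zz = rel @ ax
        uu = rel @ u1
        vv = rel @ u2
        zst = zz / k
        rho = np.hypot(uu, vv)
        rad = np.hypot(rho, zst)
        phi = np.arctan2(rho, zst)
        mu = phi / np.pi
        th = np.mod(np.arctan2(vv, uu), 2.0 * np.pi)
        # bilinear lookup
        fi = np.clip(mu / dmu, 0, n_mu_t - 1 - 1e-9)
        fj = th / dth
        i0 = fi.astype(int)
        j0 = fj.astype(int) % n_th_t
        i1 = np.minimum(i0 + 1, n_mu_t - 1)
        j1 = (j0 + 1) % n_th_t
        wi = fi - i0
        wj = fj - fj.astype(int)
        lam = ((1 - wi) * (1 - wj) * table[i0, j0]
               + wi * (1 - wj) * table[i1, j0]
               + (1 - wi) * wj * table[i0, j1]
               + wi * wj * table[i1, j1])
        inside = (rad <= lam) & ((pts - p0) @ n >= 0)
        count += int(inside.sum())
    return count * voxel_mm ** 3


def ellipsoid_model(a: float, b: float, c: float,
                    center=(0.0, 0.0, 0.0),
                    basis_order: tuple[int, int] = (20, 12),
                    wall: float = 0.0) -> LVSurfaceModel:
    """Convenience constructor: (near-)exact ellipsoid surface model.

    Long axis along -z (apex at z = -c). For ``a == b`` the endocardial
    surface is exact (constant radial field); otherwise the field is
    interpolated on the spline grid. ``wall`` > 0 adds an epicardial
    ellipsoid with all semi-axes grown by ``wall``.
    """
    basis = TensorSplineBasis(*basis_order)
    k = c / a

    def lam(axes):
        aa, bb, cc = axes

        def f(mu, th):
            phi = np.pi * mu
            sp, cp = np.sin(phi), np.cos(phi)
            inv = (sp * np.cos(th) / aa) ** 2 + (sp * np.sin(th) / bb) ** 2 \
                + (k * cp / cc) ** 2
            return 1.0 / np.sqrt(inv)
        return f

    ce = basis.interpolate(lam((a, b, c)))
    cp = basis.interpolate(lam((a + wall, b + wall, c + wall))) if wall > 0 \
        else ce.copy()
    axis = np.array([0.0, 0.0, -1.0])
    u1 = np.array([1.0, 0.0, 0.0])
    return LVSurfaceModel(
        axis_origin=np.asarray(center, dtype=float),
        axis_direction=axis,
        transverse_u=u1,
        transverse_v=np.cross(axis, u1),   # right-handed (u1, u2, axis)
        elongation=k,
        coeffs_endo=ce, coeffs_epi=cp, basis_order=basis_order)


def truncated_ellipsoid_volume(a: float, b: float, c: float, h: float) -> float:
    """Closed-form volume of an ellipsoid truncated at height h above center.

    The region kept is z in [-c, h]; h in (-c, c].
    """
    if not -c < h <= c:
        raise ValueError("truncation height must lie within the ellipsoid")
    return np.pi * a * b * ((h + c) - (h ** 3 + c ** 3) / (3.0 * c ** 2))
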