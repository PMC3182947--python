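"""Tensor-product spline basis for radial LV surface fields.

The radial field lambda(mu, theta) of each ventricular surface is expanded in
a tensor product of

* clamped cubic B-splines in the longitudinal parameter mu in [0, 1]
  (apex pole at mu = 0, basal pole at mu = 1), via :class:`scipy.interpolate.BSpline`;
* uniform *periodic* cubic B-splines in the circumferential angle theta,
  evaluated in closed (truncated-power) cardinal form, because scipy exposes
  no periodic design-matrix evaluation.

Both bases are non-negative partitions of unity, so coefficient-wise bounds
(positivity, epicardial >= endocardial) transfer directly to the field.
"""
from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.interpolate import BSpline


def _cardinal_cubic(x: np.ndarray, der: int = 0) -> np.ndarray:
    """Cardinal cubic B-spline N(x) with knots 0..4 (support [0, 4])."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    # truncated-power expansion: N = (1/6) sum_k (-1)^k C(4,k) (x-k)_+^3
    binom = (1.0, -4.0, 6.0, -4.0, 1.0)
    p = 3 - der
    if p < 0:
        return out
    coef = 1.0
    for d in range(der):
        coef *= (3 - d)
    for k, b in enumerate(binom):
        t = np.clip(x - k, 0.0, None)
        out += b * t ** p
    return coef * out / 6.0


class TensorSplineBasis:
    """Clamped-cubic (mu) x periodic-cubic (theta) tensor basis.

    Parameters
    ----------
    n_mu, n_theta : int
        Number of basis functions (= control values) in each direction.
        ``n_mu >= 4``, ``n_theta >= 5``.
    """

    def __init__(self, n_mu: int, n_theta: int):
        if n_mu < 4:
            raise ValueError("n_mu must be >= 4 for a cubic basis")
        if n_theta < 5:
            raise ValueError("n_theta must be >= 5 for a periodic cubic basis")
        self.n_mu = int(n_mu)
        self.n_theta = int(n_theta)
        # clamped knot vector on [0, 1] with n_mu - 4 interior knots
        interior = np.linspace(0.0, 1.0, n_mu - 2)[1:-1]
        self.knots_mu = np.concatenate([np.zeros(4), interior, np.ones(4)])
        self._mu_splines: dict[int, list[BSpline]] = {}
        self._h_theta = 2.0 * np.pi / n_theta

    # -- 1D design matrices -------------------------------------------------
    def _mu_basis(self, der: int) -> list[BSpline]:
        if der not in self._mu_splines:
            base = []
            for j in range(self.n_mu):
                c = np.zeros(self.n_mu)
                c[j] = 1.0
                s = BSpline(self.knots_mu, c, 3, extrapolate=False)
                base.append(s.derivative(der) if der else s)
            self._mu_splines[der] = base
        return self._mu_splines[der]

    def mu_design(self, mu: np.ndarray, der: int = 0) -> np.ndarray:
        """(npts, n_mu) design matrix of the mu basis (derivative ``der``)."""
        mu = np.clip(np.asarray(mu, dtype=float), 0.0, 1.0)
        if der == 0:
            return BSpline.design_matrix(mu, self.knots_mu, 3).toarray()
        cols = [s(mu) for s in self._mu_basis(der)]
        out = np.stack(cols, axis=-1)
        return np.nan_to_num(out)

    def theta_design(self, theta: np.ndarray, der: int = 0) -> np.ndarray:
        """(npts, n_theta) design matrix of the periodic theta basis."""
        theta = np.asarray(theta, dtype=float)
        h, n = self._h_theta, self.n_theta
        # basis j is the cardinal spline centred at theta = j*h, wrapped
        s = (theta[..., None] / h - np.arange(n)[None, :] + 2.0) % n
        vals = _cardinal_cubic(s, der)
        return vals / h ** der

    # -- field evaluation ---------------------------------------------------
    def evaluate(self, coeffs: np.ndarray, mu: np.ndarray, theta: np.ndarray,
                 dmu: int = 0, dtheta: int = 0) -> np.ndarray:
        """Evaluate lambda (or a partial derivative) at paired (mu, theta)."""
        mu = np.atleast_1d(np.asarray(mu, dtype=float))
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        B = self.mu_design(mu.ravel(), dmu)
        C = self.theta_design(theta.ravel(), dtheta)
        vals = np.einsum("pi,ij,pj->p", B, coeffs, C)
        return vals.reshape(mu.shape)

    # -- interpolation (used by the phantom generator) ----------------------
    def greville_mu(self) -> np.ndarray:
        t = self.knots_mu
        return np.array([t[j + 1:j + 4].mean() for j in range(self.n_mu)])

    def theta_nodes(self) -> np.ndarray:
        return np.arange(self.n_theta) * self._h_theta

    def interpolate(self, fn) -> np.ndarray:
        """Coefficient grid whose spline interpolates ``fn(mu, theta)``.

        Collocation at Greville abscissae (mu) x uniform nodes (theta).
        """
        gm = self.greville_mu()
        gt = self.theta_nodes()
        Bm = self.mu_design(gm)                       # (n_mu, n_mu)
        Ct = self.theta_design(gt)                    # (n_theta, n_theta)
        M, T = np.meshgrid(gm, gt, indexing="ij")
        V = np.asarray(fn(M, T), dtype=float)
        # solve Bm @ C @ Ct.T = V
        tmp = np.linalg.solve(Bm, V)
        return np.linalg.solve(Ct, tmp.T).T

    # -- smoothing penalty matrices ------------------------------------------
    @lru_cache(maxsize=4)
    def penalty_matrices(self, n_qmu: int = 32, n_qtheta: int = 64):
        """Quadrature approximations of the integrated squared derivative forms.

        Returns ``(P1, P2)`` acting on the flattened coefficient grid, with
        ``c' P1 c = int (l_mu^2 + l_th^2)`` and
        ``c' P2 c = int (l_mumu^2 + 2 l_muth^2 + l_thth^2)``.
        """
        # Gauss-Legendre in mu, uniform (trapezoid on periodic) in theta
        qx, qw = np.polynomial.legendre.leggauss(n_qmu)
        mu = 0.5 * (qx + 1.0)
        wmu = 0.5 * qw
        th = np.arange(n_qtheta) * 2.0 * np.pi / n_qtheta
        wth = np.full(n_qtheta, 2.0 * np.pi / n_qtheta)

        B = {d: self.mu_design(mu, d) for d in (0, 1, 2)}
        C = {d: self.theta_design(th, d) for d in (0, 1, 2)}

        def quad_form(dm, dt, factor=1.0):
            Gm = (B[dm] * wmu[:, None]).T @ B[dm]
            Gt = (C[dt] * wth[:, None]).T @ C[dt]
            return factor * np.kron(Gm, Gt)

        P1 = quad_form(1, 0) + quad_form(0, 1)
        P2 = quad_form(2, 0) + quad_form(1, 1, 2.0) + quad_form(0, 2)
        return P1, P2

    def pole_tie_matrix(self) -> np.ndarray:
        """Map reduced coefficients -> full grid with both pole rows tied.

        Tying the first and last mu rows of the coefficient grid to single
        values closes the surface at the apex (single apex point) and at the
        basal pole of the parameterization.
        """
        n_mu, n_th = self.n_mu, self.n_theta
        n_red = 2 + (n_mu - 2) * n_th
        T = np.zeros((n_mu * n_th, n_red))
        for j in range(n_th):
            T[j, 0] = 1.0                               # apex row
            T[(n_mu - 1) * n_th + j, 1] = 1.0           # basal-pole row
        for i in range(1, n_mu - 1):
            for j in range(n_th):
                T[i * n_th + j, 2 + (i - 1) * n_th + j] = 1.0
        return T
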