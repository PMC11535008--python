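"""Neumann Green's functions of the modified Helmholtz equation.

For a bounded domain Omega with reflecting outer boundary, the Green's
function G(x, x'; s) solves

    D lap G - (gamma0 + s) G = -delta(x - x'),   n . grad G = 0 on dOmega,

normalised so that the integral of G over Omega equals 1/(gamma0 + s).
When the bulk degradation rate vanishes the steady problem is only defined
up to a constant and the pseudo (generalised Neumann) Green's function G0
is used instead,

    D lap G0 = 1/|Omega| - delta(x - x'),  n . grad G0 = 0,  int G0 = 0.

Four geometries are supported: the unit disk and unit sphere (separable
series in modified Bessel / modified spherical Bessel functions, with
closed-form pseudo-Green's functions), and rectangles / boxes (Ewald-split
method of images: a Gaussian-screened short-range image sum plus a rapidly
converging cosine eigenfunction sum).  The derivative H = dG/ds at s = 0,
needed by accumulation-time formulas, is computed term-wise analytically.

All evaluators are vectorised over the first argument.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special as sp

EULER_GAMMA = float(np.euler_gamma)

_GEOMETRIES_2D = ("disk2d", "rect2d")
_GEOMETRIES_3D = ("sphere3d", "box3d")
_GEOMETRIES = _GEOMETRIES_2D + _GEOMETRIES_3D


class GeometryError(ValueError):
    """Unsupported or invalid domain geometry."""


class CoincidentPointsError(ValueError):
    """G(x, x) is singular; use the regular part instead."""


@dataclass(frozen=True)
class DomainSpec:
    """Bulk domain: geometry, diffusivity D, degradation gamma0, source I0.

    Lengths are measured in units of the smallest inscribed dimension,
    so the disk/sphere radius is 1 and the smallest rectangle/box side is 1.
    """

    kind: str
    size: tuple = (1.0,)
    D: float = 1.0
    gamma0: float = 0.0
    I0: float = 0.0

    def __post_init__(self):
        if self.kind not in _GEOMETRIES:
            raise GeometryError(
                f"geometry not implemented: {self.kind!r} (supported: {_GEOMETRIES})"
            )
        size = tuple(float(v) for v in np.atleast_1d(np.asarray(self.size, dtype=float)))
        object.__setattr__(self, "size", size)
        if any(v <= 0 for v in size):
            raise ValueError("all size parameters must be strictly positive")
        if self.kind in ("disk2d", "sphere3d"):
            if len(size) != 1 or abs(size[0] - 1.0) > 1e-12:
                raise ValueError(f"{self.kind} requires unit radius (L = 1 normalisation)")
        else:
            want = 2 if self.kind == "rect2d" else 3
            if len(size) != want:
                raise ValueError(f"{self.kind} requires {want} side lengths")
            if abs(min(size) - 1.0) > 1e-12:
                raise ValueError("smallest side must equal 1 (L = 1 normalisation)")
        if self.D <= 0:
            raise ValueError("diffusivity D must be positive")
        if self.gamma0 < 0:
            raise ValueError("degradation rate gamma0 must be >= 0")

    @property
    def dim(self) -> int:
        return 2 if self.kind in _GEOMETRIES_2D else 3

    @property
    def volume(self) -> float:
        if self.kind == "disk2d":
            return float(np.pi)
        if self.kind == "sphere3d":
            return float(4.0 * np.pi / 3.0)
        return float(np.prod(self.size))

    def contains(self, x, slack: float = 0.0) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if self.kind in ("disk2d", "sphere3d"):
            return np.linalg.norm(x, axis=-1) <= 1.0 + slack
        lo = -slack
        hi = np.asarray(self.size) + slack
        return np.all((x >= lo) & (x <= hi), axis=-1)

    def boundary_distance(self, x) -> np.ndarray:
        """Distance from interior point(s) to the outer boundary."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if self.kind in ("disk2d", "sphere3d"):
            return 1.0 - np.linalg.norm(x, axis=-1)
        sides = np.asarray(self.size)
        return np.minimum(x, sides - x).min(axis=-1)

    def ray_extent(self, center, directions) -> np.ndarray:
        """Distance from `center` to the boundary along unit `directions`.

        Used by the singularity-adapted quadrature; requires convexity,
        which all supported geometries satisfy.
        """
        c = np.asarray(center, dtype=float)
        e = np.atleast_2d(np.asarray(directions, dtype=float))
        if self.kind in ("disk2d", "sphere3d"):
            ce = e @ c
            return -ce + np.sqrt(np.maximum(ce**2 + 1.0 - c @ c, 0.0))
        sides = np.asarray(self.size)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_hi = np.where(e > 0, (sides - c) / e, np.inf)
            t_lo = np.where(e < 0, -c / e, np.inf)
        return np.minimum(t_hi, t_lo).min(axis=-1)


# ---------------------------------------------------------------------------
# quadrature adapted to the Green's function point singularity
# ---------------------------------------------------------------------------

def _graded_radial_nodes(n_seg: int = 5, n_per: int = 12, ratio: float = 0.15):
    """Composite Gauss-Legendre nodes on [0, 1], graded toward 0."""
    gl_x, gl_w = np.polynomial.legendre.leggauss(n_per)
    edges = [1.0]
    for _ in range(n_seg - 1):
        edges.append(edges[-1] * ratio)
    edges.append(0.0)
    edges = edges[::-1]
    nodes, weights = [], []
    for a, b in zip(edges[:-1], edges[1:]):
        nodes.append(0.5 * (b - a) * gl_x + 0.5 * (a + b))
        weights.append(0.5 * (b - a) * gl_w)
    return np.concatenate(nodes), np.concatenate(weights)


def _duffy_rect(c, sides, t, wt, n_gl):
    """Duffy panels for a rectangle: 4 triangles from c to each edge."""
    u, wu = np.polynomial.legendre.leggauss(n_gl)
    u = 0.5 * (u + 1.0)
    wu = 0.5 * wu
    Lx, Ly = sides
    corners = np.array([[0.0, 0.0], [Lx, 0.0], [Lx, Ly], [0.0, Ly]])
    pts, wts = [], []
    for k in range(4):
        A = corners[k] - c
        B = corners[(k + 1) % 4] - c
        cross = abs(A[0] * B[1] - A[1] * B[0])
        if cross < 1e-14:
            continue
        # x = c + t (A + u (B - A)); Jacobian = t |A x B|
        edge = A[None, :] + u[:, None] * (B - A)[None, :]
        p = c[None, None, :] + t[None, :, None] * edge[:, None, :]
        w = cross * (wu[:, None] * (wt * t)[None, :])
        pts.append(p.reshape(-1, 2))
        wts.append(w.ravel())
    return np.concatenate(pts), np.concatenate(wts)


def _duffy_box(c, sides, t, wt, n_gl):
    """Duffy panels for a box: 6 pyramids from c to each face."""
    u, wu = np.polynomial.legendre.leggauss(n_gl)
    u = 0.5 * (u + 1.0)
    wu = 0.5 * wu
    pts, wts = [], []
    for axis in range(3):
        for face_val in (0.0, sides[axis]):
            o1, o2 = [a for a in range(3) if a != axis]
            # face corner and spanning edges, relative to c
            F0 = -c.copy()
            F0[axis] = face_val - c[axis]
            e1 = np.zeros(3)
            e1[o1] = sides[o1]
            e2 = np.zeros(3)
            e2[o2] = sides[o2]
            jac0 = abs(F0 @ np.cross(e1, e2))
            if jac0 < 1e-14:
                continue
            q = (F0[None, None, :] + u[:, None, None] * e1[None, None, :]
                 + u[None, :, None] * e2[None, None, :])
            p = c[None, None, None, :] + t[None, None, :, None] * q[:, :, None, :]
            w = jac0 * (wu[:, None, None] * wu[None, :, None]
                        * (wt * t**2)[None, None, :])
            pts.append(p.reshape(-1, 3))
            wts.append(w.ravel())
    return np.concatenate(pts), np.concatenate(wts)


def singular_quadrature(domain: DomainSpec, center, n_ang: int = 96,
                        n_rad_seg: int = 5, n_rad_per: int = 14):
    """Nodes/weights for integrating f over Omega when f is singular at `center`.

    Disk/sphere: polar (spherical) coordinates about the singular point, whose
    Jacobian r^(d-1) tames the -log r and 1/r Green's singularities; the
    angular radial extent is smooth, so uniform angles converge spectrally.
    Rectangle/box: Duffy decomposition into triangles (pyramids) from the
    singular point to each face, which keeps every panel integrand smooth in
    the angular variables.  Returns (points, weights).
    """
    c = np.asarray(center, dtype=float)
    t, wt = _graded_radial_nodes(n_rad_seg, n_rad_per)
    if domain.kind == "rect2d":
        return _duffy_rect(c, np.asarray(domain.size), t, wt, max(n_ang // 3, 16))
    if domain.kind == "box3d":
        return _duffy_box(c, np.asarray(domain.size), t, wt, max(n_ang // 5, 12))
    if domain.dim == 2:
        theta = 2.0 * np.pi * np.arange(n_ang) / n_ang
        dirs = np.stack([np.cos(theta), np.sin(theta)], axis=-1)
        w_ang = np.full(n_ang, 2.0 * np.pi / n_ang)
    else:
        mu, w_mu = np.polynomial.legendre.leggauss(max(n_ang // 4, 12))
        phi = 2.0 * np.pi * np.arange(n_ang) / n_ang
        mu_g, phi_g = np.meshgrid(mu, phi, indexing="ij")
        sin_t = np.sqrt(1.0 - mu_g**2)
        dirs = np.stack(
            [sin_t * np.cos(phi_g), sin_t * np.sin(phi_g), mu_g], axis=-1
        ).reshape(-1, 3)
        w_ang = (w_mu[:, None] * np.full(n_ang, 2.0 * np.pi / n_ang)[None, :]).ravel()
    rmax = domain.ray_extent(c, dirs)
    r = rmax[:, None] * t[None, :]
    w_r = rmax[:, None] * wt[None, :]
    pts = c[None, None, :] + r[..., None] * dirs[:, None, :]
    jac = r ** (domain.dim - 1)
    w = (w_ang[:, None] * w_r * jac).ravel()
    return pts.reshape(-1, domain.dim), w


# ---------------------------------------------------------------------------
# provider base
# ---------------------------------------------------------------------------

def _as_points(x, dim):
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[-1] != dim:
        raise ValueError(f"points must have dimension {dim}")
    return x, scalar


class GreensProvider:
    """Evaluator bundle for one domain geometry.

    Methods
    -------
    G(x, x0, s)   : Green's function at rate gamma0 + s  (gamma0 + s > 0)
    R(x0, s)      : regular part at coincidence, R(x0, x0; s)
    G0(x, x0)     : pseudo-Green's function (zero-degradation branch)
    R0(x0)        : its regular part at coincidence
    H(x, x0)      : dG/ds at s = 0          (gamma0 > 0 only)
    Hreg(x0)      : dR(x0, x0; s)/ds at s=0 (gamma0 > 0 only)
    """

    def __init__(self, domain: DomainSpec, tol: float = 1e-10,
                 boundary_margin: float = 1e-3):
        self.domain = domain
        self.tol = float(tol)
        self.boundary_margin = float(boundary_margin)

    # -- argument checking ---------------------------------------------------

    def _check_rate(self, s):
        if self.domain.gamma0 + s <= 0:
            raise ValueError(
                "gamma0 + s must be positive; use the pseudo-Green's branch "
                "(G0/R0) for the zero-degradation problem"
            )
        return np.sqrt((self.domain.gamma0 + s) / self.domain.D)

    def _check_pole(self):
        if self.domain.gamma0 <= 0:
            raise ValueError(
                "pole at s=0: accumulation-time branch unsupported for gamma0=0"
            )

    def _check_interior(self, x0):
        d = self.domain.boundary_distance(x0)
        if np.any(d < self.boundary_margin):
            raise ValueError(
                "regular part requested within the boundary margin "
                f"({self.boundary_margin:g}); compartments must be O(1) from dOmega"
            )

    def _check_separation(self, x, x0):
        d = np.linalg.norm(np.atleast_2d(x) - np.asarray(x0), axis=-1)
        if np.any(d < 1e-13):
            raise CoincidentPointsError("coincident points: use regular part")
        return d

    # subclasses implement _G, _R, _G0, _R0, _H, _Hreg

    def G(self, x, x0, s: float = 0.0):
        beta = self._check_rate(s)
        x, scalar = _as_points(x, self.domain.dim)
        x0 = np.asarray(x0, dtype=float)
        self._check_separation(x, x0)
        out = self._G(x, x0, beta)
        return float(out[0]) if scalar else out

    def R(self, x0, s: float = 0.0) -> float:
        beta = self._check_rate(s)
        x0 = np.asarray(x0, dtype=float)
        self._check_interior(x0)
        return float(self._R(x0, beta))

    def G0(self, x, x0):
        x, scalar = _as_points(x, self.domain.dim)
        x0 = np.asarray(x0, dtype=float)
        self._check_separation(x, x0)
        out = self._G0(x, x0)
        return float(out[0]) if scalar else out

    def R0(self, x0) -> float:
        x0 = np.asarray(x0, dtype=float)
        self._check_interior(x0)
        return float(self._R0(x0))

    def H(self, x, x0):
        self._check_pole()
        beta = self._check_rate(0.0)
        x, scalar = _as_points(x, self.domain.dim)
        x0 = np.asarray(x0, dtype=float)
        self._check_separation(x, x0)
        out = self._H(x, x0, beta)
        return float(out[0]) if scalar else out

    def Hreg(self, x0) -> float:
        self._check_pole()
        beta = self._check_rate(0.0)
        x0 = np.asarray(x0, dtype=float)
        self._check_interior(x0)
        return float(self._Hreg(x0, beta))

    # finite-difference cross-check used by the test-suite
    def H_fd(self, x, x0, h: float = 1e-4):
        """Richardson-extrapolated central difference of G in s."""
        self._check_pole()

        def cd(step):
            return (self.G(x, x0, s=step) - self.G(x, x0, s=-step)) / (2.0 * step)

        d1, d2 = cd(h), cd(h / 2.0)
        return (4.0 * d2 - d1) / 3.0


# ---------------------------------------------------------------------------
# unit disk (2D): modified-Bessel series; closed-form pseudo-Green's function
# ---------------------------------------------------------------------------

class DiskGreens(GreensProvider):
    """Unit disk.  G = K0 free-space term plus an I_n reflection series.

    G(x,x';s) = (1/2piD) [ K0(beta d)
                + sum_n sigma_n c_n(beta) I_n(beta r) I_n(beta r') cos n dtheta ]
    with c_n = -K_n'(beta)/I_n'(beta), enforcing the no-flux condition at r=1.
    """

    _NMAX = 320

    def _series_orders(self, rr):
        # geometric decay ~ (r r')^n; keep a safety margin over self.tol
        rr = min(max(rr, 1e-3), 0.999999)
        n = int(np.ceil(np.log(self.tol * 1e-3) / np.log(rr))) + 8
        return np.arange(0, min(max(n, 24), self._NMAX))

    @staticmethod
    def _bessel_pair(n, z):
        iv = sp.iv(n, z)
        kv = sp.kv(n, z)
        ivp = sp.ivp(n, z)
        kvp = sp.kvp(n, z)
        return iv, kv, ivp, kvp

    def _polar(self, x, x0):
        r = np.linalg.norm(x, axis=-1)
        r0 = float(np.linalg.norm(x0))
        th = np.arctan2(x[:, 1], x[:, 0])
        th0 = float(np.arctan2(x0[1], x0[0]))
        return r, r0, th - th0

    def _reflection_series(self, beta, r, r0, dth, deriv=False):
        """sum_n sigma_n c_n I_n(beta r) I_n(beta r0) cos(n dth), optionally
        its beta-derivative.

        Exact Bessel terms are summed up to the order where they can be
        evaluated in double precision; beyond that the terms approach their
        rate-independent large-order limit (r r0)^n cos(n dth)/n, whose sum
        has the closed log form, so the tail is added analytically.
        """
        n = self._series_orders(np.max(r) * max(r0, 1e-6))
        nf = n.astype(float)
        sigma = np.where(n == 0, 1.0, 2.0)
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            _, _, ivp_b, kvp_b = self._bessel_pair(n, beta)
            c = -kvp_b / ivp_b
            i_r = sp.iv(n[None, :], beta * r[:, None])
            i_r0 = sp.iv(n, beta * r0)[None, :]
            term = sigma[None, :] * c[None, :] * i_r * i_r0
        good = np.isfinite(c) & np.isfinite(i_r0[0]) & np.isfinite(term).all(axis=0)
        cosn = np.cos(n[None, :] * dth[:, None])
        val = (np.where(good[None, :], term, 0.0) * cosn).sum(axis=1)
        # analytic tail over the orders not summed exactly, using the
        # rate-independent large-order form t^n cos(n dth)/n
        t = np.clip(r * r0, 0.0, 1.0 - 1e-15)
        full = -0.5 * np.log1p(t * (t - 2.0 * np.cos(dth)))
        inv_n = np.where(nf > 0, 1.0 / np.maximum(nf, 1.0), 0.0)
        partial = (np.where(good, inv_n, 0.0)[None, :]
                   * (t[:, None] ** nf[None, :]) * cosn).sum(axis=1)
        val = val + (full - partial)
        if not deriv:
            return val
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            iv_b = sp.iv(n, beta)
            kv_b = sp.kv(n, beta)
            # second derivatives from the modified Bessel ODE
            ipp = iv_b * (1.0 + nf**2 / beta**2) - ivp_b / beta
            kpp = kv_b * (1.0 + nf**2 / beta**2) - kvp_b / beta
            cp = -(kpp * ivp_b - kvp_b * ipp) / ivp_b**2
            ip_r = sp.ivp(n[None, :], beta * r[:, None])
            ip_r0 = sp.ivp(n, beta * r0)[None, :]
            dterm = (cp[None, :] * i_r * i_r0
                     + c[None, :] * (r[:, None] * ip_r * i_r0
                                     + r0 * i_r * ip_r0)) * sigma[None, :]
        # large-order terms are beta-independent, so the derivative tail
        # vanishes; truncating at n_stop is enough
        dgood = good & np.isfinite(cp)
        dval = (np.where(dgood[None, :], dterm, 0.0) * cosn).sum(axis=1)
        return val, dval

    def _G(self, x, x0, beta):
        D = self.domain.D
        d = np.linalg.norm(x - x0, axis=-1)
        r, r0, dth = self._polar(x, x0)
        ser = self._reflection_series(beta, r, r0, dth)
        return (sp.kv(0, beta * d) + ser) / (2.0 * np.pi * D)

    def _R(self, x0, beta):
        D = self.domain.D
        r0 = float(np.linalg.norm(x0))
        ser = self._reflection_series(beta, np.array([r0]), r0, np.zeros(1))[0]
        return (-np.log(beta / 2.0) - EULER_GAMMA + ser) / (2.0 * np.pi * D)

    def _G0(self, x, x0):
        D = self.domain.D
        d = np.linalg.norm(x - x0, axis=-1)
        r2 = (x**2).sum(axis=-1)
        r02 = float(x0 @ x0)
        img = r2 * r02 - 2.0 * (x @ x0) + 1.0  # |x'|^2 |x - x'/|x'|^2|^2
        return (
            -np.log(d) - 0.5 * np.log(img) + 0.5 * (r2 + r02) - 0.75
        ) / (2.0 * np.pi * D)

    def _R0(self, x0):
        D = self.domain.D
        r02 = float(x0 @ x0)
        return (-np.log(1.0 - r02) + r02 - 0.75) / (2.0 * np.pi * D)

    def _H(self, x, x0, beta):
        D = self.domain.D
        d = np.linalg.norm(x - x0, axis=-1)
        r, r0, dth = self._polar(x, x0)
        _, dser = self._reflection_series(beta, r, r0, dth, deriv=True)
        dfree = -d * sp.kv(1, beta * d)
        # dG/ds = (dG/dbeta) * dbeta/ds, dbeta/ds = 1/(2 D beta)
        return (dfree + dser) / (2.0 * np.pi * D) / (2.0 * D * beta)

    def _Hreg(self, x0, beta):
        D = self.domain.D
        r0 = float(np.linalg.norm(x0))
        _, dser = self._reflection_series(
            beta, np.array([r0]), r0, np.zeros(1), deriv=True
        )
        return (-1.0 / beta + dser[0]) / (2.0 * np.pi * D) / (2.0 * D * beta)


# ---------------------------------------------------------------------------
# unit sphere (3D): modified spherical Bessel series; closed-form G0
# ---------------------------------------------------------------------------

class SphereGreens(GreensProvider):
    """Unit sphere.

    G(x,x';s) = e^{-beta d}/(4 pi D d)
              + (beta/4 pi D) sum_n (2n+1) a_n i_n(beta r) i_n(beta r') P_n(mu)
    with a_n = -k_n'(beta)/i_n'(beta) and mu the cosine of the angle between
    x and x'.  The pseudo-Green's function has the closed form assembled from
    the generating functions of P_n.
    """

    _NMAX = 320

    def _series_orders(self, rr):
        rr = min(max(rr, 1e-3), 0.999999)
        n = int(np.ceil(np.log(self.tol * 1e-3) / np.log(rr))) + 8
        return np.arange(0, min(max(n, 24), self._NMAX))

    @staticmethod
    def _legendre_table(nmax, mu):
        """P_n(mu) for n = 0..nmax-1, vectorised over mu (recurrence)."""
        P = np.empty((nmax, mu.size))
        P[0] = 1.0
        if nmax > 1:
            P[1] = mu
        for n in range(1, nmax - 1):
            P[n + 1] = ((2 * n + 1) * mu * P[n] - n * P[n - 1]) / (n + 1)
        return P

    def _angles(self, x, x0):
        r = np.linalg.norm(x, axis=-1)
        r0 = float(np.linalg.norm(x0))
        denom = np.where(r * r0 > 0, r * r0, 1.0)
        mu = np.clip((x @ x0) / denom, -1.0, 1.0)
        return r, r0, mu

    def _reflection_series(self, beta, r, r0, mu, deriv=False):
        """Reflection series with an analytic large-order tail.

        Beyond the exactly summed orders the terms approach the
        rate-independent limit ((n+1)/n) t^n P_n(mu) with t = r r0, whose
        sum has a closed form from the Legendre generating functions.
        """
        n = self._series_orders(np.max(r) * max(r0, 1e-6))
        nn = n.astype(float)
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            i_b = sp.spherical_in(n, beta)
            k_b = sp.spherical_kn(n, beta)
            ip_b = sp.spherical_in(n, beta, derivative=True)
            kp_b = sp.spherical_kn(n, beta, derivative=True)
            a = -kp_b / ip_b
            i_r = sp.spherical_in(n[None, :], beta * r[:, None])
            i_r0 = sp.spherical_in(n, beta * r0)[None, :]
            # scipy's k_n carries a pi/2 factor relative to e^-z/z; the
            # addition theorem for e^{-beta d}/d then brings in 2/pi
            w = (2.0 / np.pi) * (2.0 * nn + 1.0)
            term = beta * w[None, :] * a[None, :] * i_r * i_r0
        good = np.isfinite(a) & np.isfinite(i_r0[0]) & np.isfinite(term).all(axis=0)
        P = self._legendre_table(n.size, mu).T  # (npts, n)
        val = (np.where(good[None, :], term, 0.0) * P).sum(axis=1)
        t = np.clip(r * r0, 0.0, 1.0 - 1e-15)
        q = np.sqrt(np.maximum(1.0 - 2.0 * t * mu + t**2, 1e-300))
        full = 1.0 / q - 1.0 - np.log(0.5 * (1.0 - t * mu + q))
        coef = np.where(nn > 0, (nn + 1.0) / np.maximum(nn, 1.0), 0.0)
        partial = (np.where(good, coef, 0.0)[None, :]
                   * (t[:, None] ** nn[None, :]) * P).sum(axis=1)
        val = val + (full - partial)
        if not deriv:
            return val
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            ipp = i_b * (1.0 + nn * (nn + 1.0) / beta**2) - 2.0 * ip_b / beta
            kpp = k_b * (1.0 + nn * (nn + 1.0) / beta**2) - 2.0 * kp_b / beta
            ap = -(kpp * ip_b - kp_b * ipp) / ip_b**2
            ip_r = sp.spherical_in(n[None, :], beta * r[:, None],
                                   derivative=True)
            ip_r0 = sp.spherical_in(n, beta * r0, derivative=True)[None, :]
            # d/dbeta of  beta a_n i_n(beta r) i_n(beta r0); the large-order
            # terms are beta-independent so the derivative tail vanishes
            dterm = w[None, :] * (
                a[None, :] * i_r * i_r0
                + beta
                * (
                    ap[None, :] * i_r * i_r0
                    + a[None, :] * (r[:, None] * ip_r * i_r0 + r0 * i_r * ip_r0)
                )
            )
        dgood = good & np.isfinite(ap)
        dval = (np.where(dgood[None, :], dterm, 0.0) * P).sum(axis=1)
        return val, dval

    def _G(self, x, x0, beta):
        D = self.domain.D
        d = np.linalg.norm(x - x0, axis=-1)
        r, r0, mu = self._angles(x, x0)
        ser = self._reflection_series(beta, r, r0, mu)
        return (np.exp(-beta * d) / d + ser) / (4.0 * np.pi * D)

    def _R(self, x0, beta):
        D = self.domain.D
        r0 = float(np.linalg.norm(x0))
        ser = self._reflection_series(beta, np.array([r0]), r0, np.ones(1))[0]
        return (-beta + ser) / (4.0 * np.pi * D)

    def _G0(self, x, x0):
        D = self.domain.D
        d = np.linalg.norm(x - x0, axis=-1)
        r2 = (x**2).sum(axis=-1)
        r02 = float(x0 @ x0)
        dot = x @ x0
        q = np.sqrt(np.maximum(r2 * r02 - 2.0 * dot + 1.0, 1e-300))
        return (
            1.0 / d
            + 1.0 / q
            - 1.0
            - np.log(0.5 * (1.0 - dot + q))
            + 0.5 * (r2 + r02)
            - 9.0 / 5.0
        ) / (4.0 * np.pi * D)

    def _R0(self, x0):
        D = self.domain.D
        r02 = float(x0 @ x0)
        return (
            1.0 / (1.0 - r02)
            - 1.0
            - np.log(1.0 - r02)
            + r02
            - 9.0 / 5.0
        ) / (4.0 * np.pi * D)

    def _H(self, x, x0, beta):
        D = self.domain.D
        d = np.linalg.norm(x - x0, axis=-1)
        r, r0, mu = self._angles(x, x0)
        _, dser = self._reflection_series(beta, r, r0, mu, deriv=True)
        dfree = -np.exp(-beta * d)
        return (dfree + dser) / (4.0 * np.pi * D) / (2.0 * D * beta)

    def _Hreg(self, x0, beta):
        D = self.domain.D
        r0 = float(np.linalg.norm(x0))
        _, dser = self._reflection_series(beta, np.array([r0]), r0, np.ones(1),
                                          deriv=True)
        return (-1.0 + dser[0]) / (4.0 * np.pi * D) / (2.0 * D * beta)


# ---------------------------------------------------------------------------
# rectangle / box: Ewald split
# ---------------------------------------------------------------------------

def _phi_short_2d(z0, b2eta, n_seg: int = 24, n_per: int = 10):
    """(1/4pi) * int_0^inf exp(-z0 e^v - b2eta e^-v) dv  (vectorised in z0).

    This is the short-range Ewald kernel of the 2D screened Laplacian,
    phi(r) = (1/4pi) int_0^eta exp(-beta^2 t - r^2/4t) dt/t, written with
    z0 = r^2/(4 eta) and b2eta = beta^2 eta.  The integrand is analytic and
    decays doubly exponentially; composite Gauss-Legendre panels resolve it
    to near machine precision.
    """
    z0 = np.atleast_1d(np.asarray(z0, dtype=float))
    vmax = np.log(45.0 / np.minimum(z0, 1.0))
    vmax = np.maximum(vmax, 4.0)
    gl_x, gl_w = np.polynomial.legendre.leggauss(n_per)
    edges = np.linspace(0.0, 1.0, n_seg + 1)
    out = np.zeros_like(z0)
    for a, b in zip(edges[:-1], edges[1:]):
        # panel [a, b] in units of vmax (per-point panel lengths)
        va = a * vmax
        vb = b * vmax
        half = 0.5 * (vb - va)
        mid = 0.5 * (vb + va)
        v = mid[:, None] + half[:, None] * gl_x[None, :]
        f = np.exp(-z0[:, None] * np.exp(v) - b2eta * np.exp(-v))
        out += (half[:, None] * (f * gl_w[None, :])).sum(axis=1)
    return out / (4.0 * np.pi)


def _psi_short_2d(z0, b2eta, eta, n_seg: int = 24, n_per: int = 10):
    """int_0^eta exp(-beta^2 t - r^2/4t) dt, same substitution as above."""
    z0 = np.atleast_1d(np.asarray(z0, dtype=float))
    vmax = np.log(45.0 / np.minimum(z0, 1.0))
    vmax = np.maximum(vmax, 4.0)
    gl_x, gl_w = np.polynomial.legendre.leggauss(n_per)
    edges = np.linspace(0.0, 1.0, n_seg + 1)
    out = np.zeros_like(z0)
    for a, b in zip(edges[:-1], edges[1:]):
        va = a * vmax
        vb = b * vmax
        half = 0.5 * (vb - va)
        mid = 0.5 * (vb + va)
        v = mid[:, None] + half[:, None] * gl_x[None, :]
        f = np.exp(-v - z0[:, None] * np.exp(v) - b2eta * np.exp(-v))
        out += (half[:, None] * (f * gl_w[None, :])).sum(axis=1)
    return eta * out


class _EwaldGreens(GreensProvider):
    """Shared Ewald machinery for rect2d and box3d."""

    def __init__(self, domain, tol=1e-10, boundary_margin=1e-3, eta=None,
                 kmax_exponent=32.0):
        super().__init__(domain, tol, boundary_margin)
        L = np.asarray(domain.size, dtype=float)
        self.L = L
        self.eta = float(eta) if eta is not None else (min(L) / 6.0) ** 2
        # real-space images: Gaussian factor exp(-r^2/4eta) below ~1e-14
        self.rcut = np.sqrt(4.0 * self.eta * 34.0)
        shifts = []
        nmax = np.ceil((self.rcut + L) / (2.0 * L)).astype(int)
        ranges = [np.arange(-n, n + 1) for n in nmax]
        mesh = np.meshgrid(*ranges, indexing="ij")
        shift_grid = np.stack([m.ravel() for m in mesh], axis=-1) * 2.0 * L
        signs = np.stack(
            np.meshgrid(*([np.array([1.0, -1.0])] * len(L)), indexing="ij"),
            axis=-1,
        ).reshape(-1, len(L))
        self._shifts = shift_grid
        self._signs = signs
        # k-space modes: exp(-eta lam) below ~1e-14
        lam_max = kmax_exponent / self.eta
        mmax = np.floor(np.sqrt(lam_max) * L / np.pi).astype(int)
        self._modes = [np.arange(0, m + 1) for m in mmax]

    def _images(self, x0):
        """Reflected/translated images of x0 that can reach the domain.

        Images farther than the Gaussian cutoff from every domain point
        contribute below the truncation tolerance and are dropped.
        """
        imgs = (self._signs[None, :, :] * x0[None, None, :]
                + self._shifts[:, None, :]).reshape(-1, len(self.L))
        center = self.L / 2.0
        reach = self.rcut + 0.5 * float(np.linalg.norm(self.L))
        keep = np.linalg.norm(imgs - center, axis=-1) <= reach
        return imgs[keep]

    def _ksum(self, x, x0, beta2, mode="value"):
        """Long-range cosine sum; mode in {value, deriv} (deriv = d/d beta^2)."""
        L = self.L
        vol = float(np.prod(L))
        axes_x, axes_x0, lams = [], [], []
        for d, m in enumerate(self._modes):
            km = m * np.pi / L[d]
            sig = np.where(m == 0, 1.0, 2.0)
            cx = np.cos(km[None, :] * x[:, d][:, None]) * np.sqrt(sig)[None, :]
            cx0 = np.cos(km * x0[d]) * np.sqrt(sig)
            axes_x.append(cx)
            axes_x0.append(cx0)
            lams.append(km**2)
        if len(L) == 2:
            lam = lams[0][:, None] + lams[1][None, :]
            denom = lam + beta2
            core = np.exp(-self.eta * denom) / denom
            if mode == "deriv":
                core = -core * (self.eta + 1.0 / denom)
            w0 = axes_x0[0][:, None] * axes_x0[1][None, :] * core
            out = np.einsum("pm,pn,mn->p", axes_x[0], axes_x[1], w0)
        else:
            lam = (lams[0][:, None, None] + lams[1][None, :, None]
                   + lams[2][None, None, :])
            denom = lam + beta2
            core = np.exp(-self.eta * denom) / denom
            if mode == "deriv":
                core = -core * (self.eta + 1.0 / denom)
            w0 = (axes_x0[0][:, None, None] * axes_x0[1][None, :, None]
                  * axes_x0[2][None, None, :] * core)
            out = np.einsum("pm,pn,pk,mnk->p", axes_x[0], axes_x[1], axes_x[2], w0)
        return out / vol


class RectGreens(_EwaldGreens):
    """Rectangle [0, Lx] x [0, Ly]."""

    def _short_sum(self, x, x0, beta2, drop_self=False, deriv=False):
        imgs = self._images(x0)
        diffs = x[:, None, :] - imgs[None, :, :]
        r2 = (diffs**2).sum(axis=-1)
        if drop_self:
            r2 = np.where(r2 < 1e-26, np.inf, r2)
        mask = r2 < self.rcut**2
        out = np.zeros(x.shape[0])
        if not np.any(mask):
            return out
        z0 = r2[mask] / (4.0 * self.eta)
        b2eta = beta2 * self.eta
        if deriv:
            vals = -_psi_short_2d(z0, b2eta, self.eta) / (4.0 * np.pi)
        else:
            vals = _phi_short_2d(z0, b2eta)
        acc = np.zeros_like(r2)
        acc[mask] = vals
        return acc.sum(axis=1)

    def _G(self, x, x0, beta):
        D = self.domain.D
        b2 = beta**2
        short = self._short_sum(x, x0, b2)
        longr = self._ksum(x, x0, b2)
        return (short + longr) / D

    def _R(self, x0, beta):
        D = self.domain.D
        b2 = beta**2
        x = x0[None, :]
        short = self._short_sum(x, x0, b2, drop_self=True)[0]
        longr = self._ksum(x, x0, b2)[0]
        self_term = (-np.log(beta / 2.0) - EULER_GAMMA) / (2.0 * np.pi) \
            - sp.exp1(self.eta * b2) / (4.0 * np.pi)
        return (self_term + short + longr) / D

    def _G0(self, x, x0):
        D = self.domain.D
        imgs = self._images(x0)
        diffs = x[:, None, :] - imgs[None, :, :]
        r2 = (diffs**2).sum(axis=-1)
        short = np.where(
            r2 < self.rcut**2, sp.exp1(r2 / (4.0 * self.eta)) / (4.0 * np.pi), 0.0
        ).sum(axis=1)
        longr = self._ksum_pseudo(x, x0)
        return (short + longr - self.eta / self.domain.volume) / D

    def _R0(self, x0):
        D = self.domain.D
        x = x0[None, :]
        imgs = self._images(x0)
        diffs = x[:, None, :] - imgs[None, :, :]
        r2 = (diffs**2).sum(axis=-1)
        r2 = np.where(r2 < 1e-26, np.inf, r2)
        short = np.where(
            r2 < self.rcut**2, sp.exp1(r2 / (4.0 * self.eta)) / (4.0 * np.pi), 0.0
        ).sum()
        self_term = (np.log(4.0 * self.eta) - EULER_GAMMA) / (4.0 * np.pi)
        longr = self._ksum_pseudo(x, x0)[0]
        return (self_term + short + longr - self.eta / self.domain.volume) / D

    def _ksum_pseudo(self, x, x0):
        L = self.L
        vol = float(np.prod(L))
        axes_x, axes_x0, lams = [], [], []
        for d, m in enumerate(self._modes):
            km = m * np.pi / L[d]
            sig = np.where(m == 0, 1.0, 2.0)
            axes_x.append(np.cos(km[None, :] * x[:, d][:, None])
                          * np.sqrt(sig)[None, :])
            axes_x0.append(np.cos(km * x0[d]) * np.sqrt(sig))
            lams.append(km**2)
        if len(L) == 2:
            lam = lams[0][:, None] + lams[1][None, :]
            with np.errstate(divide="ignore"):
                core = np.where(lam > 0, np.exp(-self.eta * lam) / np.where(lam > 0, lam, 1.0), 0.0)
            w0 = axes_x0[0][:, None] * axes_x0[1][None, :] * core
            out = np.einsum("pm,pn,mn->p", axes_x[0], axes_x[1], w0)
        else:
            lam = (lams[0][:, None, None] + lams[1][None, :, None]
                   + lams[2][None, None, :])
            core = np.where(lam > 0, np.exp(-self.eta * lam) / np.where(lam > 0, lam, 1.0), 0.0)
            w0 = (axes_x0[0][:, None, None] * axes_x0[1][None, :, None]
                  * axes_x0[2][None, None, :] * core)
            out = np.einsum("pm,pn,pk,mnk->p", axes_x[0], axes_x[1], axes_x[2], w0)
        return out / vol

    def _H(self, x, x0, beta):
        D = self.domain.D
        b2 = beta**2
        short = self._short_sum(x, x0, b2, deriv=True)
        longr = self._ksum(x, x0, b2, mode="deriv")
        # d beta^2 / ds = 1/D
        return (short + longr) / D / D

    def _Hreg(self, x0, beta):
        D = self.domain.D
        b2 = beta**2
        x = x0[None, :]
        short = self._short_sum(x, x0, b2, drop_self=True, deriv=True)[0]
        longr = self._ksum(x, x0, b2, mode="deriv")[0]
        dself = (-1.0 / (2.0 * b2)) / (2.0 * np.pi) \
            + np.exp(-self.eta * b2) / (4.0 * np.pi * b2)
        return (dself + short + longr) / D / D


class BoxGreens(_EwaldGreens):
    """Box [0,Lx] x [0,Ly] x [0,Lz]; erfc-form Ewald short-range kernel."""

    def _short_kernel(self, r, beta):
        a = r / (2.0 * np.sqrt(self.eta))
        b = beta * np.sqrt(self.eta)
        return (np.exp(-beta * r) * sp.erfc(a - b)
                + np.exp(beta * r) * sp.erfc(a + b)) / (8.0 * np.pi * r)

    def _short_kernel_deriv(self, r, beta):
        # d/d(beta^2) of the short kernel = -(4pi)^{-3/2} int_0^eta t^{-1/2} e^{...}
        a = r / (2.0 * np.sqrt(self.eta))
        b = beta * np.sqrt(self.eta)
        integral = (np.sqrt(np.pi) / (2.0 * beta)) * (
            np.exp(-beta * r) * sp.erfc(a - b) - np.exp(beta * r) * sp.erfc(a + b)
        )
        return -integral / (4.0 * np.pi) ** 1.5

    def _short_sum(self, x, x0, beta, drop_self=False, deriv=False):
        imgs = self._images(x0)
        diffs = x[:, None, :] - imgs[None, :, :]
        r = np.sqrt((diffs**2).sum(axis=-1))
        if drop_self:
            r = np.where(r < 1e-13, np.inf, r)
        r = np.where(r < self.rcut, r, np.inf)
        fin = np.isfinite(r)
        acc = np.zeros_like(r)
        if deriv:
            acc[fin] = self._short_kernel_deriv(r[fin], beta)
        else:
            acc[fin] = self._short_kernel(r[fin], beta)
        return acc.sum(axis=1)

    def _G(self, x, x0, beta):
        D = self.domain.D
        short = self._short_sum(x, x0, beta)
        longr = self._ksum(x, x0, beta**2)
        return (short + longr) / D

    def _R(self, x0, beta):
        D = self.domain.D
        x = x0[None, :]
        short = self._short_sum(x, x0, beta, drop_self=True)[0]
        longr = self._ksum(x, x0, beta**2)[0]
        b2eta = beta**2 * self.eta
        # lim_{r->0} [phi(r) - 1/(4 pi r)]: the screened-kernel tail plus the
        # difference between the screened and bare Coulomb singularities
        self_term = -(
            2.0 * np.exp(-b2eta) / np.sqrt(self.eta)
            - 2.0 * beta * np.sqrt(np.pi) * sp.erfc(beta * np.sqrt(self.eta))
        ) / (4.0 * np.pi) ** 1.5 - beta / (4.0 * np.pi)
        return (self_term + short + longr) / D

    def _G0(self, x, x0):
        D = self.domain.D
        imgs = self._images(x0)
        diffs = x[:, None, :] - imgs[None, :, :]
        r = np.sqrt((diffs**2).sum(axis=-1))
        r = np.where(r < self.rcut, r, np.inf)
        fin = np.isfinite(r)
        acc = np.zeros_like(r)
        acc[fin] = sp.erfc(r[fin] / (2.0 * np.sqrt(self.eta))) / (4.0 * np.pi * r[fin])
        short = acc.sum(axis=1)
        longr = RectGreens._ksum_pseudo(self, x, x0)
        return (short + longr - self.eta / self.domain.volume) / D

    def _R0(self, x0):
        D = self.domain.D
        x = x0[None, :]
        imgs = self._images(x0)
        diffs = x[:, None, :] - imgs[None, :, :]
        r = np.sqrt((diffs**2).sum(axis=-1))
        r = np.where(r < 1e-13, np.inf, r)
        r = np.where(r < self.rcut, r, np.inf)
        fin = np.isfinite(r)
        acc = np.zeros_like(r)
        acc[fin] = sp.erfc(r[fin] / (2.0 * np.sqrt(self.eta))) / (4.0 * np.pi * r[fin])
        short = acc.sum()
        self_term = -1.0 / (4.0 * np.pi * np.sqrt(np.pi * self.eta))
        longr = RectGreens._ksum_pseudo(self, x, x0)[0]
        return (self_term + short + longr - self.eta / self.domain.volume) / D

    def _H(self, x, x0, beta):
        D = self.domain.D
        short = self._short_sum(x, x0, beta, deriv=True)
        longr = self._ksum(x, x0, beta**2, mode="deriv")
        return (short + longr) / D / D

    def _Hreg(self, x0, beta):
        D = self.domain.D
        x = x0[None, :]
        short = self._short_sum(x, x0, beta, drop_self=True, deriv=True)[0]
        longr = self._ksum(x, x0, beta**2, mode="deriv")[0]
        dself = (np.sqrt(np.pi) / beta) * sp.erfc(beta * np.sqrt(self.eta)) \
            / (4.0 * np.pi) ** 1.5 - 1.0 / (8.0 * np.pi * beta)
        return (dself + short + longr) / D / D


# ---------------------------------------------------------------------------
# factory + functional interface
# ---------------------------------------------------------------------------

_PROVIDERS = {
    "disk2d": DiskGreens,
    "rect2d": RectGreens,
    "sphere3d": SphereGreens,
    "box3d": BoxGreens,
}


def make_greens_provider(domain: DomainSpec, tol: float = 1e-10,
                         boundary_margin: float = 1e-3) -> GreensProvider:
    """Build the Green's-function evaluator bundle for a supported geometry."""
    try:
        cls = _PROVIDERS[domain.kind]
    except KeyError:  # pragma: no cover - DomainSpec already validates
        raise GeometryError(f"geometry not implemented: {domain.kind!r}")
    return cls(domain, tol=tol, boundary_margin=boundary_margin)


def greens_value(provider: GreensProvider, x, x0, s: float = 0.0):
    return provider.G(x, x0, s)


def greens_regular(provider: GreensProvider, x0, s: float = 0.0) -> float:
    return provider.R(x0, s)


def greens_s_derivative(provider: GreensProvider, x, x0):
    return provider.H(x, x0)
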