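"""Accumulation times: local measures of relaxation to steady state.

For a linear diffusion problem relaxing to a steady state u(x), the
fractional deviation Z(x,t) = 1 - u(x,t)/u(x) decays from 1 to 0, and the
accumulation time T(x) = int_0^inf Z dt measures how slowly the steady
state is approached at x.  Working in Laplace space, T(x) is the s->0
derivative of s*u~(x,s) divided by u(x); the Laplace-transformed problem is
the steady problem under gamma0 -> gamma0 + s with boundary data c_j/s and
an effective bulk source u0(x), so the matched-asymptotics machinery of the
steady module applies verbatim at rate s and the limit only needs the
Green's function and its s-derivative H at s = 0.

Sign conventions: with zero initial data the compartments act as sources
filling the bulk ("fill"); with bulk initial data and compartment sinks the
deviation reverses sign and the definition is negated ("drain").  Only
gamma0 > 0 is supported: at zero degradation the Laplace-space Green's
function has a simple pole at s = 0 and the expansion machinery here does
not apply.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .domains import GreensProvider, singular_quadrature
from .steady import (CompartmentConfiguration, _effective_c0_psi,
                     assemble_matrix_2d, trap_strength)


# ---------------------------------------------------------------------------
# 1D half-line problem (flux injection at the origin)
# ---------------------------------------------------------------------------

def accumulation_time_1d(x, D: float, gamma0: float):
    """Closed form T(x) = (1/2 gamma0)(1 + sqrt(gamma0/D) x) for diffusion
    on a long interval with constant influx at x = 0."""
    if gamma0 <= 0:
        raise ValueError("gamma0 > 0 required")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("x must be >= 0")
    return (1.0 + np.sqrt(gamma0 / D) * x) / (2.0 * gamma0)


def accumulation_time_1d_laplace(x, D: float, gamma0: float, L: float):
    """Generic Laplace-space evaluation on the finite interval [0, L].

    The transformed solution is u~ = (J0/s) cosh(beta_s (L-x)) /
    (D beta_s sinh(beta_s L)); T = -d log(s u~)/ds at s = 0, evaluated
    analytically.  Converges to the closed form as L grows.
    """
    if gamma0 <= 0:
        raise ValueError("gamma0 > 0 required")
    x = np.asarray(x, dtype=float)
    beta = math.sqrt(gamma0 / D)
    dlogf_dbeta = ((L - x) * np.tanh(beta * (L - x))
                   - 1.0 / beta - L / np.tanh(beta * L))
    return -dlogf_dbeta / (2.0 * D * beta)


def accumulation_time_1d_eigen(x, D: float, gamma0: float, L: float,
                               n_modes: int = 4000):
    """Eigenfunction-sum evaluation of T(x) on [0, L] (oracle route).

    Uses the cosine eigenbasis phi_n = A_n cos(n pi (L-x)/L) with
    lambda_n = gamma0 + n^2 pi^2 D / L^2 and zero initial data, for which
    the expansion coefficients of u(x,t) - u(x) are c_n = -<u, phi_n>.
    """
    if gamma0 <= 0:
        raise ValueError("gamma0 > 0 required")
    x = np.asarray(x, dtype=float)
    beta = math.sqrt(gamma0 / D)

    def u_ss(z):
        return np.cosh(beta * (L - z)) / (D * beta * np.sinh(beta * L))

    n = np.arange(n_modes)
    b = n * np.pi / L
    norm = np.where(n == 0, 1.0 / L, 2.0 / L)
    # <u_ss, cos(n pi (L-x)/L)> has the closed form (-1)^n / (D (beta^2+b^2))
    cn = -((-1.0) ** n) / (D * (beta**2 + b**2))
    lam = gamma0 + D * b**2
    phi_x = np.cos(np.outer(n, np.pi * (L - x) / L))
    T = -(norm[:, None] * cn[:, None] * phi_x / lam[:, None]).sum(axis=0) / u_ss(x)
    return T


# ---------------------------------------------------------------------------
# initial data and its Green's-function convolution
# ---------------------------------------------------------------------------

@dataclass
class InitialCondition:
    """Initial bulk profile u0(x) with compact support away from compartments.

    If the support is a known annulus/shell (center, r_inner, r_outer), the
    Green's-function convolution integrates over the support directly
    whenever the evaluation point lies outside it, which resolves narrow
    profiles that a probe-centred quadrature would undersample.
    """

    fn: object                    # callable (n, d) -> (n,)
    support_center: np.ndarray | None = None
    support_radii: tuple | None = None      # (r_inner, r_outer)

    def __call__(self, pts):
        return np.asarray(self.fn(np.atleast_2d(pts)), dtype=float)


def radial_bump(center, r_inner, r_outer, amplitude=1.0):
    """Smooth radially symmetric bump supported on the annulus/shell
    r_inner < |x - center| < r_outer."""
    c = np.asarray(center, dtype=float)

    def fn(pts):
        r = np.linalg.norm(np.atleast_2d(pts) - c[None, :], axis=-1)
        t = (r - r_inner) / (r_outer - r_inner)
        out = np.zeros_like(r)
        on = (t > 0) & (t < 1)
        out[on] = amplitude * np.exp(-1.0 / (t[on] * (1.0 - t[on]) * 4.0 + 1e-300))
        return out

    return InitialCondition(fn, support_center=c,
                            support_radii=(r_inner, r_outer))


def _support_quadrature(dim, center, r_inner, r_outer, n_rad=48, n_ang=96):
    """Product quadrature over an annulus (2D) or spherical shell (3D)."""
    gl, glw = np.polynomial.legendre.leggauss(n_rad)
    r = 0.5 * (r_outer - r_inner) * gl + 0.5 * (r_outer + r_inner)
    wr = 0.5 * (r_outer - r_inner) * glw
    if dim == 2:
        th = 2.0 * np.pi * np.arange(n_ang) / n_ang
        dirs = np.stack([np.cos(th), np.sin(th)], axis=-1)
        wa = np.full(n_ang, 2.0 * np.pi / n_ang)
    else:
        mu, wmu = np.polynomial.legendre.leggauss(max(n_ang // 4, 12))
        ph = 2.0 * np.pi * np.arange(n_ang) / n_ang
        mg, pg = np.meshgrid(mu, ph, indexing="ij")
        st = np.sqrt(1.0 - mg**2)
        dirs = np.stack([st * np.cos(pg), st * np.sin(pg), mg],
                        axis=-1).reshape(-1, 3)
        wa = (wmu[:, None] * np.full(n_ang, 2.0 * np.pi / n_ang)[None, :]).ravel()
    pts = center[None, None, :] + r[None, :, None] * dirs[:, None, :]
    w = wa[:, None] * wr[None, :] * r[None, :] ** (dim - 1)
    return pts.reshape(-1, dim), w.ravel()


def gamma0_source_field(config: CompartmentConfiguration,
                        provider: GreensProvider,
                        u0: InitialCondition, x, s: float = 0.0,
                        n_ang: int = 64):
    """Gamma_0(x, s) = int_Omega G(x, x'; s) u0(x') dx' by quadrature
    adapted to the Green's singularity at x."""
    if config.domain.gamma0 <= 0:
        raise ValueError("gamma0 > 0 required")
    for c in config.compartments:
        # sample the centre and the compartment surface
        rad = config.eps * c.ell
        ang = np.linspace(0.0, 2.0 * np.pi, 9)[:-1]
        if config.domain.dim == 2:
            ring = c.center[None, :] + rad * np.stack(
                [np.cos(ang), np.sin(ang)], axis=-1)
        else:
            ring = c.center[None, :] + rad * np.stack(
                [np.cos(ang), np.sin(ang), np.zeros_like(ang)], axis=-1)
        samples = np.vstack([c.center[None, :], ring])
        if np.any(u0(samples) != 0.0):
            raise ValueError("u0 support overlaps a compartment")
    x = np.asarray(x, dtype=float)
    if (u0.support_center is not None and u0.support_radii is not None):
        r_in, r_out = u0.support_radii
        d = float(np.linalg.norm(x - u0.support_center))
        if d > r_out + 1e-9 or d < r_in - 1e-9:
            # x outside the support: G(x, .) is smooth there, integrate
            # over the support shell directly
            pts, w = _support_quadrature(config.domain.dim,
                                         u0.support_center, r_in, r_out,
                                         n_ang=n_ang)
            u0v = u0(pts)
            g = provider.G(pts, x, s=s)
            return float((g * u0v * w).sum())
    pts, w = singular_quadrature(config.domain, x, n_ang=n_ang)
    u0v = u0(pts)
    live = u0v != 0.0
    if not np.any(live):
        return 0.0
    g = provider.G(pts[live], x, s=s)
    return float((g * u0v[live] * w[live]).sum())


# ---------------------------------------------------------------------------
# singularly perturbed accumulation times
# ---------------------------------------------------------------------------

@dataclass
class AccumulationResult:
    probes: np.ndarray
    T: np.ndarray                # full formula
    T_leading: np.ndarray        # leading-order simplification
    direction: str
    A: np.ndarray | None = None
    A_prime: np.ndarray | None = None
    Theta: np.ndarray | None = None


def _sderiv_matrix_2d(config, provider):
    """M'(0): term-wise s-derivative of the 2D interaction matrix."""
    D = config.domain.D
    N = config.N
    centers = config.centers
    Mp = np.empty((N, N))
    for j in range(N):
        Mp[j, j] = 2.0 * math.pi * D * provider.Hreg(centers[j])
        for i in range(N):
            if i != j:
                Mp[j, i] = 2.0 * math.pi * D * provider.H(centers[j], centers[i])
    return Mp


def accumulation_time_2d(config: CompartmentConfiguration,
                         provider: GreensProvider,
                         u0: InitialCondition | None,
                         probes,
                         direction: str = "drain",
                         n_ang: int = 64) -> AccumulationResult:
    """Accumulation time at probe points for the 2D compartment problem.

    Full form: T = +/- [Gamma0(x,0) - 2 pi nu D sum_k (A'_k G + A_k H)] / u(x)
    with A_k the steady matching coefficients, A'_k the s-derivative of
    s A~_k(s) at 0 (through the Theta matrix), and H = dG/ds.  The
    leading-order variant keeps only Gamma0 over the leading steady field.
    """
    if direction not in ("fill", "drain"):
        raise ValueError("direction must be 'fill' or 'drain'")
    if config.domain.gamma0 <= 0:
        raise ValueError(
            "accumulation times require gamma0 > 0 (pole at s=0 otherwise)")
    D = config.domain.D
    nu = config.nu
    N = config.N
    centers = config.centers
    c0, psi = _effective_c0_psi(config)
    M, _ = assemble_matrix_2d(config, provider, s=0.0)
    K = np.eye(N) + nu * M
    Kinv = np.linalg.inv(K)
    A = -Kinv @ c0
    Mp = _sderiv_matrix_2d(config, provider)
    Theta = Kinv @ Mp @ Kinv
    if u0 is None:
        g0_at_centers = np.zeros(N)
    else:
        g0_at_centers = np.array([
            gamma0_source_field(config, provider, u0, xc, 0.0, n_ang=n_ang)
            for xc in centers
        ])
    A_prime = nu * Theta @ c0 + Kinv @ g0_at_centers

    probes = np.atleast_2d(np.asarray(probes, dtype=float))
    T = np.empty(probes.shape[0])
    T_lead = np.empty(probes.shape[0])
    sign = 1.0 if direction == "drain" else -1.0
    for i, x in enumerate(probes):
        G_xc = np.array([provider.G(x, xc) for xc in centers])
        H_xc = np.array([provider.H(x, xc) for xc in centers])
        gam0 = (gamma0_source_field(config, provider, u0, x, 0.0, n_ang=n_ang)
                if u0 is not None else 0.0)
        u_ss = -2.0 * math.pi * nu * D * float(A @ G_xc)
        num = gam0 - 2.0 * math.pi * nu * D * float(A_prime @ G_xc + A @ H_xc)
        if abs(u_ss) < 1e-300:
            T[i] = T_lead[i] = math.nan
            continue
        T[i] = sign * num / u_ss
        lead_den = 2.0 * math.pi * nu * D * float(c0 @ G_xc)
        T_lead[i] = gam0 / lead_den if lead_den != 0 else math.nan
    return AccumulationResult(probes, T, T_lead, direction, A, A_prime, Theta)


def accumulation_time_3d(config: CompartmentConfiguration,
                         provider: GreensProvider,
                         u0: InitialCondition | None,
                         probes,
                         direction: str = "drain",
                         n_ang: int = 48) -> AccumulationResult:
    """3D analogue at leading order in eps:

    T = +/- [Gamma0(x,0) + 4 pi eps D sum_k Lambda_k (c_k H - Gamma0(x_k) G)]
        / (4 pi eps D sum_k Lambda_k c_k G).
    """
    if direction not in ("fill", "drain"):
        raise ValueError("direction must be 'fill' or 'drain'")
    if config.domain.gamma0 <= 0:
        raise ValueError(
            "accumulation times require gamma0 > 0 (pole at s=0 otherwise)")
    D = config.domain.D
    eps = config.eps
    centers = config.centers
    lam = np.array([trap_strength(c, D) for c in config.compartments])
    c0 = np.array([c.c0 for c in config.compartments]) - config.shift
    if u0 is None:
        g0_at_centers = np.zeros(config.N)
    else:
        g0_at_centers = np.array([
            gamma0_source_field(config, provider, u0, xc, 0.0, n_ang=n_ang)
            for xc in centers
        ])
    probes = np.atleast_2d(np.asarray(probes, dtype=float))
    T = np.empty(probes.shape[0])
    T_lead = np.empty(probes.shape[0])
    sign = 1.0 if direction == "drain" else -1.0
    for i, x in enumerate(probes):
        G_xc = np.array([provider.G(x, xc) for xc in centers])
        H_xc = np.array([provider.H(x, xc) for xc in centers])
        gam0 = (gamma0_source_field(config, provider, u0, x, 0.0, n_ang=n_ang)
                if u0 is not None else 0.0)
        den = 4.0 * math.pi * eps * D * float((lam * c0) @ G_xc)
        if abs(den) < 1e-300:
            T[i] = T_lead[i] = math.nan
            continue
        num = gam0 + 4.0 * math.pi * eps * D * float(
            (lam * c0) @ H_xc - (lam * g0_at_centers) @ G_xc)
        T[i] = sign * num / den
        T_lead[i] = gam0 / den if gam0 != 0 else math.nan
    return AccumulationResult(probes, T, T_lead, direction)
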