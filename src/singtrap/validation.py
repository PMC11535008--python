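"""Independent oracles: exact radial solutions, finite-difference solvers,
trap capacitances, and the synthetic configuration generator.

Every asymptotic solver in the package is paired with at least one oracle
from this module: the concentric-compartment problems have closed-form
radial solutions in modified Bessel functions (2D) or exponentials (3D);
multi-compartment steady states are checked against a second-order
embedded-boundary finite-difference solve; Green's functions are checked
against a direct discretisation of their defining PDE with a mollified
point source.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy import special as sp
from scipy.sparse.linalg import spsolve

from .domains import DomainSpec
from .steady import Compartment, CompartmentConfiguration, ConfigurationError


# ---------------------------------------------------------------------------
# exact radial solutions (single concentric compartment, unit disk / sphere)
# ---------------------------------------------------------------------------

class RadialSolution:
    """Closed-form radial steady state u(r) on [eps*ell, 1]."""

    def __init__(self, fn, a, robin_residual):
        self._fn = fn
        self.inner_radius = a
        self.robin_residual = robin_residual

    def __call__(self, r):
        r = np.asarray(r, dtype=float)
        if np.any(r < self.inner_radius - 1e-12) or np.any(r > 1.0 + 1e-12):
            raise ValueError("radius outside the annulus/shell")
        return self._fn(r)


def exact_annulus_2d(ell, eps, kappa, c0, D, gamma0) -> RadialSolution:
    """u(r) = A [I0(beta r) + (I1(beta)/K1(beta)) K0(beta r)] with the Robin
    condition D u'(a) = (kappa/eps)(u(a) - c0) at a = eps*ell; the I1/K1
    combination makes u'(1) = 0 exactly."""
    if gamma0 <= 0:
        raise ValueError("gamma0 > 0 required for the screened annulus solution")
    a = eps * ell
    if not 0.0 < a < 1.0:
        raise ValueError("inner radius must lie in (0, 1)")
    beta = math.sqrt(gamma0 / D)
    c = sp.i1(beta) / sp.k1(beta)

    def w(r):
        return sp.i0(beta * r) + c * sp.k0(beta * r)

    def wp(r):
        return beta * (sp.i1(beta * r) - c * sp.k1(beta * r))

    if math.isinf(kappa):
        A = c0 / w(a)
        resid = abs(A * w(a) - c0)
    else:
        kap = kappa / eps
        A = -kap * c0 / (D * wp(a) - kap * w(a))
        resid = abs(D * A * wp(a) - kap * (A * w(a) - c0))
    return RadialSolution(lambda r: A * w(r), a, resid)


def exact_shell_3d(ell, eps, kappa, c0, D, gamma0) -> RadialSolution:
    """u(r) = A [cosh(beta(1-r)) - sinh(beta(1-r))/beta] / r; the combination
    enforces u'(1) = 0 identically, A is fixed by the Robin condition."""
    if gamma0 <= 0:
        raise ValueError("gamma0 > 0 required for the screened shell solution")
    a = eps * ell
    if not 0.0 < a < 1.0:
        raise ValueError("inner radius must lie in (0, 1)")
    beta = math.sqrt(gamma0 / D)

    def f(r):
        return np.cosh(beta * (1.0 - r)) - np.sinh(beta * (1.0 - r)) / beta

    def fp(r):
        return -beta * np.sinh(beta * (1.0 - r)) + np.cosh(beta * (1.0 - r))

    def w(r):
        return f(r) / r

    def wp(r):
        return (fp(r) * r - f(r)) / r**2

    if math.isinf(kappa):
        A = c0 / w(a)
        resid = abs(A * w(a) - c0)
    else:
        kap = kappa / eps
        A = -kap * c0 / (D * float(wp(a)) - kap * float(w(a)))
        resid = abs(D * A * float(wp(a)) - kap * (A * float(w(a)) - c0))
    return RadialSolution(lambda r: A * w(r), a, resid)


# ---------------------------------------------------------------------------
# radial finite differences (steady and time-dependent)
# ---------------------------------------------------------------------------

def fd_radial_steady(ell, eps, kappa, c0, D, gamma0, n=2000, dim=2):
    """Second-order radial FD for the concentric problem; returns (r, u)."""
    a = eps * ell
    r = np.linspace(a, 1.0, n)
    h = r[1] - r[0]
    main = np.full(n, -2.0 * D / h**2 - gamma0)
    upper = D / h**2 + D * (dim - 1) / (2.0 * r[:-1] * h)
    lower = D / h**2 - D * (dim - 1) / (2.0 * r[1:] * h)
    Amat = sparse.diags([lower, main, upper], [-1, 0, 1], format="lil")
    rhs = np.zeros(n)
    # Robin at r = a (ghost node eliminated): D u'(a) = (kappa/eps)(u - c0)
    if math.isinf(kappa):
        Amat[0, :] = 0.0
        Amat[0, 0] = 1.0
        rhs[0] = c0
    else:
        kap = kappa / eps
        # ghost: u_{-1} = u_1 - 2 h (kap/D) (u_0 - c0)
        Amat[0, 0] = -2.0 * D / h**2 - gamma0 \
            - (D / h**2 - D * (dim - 1) / (2.0 * a * h)) * 2.0 * h * kap / D
        Amat[0, 1] = 2.0 * D / h**2
        rhs[0] = -(D / h**2 - D * (dim - 1) / (2.0 * a * h)) * 2.0 * h * kap / D * c0
    # Neumann at r = 1: ghost u_n = u_{n-2}
    Amat[n - 1, n - 2] = 2.0 * D / h**2
    u = spsolve(sparse.csr_matrix(Amat), rhs)
    return r, u


def richardson_order(coarse, mid, fine):
    """Observed order of accuracy from solutions at h, h/2, h/4."""
    return math.log2(abs(coarse - mid) / abs(mid - fine))


def fd_radial_accumulation(ell, eps, kappa, c0, D, gamma0, u0_fn, probes,
                           dim=2, n=1500, dt=5e-4, t_end=None,
                           direction="drain"):
    """Time-domain FD oracle for the accumulation time (concentric case).

    Crank-Nicolson integration of u_t = D (u'' + (dim-1) u'/r) - gamma0 u on
    [eps*ell, 1] with the Robin/Dirichlet compartment condition and a
    reflecting outer boundary, starting from u0(r).  Returns T at the probe
    radii via time-quadrature of the fractional deviation, plus an
    exponential tail correction beyond t_end.
    """
    from scipy.sparse.linalg import splu

    a = eps * ell
    if t_end is None:
        t_end = 10.0 / gamma0
    r = np.linspace(a, 1.0, n)
    h = r[1] - r[0]
    # spatial operator (same stencils as fd_radial_steady)
    main = np.full(n, -2.0 * D / h**2 - gamma0)
    upper = D / h**2 + D * (dim - 1) / (2.0 * r[:-1] * h)
    lower = D / h**2 - D * (dim - 1) / (2.0 * r[1:] * h)
    L = sparse.diags([lower, main, upper], [-1, 0, 1], format="lil")
    bc_rhs = np.zeros(n)
    dirichlet0 = math.isinf(kappa)
    if dirichlet0:
        L[0, :] = 0.0
    else:
        kap = kappa / eps
        low0 = D / h**2 - D * (dim - 1) / (2.0 * a * h)
        L[0, 0] = -2.0 * D / h**2 - gamma0 - low0 * 2.0 * h * kap / D
        L[0, 1] = 2.0 * D / h**2
        bc_rhs[0] = low0 * 2.0 * h * kap / D * c0
    L[n - 1, n - 2] = 2.0 * D / h**2
    L = sparse.csr_matrix(L)
    eye = sparse.identity(n, format="csr")
    Aminus = (eye - 0.5 * dt * L).tocsc()
    Aplus = (eye + 0.5 * dt * L).tocsr()
    lu = splu(Aminus)

    # steady state for Z
    _, uss = fd_radial_steady(ell, eps, kappa, c0, D, gamma0, n=n, dim=dim)
    u = np.asarray(u0_fn(r), dtype=float).copy()
    if dirichlet0:
        u[0] = c0
    pidx = [int(np.argmin(np.abs(r - p))) for p in np.atleast_1d(probes)]
    sign = 1.0 if direction == "drain" else -1.0
    Z_hist = []
    nsteps = int(round(t_end / dt))
    Tacc = np.zeros(len(pidx))
    zprev = sign * (u[pidx] / uss[pidx] - 1.0)
    for k in range(nsteps):
        rhs = Aplus @ u + dt * bc_rhs
        u = lu.solve(rhs)
        if dirichlet0:
            u[0] = c0
        z = sign * (u[pidx] / uss[pidx] - 1.0)
        Tacc += 0.5 * dt * (zprev + z)
        zprev = z
        if k == nsteps - 2:
            z_tail_prev = z.copy()
    # exponential tail: Z ~ Z_end * exp(-rate t)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.log(np.abs(z_tail_prev / zprev)) / dt
    rate = np.where((rate > 0) & np.isfinite(rate), rate, gamma0)
    Tacc += zprev / rate
    return Tacc


# ---------------------------------------------------------------------------
# Cartesian FD on a rectangle with embedded Dirichlet circles
# ---------------------------------------------------------------------------

@dataclass
class GridField:
    """FD solution on a structured grid; NaN marks excluded interior nodes."""
    x: np.ndarray
    y: np.ndarray
    u: np.ndarray
    h: float

    def probe(self, pts):
        """Bilinear interpolation at probe points."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        out = np.empty(pts.shape[0])
        for i, (px, py) in enumerate(pts):
            ix = np.searchsorted(self.x, px) - 1
            iy = np.searchsorted(self.y, py) - 1
            ix = min(max(ix, 0), len(self.x) - 2)
            iy = min(max(iy, 0), len(self.y) - 2)
            tx = (px - self.x[ix]) / (self.x[ix + 1] - self.x[ix])
            ty = (py - self.y[iy]) / (self.y[iy + 1] - self.y[iy])
            q = self.u[ix:ix + 2, iy:iy + 2]
            out[i] = ((1 - tx) * (1 - ty) * q[0, 0] + tx * (1 - ty) * q[1, 0]
                      + (1 - tx) * ty * q[0, 1] + tx * ty * q[1, 1])
        return out


def fd_solve_2d(config: CompartmentConfiguration, n: int = 201) -> GridField:
    """Embedded-boundary (Shortley-Weller) FD solve of the full 2D steady
    problem on a rectangular domain with Dirichlet compartments.

    Supports rect2d domains and kappa = inf (Dirichlet) compartments with
    constant boundary values; this is the regime used for oracle
    comparisons.  Second-order convergence is certified by the concentric
    annulus solution and Richardson triples.
    """
    dom = config.domain
    if dom.kind != "rect2d":
        raise ConfigurationError("Cartesian FD oracle supports rect2d only")
    for comp in config.compartments:
        if not math.isinf(comp.kappa) or comp.model == "II":
            raise ConfigurationError("FD oracle supports Dirichlet (kappa=inf) "
                                     "model I compartments only")
    Lx, Ly = dom.size
    nx = n
    ny = int(round(n * Ly / Lx))
    x = np.linspace(0, Lx, nx)
    y = np.linspace(0, Ly, ny)
    h = x[1] - x[0]
    hy = y[1] - y[0]
    if abs(h - hy) > 1e-9 * h:
        ny = int(round(Ly / h)) + 1
        y = np.linspace(0, Ly, ny)
        hy = y[1] - y[0]
    D, g0 = dom.D, dom.gamma0
    eps = config.eps
    centers = config.centers
    radii = eps * config.ells
    cvals = np.array([c.c0 for c in config.compartments])
    for comp, rad in zip(config.compartments, radii):
        if rad / h < 4.0:
            raise ConfigurationError(
                "unresolved compartment: fewer than 8 nodes across it")

    X, Y = np.meshgrid(x, y, indexing="ij")
    phi = np.full(X.shape, np.inf)
    which = np.full(X.shape, -1)
    for j, (c, rad) in enumerate(zip(centers, radii)):
        d = np.hypot(X - c[0], Y - c[1]) - rad
        take = d < phi
        phi = np.where(take, d, phi)
        which = np.where(take, j, which)
    inside = phi < 0.0

    idx = -np.ones(X.shape, dtype=int)
    free = ~inside
    idx[free] = np.arange(free.sum())
    nuk = int(free.sum())
    rows, cols, vals = [], [], []
    rhs = np.zeros(nuk)

    def circle_cut(p, jc, dvec):
        """Fraction theta in (0,1] of the arm from p toward dvec*h at which
        the circle of compartment jc is crossed."""
        pz = p - centers[jc]
        dz = dvec * h
        aa = dz @ dz
        bb = 2.0 * pz @ dz
        cc = pz @ pz - radii[jc]**2
        disc = max(bb * bb - 4 * aa * cc, 0.0)
        t = (-bb - math.sqrt(disc)) / (2 * aa)
        if t <= 0:
            t = (-bb + math.sqrt(disc)) / (2 * aa)
        return min(max(t, 1e-3), 1.0)

    for i in range(nx):
        for k in range(ny):
            if inside[i, k]:
                continue
            row = idx[i, k]
            p = np.array([x[i], y[k]])
            diag = -g0
            for axis in (0, 1):
                arms = []  # (theta, kind, payload) for the -/+ directions
                for sgn in (-1, 1):
                    di, dk = (sgn, 0) if axis == 0 else (0, sgn)
                    ii, kk = i + di, k + dk
                    if ii < 0 or ii >= nx or kk < 0 or kk >= ny:
                        arms.append((1.0, "mirror", (i - di, k - dk)))
                    elif inside[ii, kk]:
                        dvec = np.array([float(di), float(dk)])
                        jc = int(which[ii, kk])
                        arms.append((circle_cut(p, jc, dvec), "dirichlet", jc))
                    else:
                        arms.append((1.0, "free", (ii, kk)))
                (tm, km, pm), (tp, kp, pp) = arms
                hm, hp = tm * h, tp * h
                cm = 2.0 * D / (hm * (hm + hp))
                cp = 2.0 * D / (hp * (hm + hp))
                diag -= 2.0 * D / (hm * hp)
                for coeff, kind, payload in ((cm, km, pm), (cp, kp, pp)):
                    if kind == "dirichlet":
                        rhs[row] -= coeff * cvals[payload]
                    else:
                        rows.append(row)
                        cols.append(idx[payload])
                        vals.append(coeff)
            rows.append(row)
            cols.append(row)
            vals.append(diag)
    A = sparse.coo_matrix((vals, (rows, cols)), shape=(nuk, nuk)).tocsr()
    sol = spsolve(A, rhs)
    U = np.full(X.shape, np.nan)
    U[free] = sol
    return GridField(x, y, U, h)


# ---------------------------------------------------------------------------
# FD Green's function oracles
# ---------------------------------------------------------------------------

def fd_greens_rect(domain: DomainSpec, x0, s: float = 0.0, n: int = 241,
                   sigma_cells: float = 2.0):
    """Direct FD solve of D lap G - (gamma0+s) G = -delta_sigma on a rectangle
    with reflecting edges; the delta is mollified by a grid Gaussian whose
    discrete sum is 1.  Returns a GridField."""
    Lx, Ly = domain.size
    nx = n
    ny = int(round((n - 1) * Ly / Lx)) + 1
    x = np.linspace(0, Lx, nx)
    y = np.linspace(0, Ly, ny)
    h = x[1] - x[0]
    D = domain.D
    g = domain.gamma0 + s
    X, Y = np.meshgrid(x, y, indexing="ij")
    sig = sigma_cells * h
    src = np.exp(-((X - x0[0])**2 + (Y - x0[1])**2) / (2 * sig**2))
    w = np.ones(nx)
    w[0] = w[-1] = 0.5
    wy = np.ones(ny)
    wy[0] = wy[-1] = 0.5
    cellw = np.outer(w, wy) * h * h
    src /= (src * cellw).sum()

    def lap1(npts):
        e = np.ones(npts)
        A = sparse.diags([e[:-1], -2 * e, e[:-1]], [-1, 0, 1], format="lil")
        A[0, 1] = 2.0
        A[-1, -2] = 2.0
        return sparse.csr_matrix(A) / h**2

    Ax = lap1(nx)
    Ay = lap1(ny)
    L = sparse.kron(Ax, sparse.identity(ny)) + sparse.kron(sparse.identity(nx), Ay)
    A = D * L - g * sparse.identity(nx * ny)
    sol = spsolve(A.tocsr(), -src.ravel())
    return GridField(x, y, sol.reshape(nx, ny), h)


def fd_greens_disk(x0, gamma0: float, D: float = 1.0, s: float = 0.0,
                   nr: int = 220, ntheta: int = 384, sigma_cells: float = 2.5):
    """Finite-volume polar-grid solve of the disk Green's PDE with a
    mollified source at x0; cell-centred radii avoid the r = 0 coordinate
    singularity and make the centre flux vanish naturally.

    Returns (points, values): cell centres in Cartesian coordinates.
    """
    g = gamma0 + s
    hr = 1.0 / nr
    r = (np.arange(nr) + 0.5) * hr
    th = 2.0 * np.pi * np.arange(ntheta) / ntheta
    hth = 2.0 * np.pi / ntheta
    R, TH = np.meshgrid(r, th, indexing="ij")
    X = R * np.cos(TH)
    Y = R * np.sin(TH)
    sig = sigma_cells * hr
    src = np.exp(-((X - x0[0])**2 + (Y - x0[1])**2) / (2 * sig**2))
    area = R * hr * hth
    src /= (src * area).sum()

    N = nr * ntheta

    def I(i, k):
        return i * ntheta + (k % ntheta)

    rows, cols, vals = [], [], []
    for i in range(nr):
        rp = r[i] + hr / 2.0
        rm = r[i] - hr / 2.0
        for k in range(ntheta):
            row = I(i, k)
            diag = -g
            if i + 1 < nr:
                c = D * rp / (r[i] * hr**2)
                rows.append(row); cols.append(I(i + 1, k)); vals.append(c)
                diag -= c
            # i+1 == nr: reflecting boundary, zero flux -> no term
            if i - 1 >= 0:
                c = D * rm / (r[i] * hr**2)
                rows.append(row); cols.append(I(i - 1, k)); vals.append(c)
                diag -= c
            elif rm > 0:
                # couple across the centre to the opposite angular cell
                c = D * rm / (r[i] * hr**2)
                rows.append(row); cols.append(I(0, k + ntheta // 2)); vals.append(c)
                diag -= c
            c = D / (r[i] * hth)**2
            rows.append(row); cols.append(I(i, k + 1)); vals.append(c)
            rows.append(row); cols.append(I(i, k - 1)); vals.append(c)
            diag -= 2 * c
            rows.append(row); cols.append(row); vals.append(diag)
    A = sparse.coo_matrix((vals, (rows, cols)), shape=(N, N)).tocsr()
    sol = spsolve(A, -src.ravel())
    pts = np.stack([X.ravel(), Y.ravel()], axis=-1)
    return pts, sol


# ---------------------------------------------------------------------------
# capacitances of non-spherical traps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShapeSpec:
    kind: str                      # sphere | hemisphere | prolate | oblate
    a: float
    b: float = 0.0

    def __post_init__(self):
        if self.kind not in ("sphere", "hemisphere", "prolate", "oblate"):
            raise ValueError(f"unknown trap shape {self.kind!r}")
        if self.a <= 0:
            raise ValueError("semi-axis a must be positive")
        if self.kind in ("prolate", "oblate"):
            if not 0 < self.b <= self.a:
                raise ValueError("spheroids require 0 < b <= a")


def capacitance(shape: ShapeSpec) -> float:
    """Electrostatic capacitance of a trap shape (units of length).

    In 3D asymptotic formulas a non-spherical trap enters only through its
    capacitance: replace the scaled radius ell_j by C_j.  The oblate formula
    uses arccos(b/a), the standard electrostatics branch.
    """
    a, b = shape.a, shape.b
    if shape.kind == "sphere":
        return a
    if shape.kind == "hemisphere":
        return 2.0 * a * (1.0 - 1.0 / math.sqrt(3.0))
    if abs(a - b) < 1e-14:
        return a
    if shape.kind == "prolate":
        return math.sqrt(a**2 - b**2) / math.acosh(a / b)
    return math.sqrt(a**2 - b**2) / math.acos(b / a)


# ---------------------------------------------------------------------------
# synthetic configuration generator
# ---------------------------------------------------------------------------

@dataclass
class FixtureConfig:
    seed: int = 0
    N: int = 3
    eps: float = 0.05
    kind: str = "disk2d"
    size: tuple = (1.0,)
    D: float = 1.0
    gamma0: float = 1.0
    separation_mult: float = 10.0
    ell_range: tuple = (0.5, 1.0)
    kappa_range: tuple = (1.0, 10.0)
    c0_range: tuple = (0.5, 2.0)
    dirichlet: bool = False
    model: str = "I"
    max_tries: int = 20000


def generate_configuration(fix: FixtureConfig) -> CompartmentConfiguration:
    """Rejection-sample a well-separated compartment configuration.

    Deterministic for a given seed; raises if the requested number of
    compartments cannot be placed at the requested separation within the
    sampling budget.
    """
    rng = np.random.default_rng(fix.seed)
    dom = DomainSpec(fix.kind, fix.size, D=fix.D, gamma0=fix.gamma0)
    dim = dom.dim
    thresh = fix.separation_mult * fix.eps
    centers = []
    tries = 0
    while len(centers) < fix.N:
        tries += 1
        if tries > fix.max_tries:
            raise ConfigurationError(
                f"cannot place {fix.N} compartments at separation {thresh:g}"
            )
        if fix.kind in ("disk2d", "sphere3d"):
            p = rng.uniform(-1.0, 1.0, dim)
            if np.linalg.norm(p) > 1.0 - thresh:
                continue
        else:
            p = rng.uniform(0.0, 1.0, dim) * np.asarray(fix.size)
            if np.min(np.minimum(p, np.asarray(fix.size) - p)) < thresh:
                continue
        if centers and min(np.linalg.norm(p - q) for q in centers) < thresh:
            continue
        centers.append(p)
    ells = rng.uniform(*fix.ell_range, fix.N)
    ells[rng.integers(fix.N)] = fix.ell_range[1]
    ells = ells / ells.max()
    kappas = (np.full(fix.N, math.inf) if fix.dirichlet
              else rng.uniform(*fix.kappa_range, fix.N))
    c0s = rng.uniform(*fix.c0_range, fix.N)
    comps = [
        Compartment(center=c, ell=float(l), kappa=float(k), model=fix.model,
                    c0=float(cv))
        for c, l, k, cv in zip(centers, ells, kappas, c0s)
    ]
    return CompartmentConfiguration(dom, fix.eps, comps,
                                    separation_mult=fix.separation_mult)
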