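"""Reduction of the 2D quorum-sensing PDE-ODE model to coupled ODEs.

N well-mixed cells (model III compartments) exchange one chemical species
with a diffusing bulk.  In the fast-diffusion regime D = D0/nu the bulk
concentration is uniform to leading order, u ~ ubar(t) + (nu/D0) u1, and
the full PDE-ODE system collapses onto ODEs for (ubar, w_j):

    d ubar/dt = -gamma0 ubar - (2 pi D0/|Omega|) sum_j A_j(t)
    |U_j| dw_{j,a}/dt = fhat_a(w_j) + 2 pi D0 delta_{a,0} A_j(t)

where the exchange amplitudes A_j solve the linear matching system

    [1 + D0/(kappa_j ell_j)] A_j + 2 pi D0 nu sum_k Gmat0_jk A_k
        = ubar - w_{j,0}

built on the pseudo-Green's function of the domain at diffusivity D0.  For
identical cells the solve is A = kappa ell/(kappa ell + D0) W (ubar - w0)
with W = (I + nu Q)^{-1}, Q = 2 pi kappa ell D0/(kappa ell + D0) Gmat0.
W -> I as D0 -> infinity, recovering the classical well-mixed model with
kappahat = 2 pi N kappa ell / |U|.  The same W suggests a spatially coupled
Kuramoto model for compartmental oscillators interacting through the bulk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .domains import DomainSpec, make_greens_provider
from .steady import CompartmentConfiguration, ConfigurationError


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------

@dataclass
class SelkovKinetics:
    """Two-species Sel'kov glycolysis oscillator.

    f0 = alpha w1 + w1 w0^2 - w0        (exchanged species, index 0)
    f1 = eps_s (mu - alpha w1 - w1 w0^2)

    The isolated-cell fixed point is w0* = mu, w1* = mu/(alpha + mu^2).
    With the default alpha = 0.5, eps_s = 0.15 the isolated cell oscillates
    for mu roughly in (0.85, 2.22); the default mu sits just above the upper
    Hopf point, i.e. each isolated cell is quiescent.
    """

    alpha: float = 0.5
    eps_s: float = 0.15
    mu: float = 2.3
    n_species: int = 2

    def f(self, w):
        w = np.asarray(w, dtype=float)
        if np.any(w < -1e-9):
            raise ValueError("negative concentrations")
        w = np.maximum(w, 0.0)
        w0, w1 = w[..., 0], w[..., 1]
        r = w1 * (self.alpha + w0**2)
        return np.stack([r - w0, self.eps_s * (self.mu - r)], axis=-1)

    def jac(self, w):
        w0, w1 = float(w[0]), float(w[1])
        return np.array([
            [2 * w0 * w1 - 1.0, self.alpha + w0**2],
            [-self.eps_s * 2 * w0 * w1, -self.eps_s * (self.alpha + w0**2)],
        ])

    def fixed_points(self):
        return np.array([[self.mu, self.mu / (self.alpha + self.mu**2)]])


@dataclass
class LinearDecayKinetics:
    """f_0 = -lam w_0; single species, unique fixed point at zero."""

    lam: float = 1.0
    n_species: int = 1

    def f(self, w):
        w = np.asarray(w, dtype=float)
        return -self.lam * w

    def fixed_points(self):
        return np.zeros((1, 1))


# ---------------------------------------------------------------------------
# reduced system
# ---------------------------------------------------------------------------

@dataclass
class ReducedQSSystem:
    config: CompartmentConfiguration
    kinetics: object
    D0: float
    coupling: np.ndarray          # E + 2 pi D0 nu Gmat0 (the 5.11 matrix)
    Gmat0: np.ndarray
    W: np.ndarray | None          # identical-cell coupling matrix
    Q: np.ndarray | None
    gamma0: float
    volumes: np.ndarray

    @property
    def N(self) -> int:
        return self.config.N

    @property
    def kappa_hat(self) -> float:
        comp = self.config.compartments[0]
        Uvol = self.volumes.sum()
        return 2.0 * math.pi * self.N * comp.kappa * comp.ell / Uvol

    @property
    def alpha_frac(self) -> float:
        """Cytosol-to-bulk volume fraction |U|/(|Omega| - |U|)."""
        Uvol = self.volumes.sum()
        return Uvol / (self.config.domain.volume - Uvol)

    @property
    def alpha_frac_reduction(self) -> float:
        """|U|/|Omega|: the volume fraction consistent with the reduction,
        which replaces |Omega \\ U| by |Omega| (an O(eps^2) difference).
        With this convention the D0 -> infinity limit of the reduced system
        matches the classical well-mixed model term by term."""
        return self.volumes.sum() / self.config.domain.volume

    def solve_A(self, ubar, w0):
        """Exchange amplitudes from the matching linear system."""
        return np.linalg.solve(self.coupling, ubar - np.asarray(w0))

    def rhs(self, t, y):
        N, K1 = self.N, self.kinetics.n_species
        ubar = y[0]
        w = y[1:].reshape(N, K1)
        A = self.solve_A(ubar, w[:, 0])
        dubar = (-self.gamma0 * ubar
                 - 2.0 * math.pi * self.D0 / self.config.domain.volume * A.sum())
        dw = np.empty_like(w)
        for j in range(N):
            f = np.asarray(self.kinetics.f(w[j]))
            dw[j] = f
            dw[j, 0] += 2.0 * math.pi * self.D0 * A[j] / self.volumes[j]
        out = np.empty_like(y)
        out[0] = dubar
        out[1:] = dw.ravel()
        return out


def build_reduced_system(config: CompartmentConfiguration, kinetics,
                         D0: float, provider=None) -> ReducedQSSystem:
    """Assemble the reduced ODE system for a 2D model-III configuration.

    The pseudo-Green's matrix is evaluated at diffusivity D0 (the scaling
    that makes the bulk well mixed to leading order), with the usual
    regularised diagonal Gmat0_jj = R0(x_j) - log(ell_j)/(2 pi D0).
    """
    if config.domain.dim != 2:
        raise ConfigurationError("the reduction applies to 2D domains")
    if any(c.model != "III" for c in config.compartments):
        raise ConfigurationError("all compartments must be model III cells")
    if any(math.isinf(c.kappa) for c in config.compartments):
        raise ConfigurationError("cells require finite membrane permeability")
    dom0 = DomainSpec(config.domain.kind, config.domain.size, D=D0, gamma0=0.0)
    if provider is None:
        provider = make_greens_provider(dom0)
    N = config.N
    centers = config.centers
    nu = config.nu
    Gmat0 = np.empty((N, N))
    for j in range(N):
        Gmat0[j, j] = provider.R0(centers[j]) \
            - math.log(config.compartments[j].ell) / (2.0 * math.pi * D0)
        for i in range(N):
            if i != j:
                Gmat0[j, i] = provider.G0(centers[j], centers[i])
    E = np.diag([1.0 + D0 / (c.kappa * c.ell) for c in config.compartments])
    coupling = E + 2.0 * math.pi * D0 * nu * Gmat0
    kappas = [c.kappa for c in config.compartments]
    ells = [c.ell for c in config.compartments]
    W = Q = None
    if len(set(kappas)) == 1 and len(set(ells)) == 1:
        kl = kappas[0] * ells[0]
        Q = 2.0 * math.pi * kl * D0 / (kl + D0) * Gmat0
        W = np.linalg.inv(np.eye(N) + nu * Q)
    vols = np.array([config.compartment_volume(j) for j in range(N)])
    return ReducedQSSystem(config, kinetics, D0, coupling, Gmat0, W, Q,
                           config.domain.gamma0, vols)


def identical_cell_A(system: ReducedQSSystem, ubar, w0):
    """A = (kappa ell/(kappa ell + D0)) W (ubar - w0) (identical cells)."""
    if system.W is None:
        raise ConfigurationError(
            "identical-cell W requested for heterogeneous cells")
    comp = system.config.compartments[0]
    kl = comp.kappa * comp.ell
    return kl / (kl + system.D0) * (system.W @ (ubar - np.asarray(w0)))


def simulate_reduced(system: ReducedQSSystem, u0: float, w0, horizon: float,
                     rtol: float = 1e-8, atol: float = 1e-10, n_out: int = 400):
    """Integrate the reduced ODEs; returns (t, ubar(t), w(t) of shape
    (N, K+1, nt)).  Deterministic for fixed initial data."""
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    N, K1 = system.N, system.kinetics.n_species
    y0 = np.concatenate([[u0], np.asarray(w0, dtype=float).ravel()])
    t_eval = np.linspace(0.0, horizon, n_out)
    sol = solve_ivp(system.rhs, (0.0, horizon), y0, method="Radau",
                    rtol=rtol, atol=atol, t_eval=t_eval)
    if not sol.success:
        raise RuntimeError(f"reduced-system integration failed: {sol.message}")
    w = sol.y[1:].reshape(N, K1, -1)
    return sol.t, sol.y[0], w


# ---------------------------------------------------------------------------
# classical well-mixed model (comparison limit)
# ---------------------------------------------------------------------------

def well_mixed_rhs(t, y, kinetics, N, kappa_hat, alpha_frac, gamma0):
    K1 = kinetics.n_species
    U = y[0]
    w = y[1:].reshape(N, K1)
    dU = alpha_frac * kappa_hat / N * (w[:, 0] - U).sum() - gamma0 * U
    dw = np.empty_like(w)
    for j in range(N):
        dw[j] = np.asarray(kinetics.f(w[j]))
        dw[j, 0] -= kappa_hat * (w[j, 0] - U)
    out = np.empty_like(y)
    out[0] = dU
    out[1:] = dw.ravel()
    return out


def simulate_well_mixed(kinetics, N, kappa_hat, alpha_frac, gamma0, u0, w0,
                        horizon, rtol=1e-8, atol=1e-10, n_out=400):
    y0 = np.concatenate([[u0], np.asarray(w0, dtype=float).ravel()])
    t_eval = np.linspace(0.0, horizon, n_out)
    sol = solve_ivp(well_mixed_rhs, (0.0, horizon), y0, method="Radau",
                    args=(kinetics, N, kappa_hat, alpha_frac, gamma0),
                    rtol=rtol, atol=atol, t_eval=t_eval)
    if not sol.success:
        raise RuntimeError(f"well-mixed integration failed: {sol.message}")
    w = sol.y[1:].reshape(N, kinetics.n_species, -1)
    return sol.t, sol.y[0], w


# ---------------------------------------------------------------------------
# fixed points and Hopf scan
# ---------------------------------------------------------------------------

def reduced_fixed_point(system: ReducedQSSystem, guess=None):
    """Root of the reduced vector field (ubar*, w*)."""
    N, K1 = system.N, system.kinetics.n_species
    if guess is None:
        wg = np.atleast_2d(system.kinetics.fixed_points())[0]
        guess = np.concatenate([[wg[0]], np.tile(wg, N)])
    sol = root(lambda y: system.rhs(0.0, y), np.asarray(guess, dtype=float),
               method="hybr", tol=1e-13)
    if not sol.success:
        return None
    return sol.x


def system_jacobian(system: ReducedQSSystem, y, h: float = 1e-7):
    """Central-difference Jacobian of the reduced vector field."""
    n = y.size
    J = np.empty((n, n))
    for i in range(n):
        e = np.zeros(n)
        e[i] = h * max(1.0, abs(y[i]))
        J[:, i] = (system.rhs(0.0, y + e) - system.rhs(0.0, y - e)) / (2 * e[i])
    return J


@dataclass
class HopfReport:
    grid: np.ndarray
    max_real: np.ndarray          # leading eigenvalue real part (NaN = no fp)
    crossings: list               # refined parameter values


def hopf_scan(make_system, grid, refine_tol: float = 1e-4) -> HopfReport:
    """Scan a parameter grid for Hopf bifurcations of the reduced system.

    `make_system(value)` must return a ReducedQSSystem at that parameter
    value.  The leading eigenvalue real part of the fixed-point Jacobian is
    tracked; sign changes are refined by bisection.
    """
    grid = np.asarray(grid, dtype=float)
    max_real = np.full(grid.size, np.nan)

    def leading_real(value):
        system = make_system(value)
        y = reduced_fixed_point(system)
        if y is None:
            return np.nan
        lam = np.linalg.eigvals(system_jacobian(system, y))
        return float(lam.real.max())

    for i, g in enumerate(grid):
        max_real[i] = leading_real(g)
    crossings = []
    for i in range(grid.size - 1):
        a, b = max_real[i], max_real[i + 1]
        if np.isnan(a) or np.isnan(b) or a * b >= 0:
            continue
        lo, hi = grid[i], grid[i + 1]
        flo = a
        while hi - lo > refine_tol:
            mid = 0.5 * (lo + hi)
            fm = leading_real(mid)
            if np.isnan(fm):
                break
            if flo * fm <= 0:
                hi = mid
            else:
                lo, flo = mid, fm
        crossings.append(0.5 * (lo + hi))
    return HopfReport(grid, max_real, crossings)


# ---------------------------------------------------------------------------
# Kuramoto variant
# ---------------------------------------------------------------------------

@dataclass
class KuramotoSystem:
    """Oscillators coupled through a decaying external medium z(t).

    dtheta_j/dt = omega_j + kappahat a sum_k W_jk sin(psi - theta_k)
    dz/dt = (alpha kappahat / N) sum_jk W_jk (e^{i theta_k} - z)
            - (gamma0 + i omega0) z,   z = a e^{i psi}.

    W = I recovers the classical medium-coupled Kuramoto model; a general W
    carries the spatial information of the quorum-sensing reduction.
    """

    N: int
    kappa_hat: float = 2.0
    alpha: float = 1.0
    gamma0: float = 0.5
    omega0: float = 0.0
    freq_scale: float = 0.0       # std of the (even, zero-mean) frequency law
    W: np.ndarray | None = None

    def sample(self, seed: int):
        rng = np.random.default_rng(seed)
        omega = (rng.normal(0.0, self.freq_scale, self.N)
                 if self.freq_scale > 0 else np.zeros(self.N))
        omega = omega - omega.mean() if self.freq_scale > 0 else omega
        theta0 = rng.uniform(0.0, 2.0 * np.pi, self.N)
        return omega, theta0


def _kuramoto_rhs(t, y, N, kappa_hat, alpha, gamma0, omega0, omega, W):
    theta = y[:N]
    z = y[N] + 1j * y[N + 1]
    a = abs(z)
    psi = np.angle(z)
    sin_terms = np.sin(psi - theta)
    dtheta = omega + kappa_hat * a * (W @ sin_terms)
    e = np.exp(1j * theta)
    dz = (alpha * kappa_hat / N) * (W @ e - W.sum(axis=1) * z).sum() \
        - (gamma0 + 1j * omega0) * z
    out = np.empty_like(y)
    out[:N] = dtheta
    out[N] = dz.real
    out[N + 1] = dz.imag
    return out


def kuramoto_simulate(ksys: KuramotoSystem, horizon: float, seed: int = 0,
                      z0: complex = 0.1 + 0.0j, n_out: int = 400,
                      rtol: float = 1e-9, atol: float = 1e-11):
    """Integrate the W-coupled Kuramoto system from seeded random phases.

    Returns (t, theta(t), z(t), abar(t)) where abar is the phase-coherence
    order parameter |N^-1 sum_j e^{i theta_j}| in [0, 1].
    """
    N = ksys.N
    W = ksys.W if ksys.W is not None else np.eye(N)
    omega, theta0 = ksys.sample(seed)
    y0 = np.concatenate([theta0, [z0.real, z0.imag]])
    t_eval = np.linspace(0.0, horizon, n_out)
    sol = solve_ivp(_kuramoto_rhs, (0.0, horizon), y0, method="RK45",
                    args=(N, ksys.kappa_hat, ksys.alpha, ksys.gamma0,
                          ksys.omega0, omega, W),
                    rtol=rtol, atol=atol, t_eval=t_eval)
    if not sol.success:
        raise RuntimeError(f"Kuramoto integration failed: {sol.message}")
    theta = sol.y[:N]
    z = sol.y[N] + 1j * sol.y[N + 1]
    if not np.all(np.isfinite(sol.y)):
        raise RuntimeError("non-finite amplitudes in Kuramoto integration")
    abar = np.abs(np.exp(1j * theta).mean(axis=0))
    return sol.t, theta, z, abar
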