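"""Volume transmission: diffusion with randomly switching varicosity boundaries.

N small varicosities release neurotransmitter into an extracellular domain
with a reflecting outer boundary and no bulk degradation.  The boundary
condition on every varicosity switches synchronously with a two-state
Markov chain: in the firing state the surface injects a constant flux J_j,
in the quiescent state it absorbs (u = 0), modelling re-uptake.  The field
is then a stochastic process; taking expectations conditioned on the
environment state N(t) in {0 (absorbing), 1 (flux)} yields coupled PDEs
for ubar_n(x) = E[u 1_{N=n}] whose steady state is obtained by two nested
constant-boundary (model I) solves:

  step 1  ubar = ubar_0 + ubar_1 solves the zero-degradation Dirichlet
          problem with unknown surface constants phi_j (pseudo-Green's
          branch, kappa -> inf);
  step 2  ubar_1 solves the same problem at effective degradation
          alpha + beta with source beta*ubar, which reduces to a
          homogeneous modified-Helmholtz solve for
          ubar_1 - beta/(alpha+beta) ubar with surface values
          alpha/(alpha+beta) phi_j;
  step 3  the phi_j are fixed by restoring the inhomogeneous Neumann
          condition through the log-coefficients of the inner expansions,
          an N x N linear system.

Conventions.  The pathwise firing boundary condition is
D grad u . n_j = -J_j with n_j pointing out of the varicosity, so that
J_j > 0 releases transmitter into the bulk (the field decays away from a
firing varicosity).  Taking expectations of that condition multiplies it
by the stationary firing occupancy rho_1 = beta/(alpha+beta):
D grad ubar_1 . n_j = -rho_1 J_j.  Dropping rho_1 (or reversing the sign)
produces conditional means that disagree with direct Monte-Carlo
simulation of the switching PDE, which is the ground truth used in the
test-suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from .domains import GreensProvider, make_greens_provider
from .steady import CompartmentConfiguration, ConfigurationError, assemble_matrix_2d


@dataclass
class SwitchingConfig:
    config: CompartmentConfiguration
    alpha: float                  # firing -> quiescent rate (1 -> 0)
    beta: float                   # quiescent -> firing rate (0 -> 1)
    J: np.ndarray                 # per-varicosity firing influx density

    def __post_init__(self):
        if self.config.domain.gamma0 != 0.0:
            raise ConfigurationError("volume transmission assumes gamma0 = 0 bulk")
        if self.alpha <= 0 or self.beta <= 0:
            raise ConfigurationError("switching rates must be positive")
        self.J = np.asarray(self.J, dtype=float)
        if self.J.size != self.config.N or np.any(self.J < 0):
            raise ConfigurationError("need one influx J_j >= 0 per varicosity")
        for c in self.config.compartments:
            if not math.isinf(c.kappa):
                raise ConfigurationError(
                    "switching boundaries use Dirichlet/flux conditions "
                    "(set kappa = inf)")

    @property
    def generator(self) -> np.ndarray:
        """Markov generator acting on conditional means (columns sum to 0)."""
        a, b = self.alpha, self.beta
        return np.array([[-b, a], [b, -a]])

    @property
    def firing_fraction(self) -> float:
        return self.beta / (self.alpha + self.beta)


@dataclass
class SwitchingSolution:
    cfg: SwitchingConfig
    phi: np.ndarray               # interface constants
    u_inf: float                  # far-field constant of the summed field
    A: np.ndarray                 # step-1 coefficients
    B: np.ndarray                 # step-2 coefficients
    neumann_residual: float
    condition_number: float

    def ubar(self, x):
        """Unconditioned mean field ubar_0 + ubar_1."""
        c = self.cfg.config
        prov = self._prov
        pts = np.atleast_2d(np.asarray(x, dtype=float))
        acc = np.zeros(pts.shape[0])
        for k, xc in enumerate(c.centers):
            acc += self.A[k] * prov.G0(pts, xc)
        out = self.u_inf - 2.0 * math.pi * c.nu * c.domain.D * acc
        return out if np.asarray(x).ndim > 1 else float(out[0])

    def ubar_1(self, x):
        """Firing-conditioned mean field."""
        c = self.cfg.config
        prov = self._prov
        geff = self.cfg.alpha + self.cfg.beta
        s_needed = geff          # modified Helmholtz rate
        pts = np.atleast_2d(np.asarray(x, dtype=float))
        acc = np.zeros(pts.shape[0])
        for k, xc in enumerate(c.centers):
            acc += self.B[k] * prov.G(pts, xc, s=s_needed)
        util = -2.0 * math.pi * c.nu * c.domain.D * acc
        ub = np.atleast_1d(self.ubar(pts))
        out = self.cfg.beta / geff * ub + util
        return out if np.asarray(x).ndim > 1 else float(out[0])

    def ubar_0(self, x):
        u = np.atleast_1d(self.ubar(x))
        u1 = np.atleast_1d(self.ubar_1(x))
        out = u - u1
        return out if np.asarray(x).ndim > 1 else float(out[0])


def solve_volume_transmission(swcfg: SwitchingConfig,
                              provider: GreensProvider | None = None
                              ) -> SwitchingSolution:
    """Nested model-I solves for the conditional-mean steady state."""
    config = swcfg.config
    if config.domain.dim != 2:
        raise ConfigurationError("volume transmission solver is 2D")
    if provider is None:
        provider = make_greens_provider(config.domain)
    N = config.N
    nu = config.nu
    D = config.domain.D
    geff = swcfg.alpha + swcfg.beta

    # step 1: pseudo-branch Dirichlet solve, linear in phi through the
    # bordered system [[I + nu M0, -1], [1^T, 0]] [A; u_inf] = [-phi; 0]
    M0, _ = assemble_matrix_2d(config, provider, s=0.0)
    Bmat = np.zeros((N + 1, N + 1))
    Bmat[:N, :N] = np.eye(N) + nu * M0
    Bmat[:N, N] = -1.0
    Bmat[N, :N] = 1.0
    Binv = np.linalg.inv(Bmat)
    L_A = -Binv[:N, :N]           # A = L_A phi
    l_u = -Binv[N, :N]            # u_inf = l_u . phi

    # step 2: homogeneous modified-Helmholtz solve at rate alpha+beta for
    # util = ubar_1 - (beta/geff) ubar, Dirichlet values (alpha/geff) phi
    Mg, _ = assemble_matrix_2d(config, provider, s=geff)
    Kg = np.eye(N) + nu * Mg
    L_B = -np.linalg.solve(Kg, np.eye(N)) * (swcfg.alpha / geff)

    # step 3: flux closure
    #   D nu [(beta/geff) A_j + B_j]/(eps ell_j) = -rho_1 J_j
    rho1 = swcfg.firing_fraction
    F = (swcfg.beta / geff) * L_A + L_B
    rhs = -rho1 * config.eps * config.ells * swcfg.J / (nu * D)
    cond = float(np.linalg.cond(F))
    if not np.isfinite(cond) or cond > 1e12:
        raise ConfigurationError(
            "no bounded steady state: flux-closure system is singular")
    phi = np.linalg.solve(F, rhs)
    A = L_A @ phi
    Bc = L_B @ phi
    resid = float(np.max(np.abs(F @ phi - rhs)))
    sol = SwitchingSolution(swcfg, phi, float(l_u @ phi), A, Bc, resid, cond)
    sol._prov = provider
    return sol


# ---------------------------------------------------------------------------
# Monte-Carlo finite-difference oracle
# ---------------------------------------------------------------------------

def _sample_chain(rng, alpha, beta, horizon):
    """Synchronous two-state trajectory: list of (t_start, state)."""
    t = 0.0
    state = 1 if rng.random() < beta / (alpha + beta) else 0
    events = [(0.0, state)]
    while t < horizon:
        rate = alpha if state == 1 else beta
        t += rng.exponential(1.0 / rate)
        state = 1 - state
        events.append((min(t, horizon), state))
    return events


def simulate_switching_fd(swcfg: SwitchingConfig, probes,
                          horizon: float = 4.0, reps: int = 200,
                          seed: int = 0, n: int = 800, dt: float = 1e-3,
                          burn_frac: float = 0.4):
    """Monte-Carlo conditional means at probe points.

    Requires a single concentric varicosity in the unit disk, for which the
    switching PDE is radial and can be integrated accurately with
    Crank-Nicolson on a fine 1D grid.  Each rep draws an independent
    environment trajectory; after a burn-in, the products u(x,t) 1_{N(t)=n}
    are time-averaged, and rep-to-rep scatter gives the standard errors.

    Returns dict with keys 'u0', 'u1' (means) and 'se0', 'se1'.
    """
    config = swcfg.config
    if config.domain.kind != "disk2d" or config.N != 1 \
            or np.linalg.norm(config.centers[0]) > 1e-12:
        raise ConfigurationError(
            "the radial MC oracle requires a single centred varicosity in "
            "the unit disk")
    D = config.domain.D
    eps = config.eps
    ell = config.ells[0]
    a = eps * ell
    J = float(swcfg.J[0])
    r = np.linspace(a, 1.0, n)
    h = r[1] - r[0]

    main = np.full(n, -2.0 * D / h**2)
    upper = D / h**2 + D / (2.0 * r[:-1] * h)
    lower = D / h**2 - D / (2.0 * r[1:] * h)
    L = sparse.diags([lower, main, upper], [-1, 0, 1], format="lil")
    L[n - 1, n - 2] = 2.0 * D / h**2     # reflecting outer boundary
    low0 = D / h**2 - D / (2.0 * a * h)

    # state 1 (firing): release flux D u'(a) = -J (ghost elimination)
    L1 = L.copy()
    L1[0, 1] = 2.0 * D / h**2
    rhs1 = np.zeros(n)
    rhs1[0] = low0 * 2.0 * h * J / D
    # state 0 (quiescent/absorbing): u(a) = 0
    L0 = L.copy()
    L0[0, :] = 0.0

    eye = sparse.identity(n, format="csr")
    ops = {}
    for st, (Ls, rr) in {1: (L1, rhs1), 0: (L0, np.zeros(n))}.items():
        Ls = sparse.csr_matrix(Ls)
        ops[st] = (splu((eye - 0.5 * dt * Ls).tocsc()),
                   (eye + 0.5 * dt * Ls).tocsr(), rr)

    probes = np.atleast_1d(np.asarray(probes, dtype=float))
    pidx = [int(np.argmin(np.abs(r - p))) for p in probes]
    burn = burn_frac * horizon
    rng = np.random.default_rng(seed)
    acc = np.zeros((reps, 2, len(pidx)))
    occ = np.zeros((reps, 2))
    nsteps = int(round(horizon / dt))
    for rep in range(reps):
        events = _sample_chain(rng, swcfg.alpha, swcfg.beta, horizon)
        u = np.zeros(n)
        ei = 0
        state = events[0][1]
        tavg = 0.0
        for k in range(nsteps):
            t = k * dt
            while ei + 1 < len(events) and events[ei + 1][0] <= t:
                ei += 1
                state = events[ei][1]
            lu, Aplus, rr = ops[state]
            u = lu.solve(Aplus @ u + dt * rr)
            if state == 0:
                u[0] = 0.0
            if t >= burn:
                acc[rep, state, :] += u[pidx] * dt
                occ[rep, state] += dt
                tavg += dt
        acc[rep] /= tavg
        occ[rep] /= tavg
    mean = acc.mean(axis=0)
    se = acc.std(axis=0, ddof=1) / math.sqrt(reps)
    return {
        "r": probes,
        "u0": mean[0], "se0": se[0],
        "u1": mean[1], "se1": se[1],
        "occupancy_firing": float(occ[:, 1].mean()),
        "occupancy_se": float(occ[:, 1].std(ddof=1) / math.sqrt(reps)),
    }
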