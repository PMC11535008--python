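"""Steady states of diffusion past N small interior compartments.

The bulk concentration u solves

    D lap u - gamma0 u + I0 = 0     outside the compartments,
    n . grad u = 0                  on the outer boundary,
    D n_j . grad u = (kappa_j / eps) (u - c_j)   on each compartment surface,

where each compartment has centre x_j, radius eps*ell_j and reactivity
kappa_j (kappa_j = inf is the Dirichlet limit).  The boundary value c_j is
a prescribed constant (model I), the interior concentration of a
semi-permeable compartment with its own diffusion/degradation/source
(model II), or the exchanged species of a well-mixed reaction network
(model III).

In 2D the matching problem is solved non-perturbatively in nu = -1/log(eps)
("summing the logarithms"): the coefficients A_j of the outer solution

    u(x) = -2 pi nu D sum_k A_k G(x, x_k)

satisfy (I + nu M) a = -c0 with M = Psi + 2 pi D Gmat.  When gamma0 = 0 the
outer solution carries an extra far-field constant u_inf, fixed together
with the solvability constraint sum_j A_j = 0 through a bordered linear
system.  In 3D the expansion is in powers of eps with trap strengths
Lambda_j = kappa_j ell_j^2/(kappa_j ell_j + D); the default keeps two terms
(the eps^2 interaction correction chi_j).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dfield

import numpy as np
from scipy import special as sp

from .domains import DomainSpec, GreensProvider, make_greens_provider


class ConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# configuration objects
# ---------------------------------------------------------------------------

@dataclass
class Compartment:
    """One small compartment (trap / synapse / droplet / cell).

    Parameters are the post-rescaling O(1) values: the physical reactivity
    is kappa/eps, and the model II interior source/degradation are
    Ibar/eps^2 and gbar/eps^2.
    """

    center: np.ndarray
    ell: float
    kappa: float = math.inf
    model: str = "I"
    c0: float = 0.0                 # model I boundary value
    Dbar: float = 1.0               # model II interior diffusivity
    gbar: float = 1.0               # model II interior degradation
    Ibar: float = 0.0               # model II interior source

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        if self.ell <= 0:
            raise ConfigurationError("compartment radius ell must be positive")
        if self.kappa < 0:
            raise ConfigurationError("reactivity kappa must be >= 0")
        if self.model not in ("I", "II", "III"):
            raise ConfigurationError(f"unknown compartment model {self.model!r}")
        if self.model == "II" and self.Ibar > 0 and self.gbar <= 0:
            raise ConfigurationError(
                "no interior steady state: model II needs gbar > 0 when Ibar > 0"
            )

    @property
    def psi(self) -> float:
        """Inner resistance Psi_j = D/(kappa ell) contribution is added by
        the caller (needs bulk D); this stores only 1/(kappa ell)."""
        return 0.0 if math.isinf(self.kappa) else 1.0 / (self.kappa * self.ell)


@dataclass
class CompartmentConfiguration:
    domain: DomainSpec
    eps: float
    compartments: list
    separation_mult: float = 10.0

    def __post_init__(self):
        if not (0.0 < self.eps < 1.0):
            raise ConfigurationError("epsilon must be in (0, 1)")
        ells = np.array([c.ell for c in self.compartments])
        if ells.size == 0:
            raise ConfigurationError("need at least one compartment")
        if abs(ells.max() - 1.0) > 1e-9:
            raise ConfigurationError(
                "scaled radii must satisfy max_j ell_j = 1 (definition of eps)"
            )
        centers = np.array([c.center for c in self.compartments])
        if centers.shape[1] != self.domain.dim:
            raise ConfigurationError("compartment centres must match domain dimension")
        thresh = self.separation_mult * self.eps
        if len(self.compartments) > 1:
            diff = centers[:, None, :] - centers[None, :, :]
            dists = np.sqrt((diff**2).sum(-1))
            np.fill_diagonal(dists, np.inf)
            if dists.min() < thresh:
                raise ConfigurationError(
                    f"compartments closer than {thresh:g} (well-separation violated)"
                )
        bdist = self.domain.boundary_distance(centers)
        if np.any(bdist < thresh):
            raise ConfigurationError(
                "compartment centre too close to the outer boundary"
            )
        if self.domain.I0 > 0 and self.domain.gamma0 <= 0:
            raise ConfigurationError("bulk source I0 > 0 requires gamma0 > 0")

    @property
    def nu(self) -> float:
        return -1.0 / math.log(self.eps)

    @property
    def N(self) -> int:
        return len(self.compartments)

    @property
    def centers(self) -> np.ndarray:
        return np.array([c.center for c in self.compartments])

    @property
    def ells(self) -> np.ndarray:
        return np.array([c.ell for c in self.compartments])

    @property
    def shift(self) -> float:
        """The uniform shift I0/gamma0 that removes a bulk source."""
        return self.domain.I0 / self.domain.gamma0 if self.domain.I0 > 0 else 0.0

    def compartment_volume(self, j: int) -> float:
        ell = self.compartments[j].ell
        if self.domain.dim == 2:
            return math.pi * (self.eps * ell) ** 2
        return 4.0 * math.pi * (self.eps * ell) ** 3 / 3.0


# ---------------------------------------------------------------------------
# model II conversions
# ---------------------------------------------------------------------------

def bessel_F(x):
    """F(x) = x I1(x) / I0(x); strictly increasing, F ~ x^2/2 for small x."""
    x = np.asarray(x, dtype=float)
    small = x < 1e-4
    with np.errstate(over="ignore"):
        full = np.where(small, 0.0, x * sp.i1(x) / sp.i0(x))
    approx = x**2 / 2.0 * (1.0 - x**2 / 8.0)
    return np.where(small, approx, full)


def model2_effective_2d(comp: Compartment, D: float):
    """Effective (c0, Psi) of a 2D semi-permeable compartment.

    The interior Bessel profile collapses onto the model-I matching
    condition with c0 = Ibar/gbar and
    Psi = D/(kappa ell) + D/(Dbar F(betabar ell)).
    """
    if comp.model != "II":
        raise TypeError("model II compartment required")
    if comp.gbar <= 0 or comp.Dbar <= 0:
        if comp.Ibar > 0:
            raise ConfigurationError("no interior steady state")
    c0 = comp.Ibar / comp.gbar
    bb = math.sqrt(comp.gbar / comp.Dbar)
    psi = D / (comp.Dbar * float(bessel_F(bb * comp.ell)))
    if not math.isinf(comp.kappa):
        psi += D / (comp.kappa * comp.ell)
    return c0, psi


def trap_strength(comp: Compartment, D: float) -> float:
    """3D trap strength Lambda_j = kappa ell^2/(kappa ell + D) (-> ell)."""
    if math.isinf(comp.kappa):
        return comp.ell
    return comp.kappa * comp.ell**2 / (comp.kappa * comp.ell + D)


def model2_inner_coefficient_3d(comp: Compartment, D: float):
    """Leading inner amplitudes (A_j, B_j) of a 3D semi-permeable compartment.

    Exterior U = A/rho; interior V = Ibar/gbar + B sinh(bb rho)/rho.
    """
    if comp.model != "II":
        raise TypeError("model II compartment required")
    if comp.Ibar == 0.0:
        return 0.0, 0.0
    ell = comp.ell
    bb = math.sqrt(comp.gbar / comp.Dbar)
    lam = trap_strength(comp, D)
    sh = math.sinh(bb * ell)
    ch = math.cosh(bb * ell)
    num = comp.Dbar * (bb * ell * ch - sh)
    den = D * sh / ell + comp.Dbar / lam * (bb * ell * ch - sh)
    A = num / den * comp.Ibar / comp.gbar
    B = -(D * A / ell) / (comp.Dbar * (bb * ch - sh / ell))
    return A, B


def _effective_c0_psi(config: CompartmentConfiguration, c0_override=None):
    """Per-compartment (c0, Psi) in model-I form, applying the I0 shift."""
    D = config.domain.D
    c0 = np.empty(config.N)
    psi = np.empty(config.N)
    for j, comp in enumerate(config.compartments):
        if comp.model == "II":
            c, p = model2_effective_2d(comp, D)
        else:
            c = comp.c0
            p = 0.0 if math.isinf(comp.kappa) else D / (comp.kappa * comp.ell)
        c0[j], psi[j] = c, p
    if c0_override is not None:
        c0 = np.asarray(c0_override, dtype=float).copy()
    c0 = c0 - config.shift
    return c0, psi


# ---------------------------------------------------------------------------
# 2D solver
# ---------------------------------------------------------------------------

@dataclass
class AsymptoticSolution2D:
    config: CompartmentConfiguration
    provider: GreensProvider
    A: np.ndarray
    Phi: np.ndarray
    Psi: np.ndarray
    c0: np.ndarray            # effective boundary values (after I0 shift)
    M: np.ndarray
    u_inf: float | None = None
    s: float = 0.0
    rho_switch_mult: float = 5.0

    @property
    def pseudo(self) -> bool:
        return self.u_inf is not None


def assemble_matrix_2d(config: CompartmentConfiguration,
                       provider: GreensProvider, s: float = 0.0):
    """Interaction matrix M_ji = Psi_j delta_ij + 2 pi D Gmat_ji and Psi.

    Gmat_jj = R(x_j, x_j; s) - log(ell_j)/(2 pi D); off-diagonal entries are
    Green's function values between centres.  The zero-degradation branch
    (gamma0 = 0, s = 0) uses the pseudo-Green's function.
    """
    D = config.domain.D
    N = config.N
    centers = config.centers
    _, psi = _effective_c0_psi(config)
    pseudo = (config.domain.gamma0 == 0.0 and s == 0.0)
    Gmat = np.empty((N, N))
    for j in range(N):
        if pseudo:
            Gmat[j, j] = provider.R0(centers[j])
        else:
            Gmat[j, j] = provider.R(centers[j], s=s)
        Gmat[j, j] -= math.log(config.compartments[j].ell) / (2.0 * math.pi * D)
        for i in range(N):
            if i == j:
                continue
            if pseudo:
                Gmat[j, i] = provider.G0(centers[j], centers[i])
            else:
                Gmat[j, i] = provider.G(centers[j], centers[i], s=s)
    M = np.diag(psi) + 2.0 * math.pi * D * Gmat
    return M, psi


def _solve_2d(config, provider, c0_eff, psi, s=0.0):
    """Core matching solve for given effective (c0, Psi)."""
    nu = config.nu
    M, _ = assemble_matrix_2d(config, provider, s=s)
    N = config.N
    K = np.eye(N) + nu * M
    pseudo = (config.domain.gamma0 == 0.0 and s == 0.0)
    try:
        if pseudo:
            B = np.zeros((N + 1, N + 1))
            B[:N, :N] = K
            B[:N, N] = -1.0
            B[N, :N] = 1.0
            rhs = np.concatenate([-c0_eff, [0.0]])
            sol = np.linalg.solve(B, rhs)
            A, u_inf = sol[:N], float(sol[N])
        else:
            A = np.linalg.solve(K, -c0_eff)
            u_inf = None
    except np.linalg.LinAlgError as exc:
        raise ConfigurationError(
            "matrix singular: compartments too close or nu too large"
        ) from exc
    Phi = c0_eff + nu * A * psi
    return A, Phi, M, u_inf


def solve_model1_2d(config: CompartmentConfiguration,
                    provider: GreensProvider | None = None,
                    s: float = 0.0) -> AsymptoticSolution2D:
    """Non-perturbative 2D matching solve (models I and II).

    Model II compartments are first mapped to effective (c0, Psi); model III
    compartments must be resolved through :func:`solve_model3`.
    """
    if config.domain.dim != 2:
        raise ConfigurationError("2D solver requires a 2D domain")
    if any(c.model == "III" for c in config.compartments):
        raise ConfigurationError("model III requires solve_model3")
    if provider is None:
        provider = make_greens_provider(config.domain)
    c0, psi = _effective_c0_psi(config)
    A, Phi, M, u_inf = _solve_2d(config, provider, c0, psi, s=s)
    return AsymptoticSolution2D(config, provider, A, Phi, psi, c0, M,
                                u_inf=u_inf, s=s)


def solve_two_step_gamma0(config, provider, c0=None):
    """Reference implementation of the zero-degradation solve via the
    explicit two-step construction (row sums of (I + nu M0)^-1)."""
    cfg_c0, psi = _effective_c0_psi(config, c0_override=c0)
    nu = config.nu
    M0, _ = assemble_matrix_2d(config, provider, s=0.0)
    Kinv = np.linalg.inv(np.eye(config.N) + nu * M0)
    u_inf = Kinv.sum(axis=0) @ cfg_c0 / Kinv.sum()
    A = Kinv @ (u_inf - cfg_c0)
    return A, float(u_inf)


# ---------------------------------------------------------------------------
# 3D solver
# ---------------------------------------------------------------------------

@dataclass
class AsymptoticSolution3D:
    config: CompartmentConfiguration
    provider: GreensProvider
    Lambda: np.ndarray
    chi: np.ndarray
    c0: np.ndarray
    order: str = "two-term"
    u_inf: float | None = None

    @property
    def pseudo(self) -> bool:
        return self.u_inf is not None


def solve_model1_3d(config: CompartmentConfiguration,
                    provider: GreensProvider | None = None,
                    order: str = "two-term") -> AsymptoticSolution3D:
    """Two-term (default) or one-term 3D expansion for models I / II."""
    if config.domain.dim != 3:
        raise ConfigurationError("3D solver requires a 3D domain")
    if order not in ("one-term", "two-term"):
        raise ConfigurationError("order must be 'one-term' or 'two-term'")
    if provider is None:
        provider = make_greens_provider(config.domain)
    D = config.domain.D
    N = config.N
    centers = config.centers
    lam = np.array([trap_strength(c, D) for c in config.compartments])
    c0 = np.empty(N)
    for j, comp in enumerate(config.compartments):
        if comp.model == "II":
            A_j, _ = model2_inner_coefficient_3d(comp, D)
            # interior source fixes the inner amplitude directly:
            # Lambda_j c_eff = A_j
            c0[j] = A_j / lam[j]
        else:
            c0[j] = comp.c0
    c0 = c0 - config.shift
    pseudo = config.domain.gamma0 == 0.0
    Gmat = np.empty((N, N))
    for j in range(N):
        Gmat[j, j] = provider.R0(centers[j]) if pseudo else provider.R(centers[j])
        for i in range(N):
            if i != j:
                Gmat[j, i] = (provider.G0(centers[j], centers[i]) if pseudo
                              else provider.G(centers[j], centers[i]))
    if pseudo:
        # chi_j = 4 pi D sum_k Gmat_jk Lambda_k (c_k - u_inf); u_inf solves
        # sum_j Lambda_j (c_j - u_inf - eps chi_j) = 0 (Laplacian solvability)
        q = 4.0 * math.pi * D * Gmat @ (lam * c0)
        p = 4.0 * math.pi * D * Gmat @ lam
        eps = config.eps if order == "two-term" else 0.0
        u_inf = float((lam * (c0 - eps * q)).sum() / (lam * (1.0 - eps * p)).sum())
        chi = q - u_inf * p
    else:
        u_inf = None
        chi = 4.0 * math.pi * D * Gmat @ (lam * c0)
    if order == "one-term":
        chi = np.zeros(N)
    return AsymptoticSolution3D(config, provider, lam, chi, c0,
                                order=order, u_inf=u_inf)


# ---------------------------------------------------------------------------
# field evaluation
# ---------------------------------------------------------------------------

def receptor_number(solution: AsymptoticSolution2D, j: int) -> float:
    """Steady-state receptor count in synapse j (2D, model II).

    N_j = pi eps^2 ell^2 Ibar/gbar + 2 pi nu D A_j eps^2 / gbar, where the
    second (heterosynaptic) term couples the synapse to all others through
    the matching coefficient A_j.
    """
    comp = solution.config.compartments[j]
    if comp.model != "II":
        raise TypeError("model II compartment required")
    eps = solution.config.eps
    D = solution.config.domain.D
    nu = solution.config.nu
    direct = math.pi * eps**2 * comp.ell**2 * comp.Ibar / comp.gbar
    hetero = 2.0 * math.pi * nu * D * float(solution.A[j]) * eps**2 / comp.gbar
    return direct + hetero


def _nearest_compartment(config, x):
    d = np.linalg.norm(config.centers - x[None, :], axis=1)
    j = int(np.argmin(d))
    return j, float(d[j])


def evaluate_field(solution, x, rho_switch_mult: float = 5.0):
    """Composite steady-state field at point(s) x.

    Within rho < rho_switch_mult * ell_j of centre j (stretched units) the
    inner solution is used; outside, the outer Green's-function sum.  Inside
    a model II compartment the interior Bessel profile is returned; model
    I/III interiors are not modelled and evaluate to NaN.
    """
    config = solution.config
    xs = np.atleast_2d(np.asarray(x, dtype=float))
    scalar = np.asarray(x).ndim == 1
    out = np.empty(xs.shape[0])
    inside = self_dom = config.domain.contains(xs)
    if not np.all(self_dom):
        raise ValueError("evaluation point outside the domain")
    for i, pt in enumerate(xs):
        j, dist = _nearest_compartment(config, pt)
        rho = dist / config.eps
        comp = config.compartments[j]
        if rho < rho_switch_mult * comp.ell:
            out[i] = _inner_value(solution, j, rho)
        else:
            out[i] = _outer_value(solution, pt[None, :])[0]
    return float(out[0]) if scalar else out


def _outer_value(solution, pts):
    config = solution.config
    D = config.domain.D
    prov = solution.provider
    centers = config.centers
    if isinstance(solution, AsymptoticSolution2D):
        nu = config.nu
        acc = np.zeros(pts.shape[0])
        for k in range(config.N):
            Gk = (prov.G0(pts, centers[k]) if solution.pseudo
                  else prov.G(pts, centers[k], s=solution.s))
            acc += solution.A[k] * Gk
        base = solution.u_inf if solution.pseudo else 0.0
        return config.shift + base - 2.0 * math.pi * nu * D * acc
    eps = config.eps
    acc = np.zeros(pts.shape[0])
    u_inf = solution.u_inf if solution.pseudo else 0.0
    for k in range(config.N):
        Gk = (prov.G0(pts, centers[k]) if solution.pseudo
              else prov.G(pts, centers[k]))
        amp = solution.Lambda[k] * (solution.c0[k] - u_inf - eps * solution.chi[k])
        acc += amp * Gk
    return config.shift + u_inf + 4.0 * math.pi * D * eps * acc


def _inner_value(solution, j, rho):
    config = solution.config
    comp = config.compartments[j]
    shift = config.shift
    if isinstance(solution, AsymptoticSolution2D):
        if rho >= comp.ell:
            U = solution.Phi[j] + config.nu * solution.A[j] * math.log(rho / comp.ell)
            return shift + U
        if comp.model != "II":
            return math.nan
        bb = math.sqrt(comp.gbar / comp.Dbar)
        Phibar = (config.nu * solution.A[j] * config.domain.D
                  / (comp.Dbar * float(bessel_F(bb * comp.ell))))
        return (comp.Ibar / comp.gbar
                + Phibar * sp.i0(bb * rho) / sp.i0(bb * comp.ell))
    # 3D
    u_inf = solution.u_inf if solution.pseudo else 0.0
    if rho >= comp.ell:
        amp = solution.Lambda[j] * (solution.c0[j] - u_inf
                                    - config.eps * solution.chi[j])
        return shift + u_inf + amp / rho
    if comp.model != "II":
        return math.nan
    A, B = model2_inner_coefficient_3d(comp, config.domain.D)
    bb = math.sqrt(comp.gbar / comp.Dbar)
    if rho == 0.0:
        return comp.Ibar / comp.gbar + B * bb
    return comp.Ibar / comp.gbar + B * math.sinh(bb * rho) / rho


# ---------------------------------------------------------------------------
# model III (well-mixed reaction compartments)
# ---------------------------------------------------------------------------

@dataclass
class Model3FixedPoint:
    w: np.ndarray          # (N, K+1) species concentrations per compartment
    residual: float
    solution: object       # the matched solution at c0 = w[:, 0]
    nfev: int = 0


def _latin_hypercube(rng, n, dim, lo=0.0, hi=2.0):
    cut = np.linspace(lo, hi, n + 1)
    pts = np.empty((n, dim))
    for d in range(dim):
        order = rng.permutation(n)
        pts[:, d] = cut[order] + rng.random(n) * (hi - lo) / n
    return pts


def solve_model3(config: CompartmentConfiguration,
                 provider: GreensProvider | None,
                 kinetics,
                 starts=None,
                 n_random_starts: int = 4,
                 seed: int = 0,
                 tol: float = 1e-10):
    """Fixed points of the coupled compartment-bulk system (model III).

    The exchanged species (index 0) couples compartments through the
    matching coefficients: in 2D, fhat_a(w_j) + 2 pi D nu A_j delta_{a,0} = 0
    with A from the model-I solve at c0 = w_{j,0}; in 3D the leading-order
    balance is fhat_a(w_j) - 4 pi D Lambda_j w_{j,0} delta_{a,0} = 0.
    Returns deduplicated fixed points found from all start points.
    """
    from scipy.optimize import root

    if provider is None:
        provider = make_greens_provider(config.domain)
    N = config.N
    K1 = kinetics.n_species
    D = config.domain.D
    nu = config.nu
    vols = np.array([config.compartment_volume(j) for j in range(N)])
    psi = np.array([
        0.0 if math.isinf(c.kappa) else D / (c.kappa * c.ell)
        for c in config.compartments
    ])
    lam = np.array([trap_strength(c, D) for c in config.compartments])
    two_d = config.domain.dim == 2

    def residual(vec):
        w = vec.reshape(N, K1)
        res = np.empty_like(w)
        if two_d:
            A, _, _, _ = _solve_2d(config, provider, w[:, 0] - config.shift, psi)
        for j in range(N):
            f = np.asarray(kinetics.f(w[j]))
            fhat = vols[j] * f
            res[j] = fhat
            if two_d:
                res[j, 0] += 2.0 * math.pi * D * nu * A[j]
            else:
                res[j, 0] -= 4.0 * math.pi * D * lam[j] * (w[j, 0] - config.shift)
        return res.ravel() / max(vols.max(), 1e-30)

    start_list = []
    if starts is not None:
        start_list.extend(np.asarray(s, dtype=float).ravel() for s in starts)
    fp_well_mixed = getattr(kinetics, "fixed_points", None)
    if fp_well_mixed is not None:
        for w in np.atleast_2d(fp_well_mixed()):
            start_list.append(np.tile(w, N))
    rng = np.random.default_rng(seed)
    for w in _latin_hypercube(rng, n_random_starts, K1):
        start_list.append(np.tile(w, N))

    found = []
    for x0 in start_list:
        sol = root(residual, x0, method="hybr", tol=1e-12)
        if not sol.success:
            continue
        r = float(np.linalg.norm(residual(sol.x)))
        if r > tol:
            continue
        w = sol.x.reshape(N, K1)
        dup = any(
            np.linalg.norm(w - f.w) <= 1e-6 * (1.0 + np.linalg.norm(f.w))
            for f in found
        )
        if dup:
            continue
        if two_d:
            matched = solve_model1_2d_from_c0(config, provider, w[:, 0])
        else:
            matched = None
        found.append(Model3FixedPoint(w, r, matched, nfev=sol.nfev))
    return found


def solve_model1_2d_from_c0(config, provider, c0_values):
    """Model-I 2D solve with explicit boundary constants (used by model III)."""
    _, psi = _effective_c0_psi(config)
    c0 = np.asarray(c0_values, dtype=float) - config.shift
    A, Phi, M, u_inf = _solve_2d(config, provider, c0, psi)
    return AsymptoticSolution2D(config, provider, A, Phi, psi, c0, M, u_inf=u_inf)
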