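"""Ostwald ripening of N well-separated droplets (leading-order theory).

Droplet interfaces obey the Gibbs-Thomson law c0(r) = phi_a (1 + ell_c/r):
smaller droplets carry a higher interfacial concentration, driving a net
diffusive flux from small to large droplets through the dilute phase.
Under the quasi-static (adiabatic) approximation the scaled radii follow

    2D:  dl_j/dtau = (D nu phi_a / (l_j phi_b)) (1/l_harm - 1/l_j)
    3D:  dl_j/dt   = (D phi_a ell_c / (phi_b l_j)) (1/l_av - 1/l_j)

with l_harm the harmonic and l_av the arithmetic mean over the surviving
droplets.  Both right-hand sides conserve the leading-order condensate
mass (sum l^2 in 2D, sum l^3 in 3D) identically, and the critical radius
(the mean) grows monotonically, so coarsening terminates in a single
droplet.  The ODEs are singular at l = 0; droplets are removed at a small
extinction threshold and the (tiny) residual mass is logged rather than
redistributed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp


@dataclass
class RipeningParams:
    phi_a: float                 # dilute-phase volume fraction
    phi_b: float                 # dense-phase volume fraction
    ell_c: float                 # capillary length
    D: float = 1.0
    eps: float = 0.02            # supplies nu in 2D
    dim: int = 3
    extinction_threshold: float = 1e-3   # fraction of initial mean radius

    def __post_init__(self):
        if not (self.phi_b > self.phi_a > 0):
            raise ValueError("need phi_b > phi_a > 0")
        if self.ell_c <= 0:
            raise ValueError("capillary length must be positive")
        if self.dim not in (2, 3):
            raise ValueError("dim must be 2 or 3")

    @property
    def nu(self) -> float:
        return -1.0 / math.log(self.eps)


def gibbs_thomson(r, params: RipeningParams):
    """Interfacial dilute-phase concentration c0(r) = phi_a (1 + ell_c/r)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("droplet radius must be positive")
    return params.phi_a * (1.0 + params.ell_c / r)


def ripening_rhs_2d(radii, params: RipeningParams):
    ell = np.asarray(radii, dtype=float)
    if np.any(ell <= 0):
        raise ValueError("extinct droplets must be removed before evaluating")
    inv_harm = np.mean(1.0 / ell)
    pref = params.D * params.nu * params.phi_a / (ell * params.phi_b)
    return pref * (inv_harm - 1.0 / ell)


def ripening_rhs_3d(radii, params: RipeningParams):
    ell = np.asarray(radii, dtype=float)
    if np.any(ell <= 0):
        raise ValueError("extinct droplets must be removed before evaluating")
    ell_av = ell.mean()
    pref = params.D * params.phi_a * params.ell_c / (params.phi_b * ell)
    return pref * (1.0 / ell_av - 1.0 / ell)


@dataclass
class RipeningTrajectory:
    t: np.ndarray                 # time grid (tau in 2D, t in 3D)
    radii: np.ndarray             # (N, nt); NaN after extinction
    alive: np.ndarray             # (N, nt) boolean
    extinction_times: dict        # droplet index -> time
    mass_leak: float              # conserved-mass lost to extinction events
    params: RipeningParams

    @property
    def conserved_mass(self) -> np.ndarray:
        p = 2 if self.params.dim == 2 else 3
        return np.nansum(np.where(self.alive, self.radii, 0.0) ** p, axis=0)

    @property
    def mean_radius(self) -> np.ndarray:
        """Critical radius over alive droplets: harmonic mean (2D) or
        arithmetic mean (3D)."""
        out = np.empty(self.t.size)
        for k in range(self.t.size):
            ell = self.radii[self.alive[:, k], k]
            if self.params.dim == 2:
                out[k] = 1.0 / np.mean(1.0 / ell)
            else:
                out[k] = ell.mean()
        return out

    @property
    def n_alive(self) -> np.ndarray:
        return self.alive.sum(axis=0)


def integrate_ripening(initial_radii, params: RipeningParams, horizon: float,
                       rtol: float = 1e-10, atol: float = 1e-12,
                       n_out: int = 200) -> RipeningTrajectory:
    """Adaptive integration with droplet-extinction events.

    A droplet is removed when its radius falls below the extinction
    threshold; the remaining system is re-integrated.  The terminal state
    always holds at least one droplet (a single droplet is stationary).
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    ell0 = np.asarray(initial_radii, dtype=float)
    if ell0.ndim != 1 or ell0.size < 1 or np.any(ell0 <= 0):
        raise ValueError("need >= 1 positive initial radius")
    N = ell0.size
    thresh = params.extinction_threshold * ell0.mean()
    rhs = ripening_rhs_2d if params.dim == 2 else ripening_rhs_3d
    p = 2 if params.dim == 2 else 3

    times = [0.0]
    snaps = [ell0.copy()]
    alive_idx = list(range(N))
    alive_snaps = [list(alive_idx)]
    ext_times = {}
    mass_leak = 0.0
    t0 = 0.0
    y = ell0.copy()
    while t0 < horizon:
        if len(alive_idx) == 1:
            times.append(horizon)
            snaps.append(y.copy())
            alive_snaps.append(list(alive_idx))
            break

        def event(t, yy):
            return yy.min() - thresh

        event.terminal = True
        event.direction = -1
        sol = solve_ivp(lambda t, yy: rhs(yy, params), (t0, horizon), y,
                        rtol=rtol, atol=atol, events=event, dense_output=True,
                        method="RK45")
        seg_t = np.linspace(t0, sol.t[-1], max(int(n_out * (sol.t[-1] - t0)
                                                   / horizon), 4))
        for tt in seg_t[1:]:
            times.append(float(tt))
            snaps.append(sol.sol(tt))
            alive_snaps.append(list(alive_idx))
        t0 = float(sol.t[-1])
        y = sol.y[:, -1].copy()
        if sol.status == 1:  # extinction event
            gone = int(np.argmin(y))
            mass_leak += float(y[gone] ** p)
            ext_times[alive_idx[gone]] = t0
            alive_idx = alive_idx[:gone] + alive_idx[gone + 1:]
            y = np.delete(y, gone)
        elif sol.status != 0:
            raise RuntimeError(f"ripening integration failed: {sol.message}")

    nt = len(times)
    radii = np.full((N, nt), np.nan)
    alive = np.zeros((N, nt), dtype=bool)
    for k, (snap, aidx) in enumerate(zip(snaps, alive_snaps)):
        radii[aidx, k] = snap
        alive[aidx, k] = True
    return RipeningTrajectory(np.asarray(times), radii, alive, ext_times,
                              mass_leak, params)
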