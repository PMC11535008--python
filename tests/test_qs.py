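"""Quorum-sensing reduction, Hopf detection, Kuramoto variant."""

import math

import numpy as np
import pytest

from singtrap import (Compartment, CompartmentConfiguration, DomainSpec,
                      KuramotoSystem, LinearDecayKinetics, SelkovKinetics,
                      build_reduced_system, hopf_scan, identical_cell_A,
                      kuramoto_simulate, reduced_fixed_point,
                      simulate_reduced, simulate_well_mixed)
from singtrap.qs import system_jacobian


def ring_config(N=3, radius=0.5, kappa=2e-3, eps=0.05, gamma0=0.5):
    dom = DomainSpec("disk2d", (1.0,), D=1.0, gamma0=gamma0)
    comps = []
    for j in range(N):
        th = 2 * math.pi * j / N
        comps.append(Compartment(
            radius * np.array([math.cos(th), math.sin(th)]), 1.0, kappa,
            "III"))
    return CompartmentConfiguration(dom, eps, comps)


def test_W_tends_to_identity():
    cfg = ring_config(N=3)
    s = build_reduced_system(cfg, SelkovKinetics(), D0=1e8)
    assert np.abs(s.W - np.eye(3)).max() < 1e-6
    # deviation scales like 1/D0
    devs = [np.abs(build_reduced_system(cfg, SelkovKinetics(), D0=d0).W
                   - np.eye(3)).max() for d0 in (1e2, 1e3, 1e4)]
    assert devs[0] / devs[1] == pytest.approx(10.0, rel=0.2)
    assert devs[1] / devs[2] == pytest.approx(10.0, rel=0.2)


def test_ring_coupling_is_circulant():
    cfg = ring_config(N=4)
    s = build_reduced_system(cfg, SelkovKinetics(), D0=2.0)
    W = s.W
    for shift in range(1, 4):
        np.testing.assert_allclose(W, np.roll(np.roll(W, shift, 0), shift, 1),
                                   atol=1e-10)


def test_matching_system_residual_and_identical_route():
    cfg = ring_config(N=3)
    s = build_reduced_system(cfg, SelkovKinetics(), D0=3.0)
    rng = np.random.default_rng(0)
    ubar = 0.7
    w0 = rng.uniform(0.2, 1.5, 3)
    A = s.solve_A(ubar, w0)
    assert np.abs(s.coupling @ A - (ubar - w0)).max() < 1e-12
    np.testing.assert_allclose(A, identical_cell_A(s, ubar, w0), atol=1e-13)


def test_heterogeneous_cells_have_no_W():
    dom = DomainSpec("disk2d", (1.0,), D=1.0, gamma0=0.5)
    cfg = CompartmentConfiguration(dom, 0.05, [
        Compartment(np.array([0.5, 0.0]), 1.0, 2e-3, "III"),
        Compartment(np.array([-0.5, 0.0]), 1.0, 5e-3, "III")])
    s = build_reduced_system(cfg, SelkovKinetics(), D0=2.0)
    assert s.W is None
    with pytest.raises(Exception):
        identical_cell_A(s, 0.5, np.array([0.2, 0.3]))


def test_zero_kinetics_zero_kappa_decay():
    """kappa -> 0: ubar decays exponentially at gamma0 and w stays put."""

    class ZeroKinetics:
        n_species = 1

        def f(self, w):
            return np.zeros_like(np.asarray(w, dtype=float))

        def fixed_points(self):
            return np.zeros((1, 1))

    cfg = ring_config(N=2, kappa=1e-12, gamma0=0.8)
    s = build_reduced_system(cfg, ZeroKinetics(), D0=1.0)
    t, u, w = simulate_reduced(s, 1.0, np.full((2, 1), 0.4), horizon=3.0)
    np.testing.assert_allclose(u, np.exp(-0.8 * t), atol=1e-6)
    np.testing.assert_allclose(w, 0.4, atol=1e-8)


def test_well_mixed_limit_convergence():
    """Reduced trajectories approach the classical well-mixed model with a
    sup-norm gap shrinking like 1/D0."""
    cfg = ring_config(N=2, kappa=2e-3)
    kin = SelkovKinetics()
    w_init = np.array([[1.0, 0.5], [1.2, 0.6]])
    gaps = []
    for D0 in (10.0, 100.0, 1000.0):
        s = build_reduced_system(cfg, kin, D0=D0)
        t, u, w = simulate_reduced(s, 0.5, w_init, horizon=10.0,
                                   rtol=1e-11, atol=1e-13)
        t2, u2, w2 = simulate_well_mixed(kin, 2, s.kappa_hat,
                                         s.alpha_frac_reduction, 0.5, 0.5,
                                         w_init, 10.0, rtol=1e-11, atol=1e-13)
        gaps.append(max(np.max(np.abs(u - u2)), np.max(np.abs(w - w2))))
    slope = np.polyfit(np.log([10.0, 100.0, 1000.0]), np.log(gaps), 1)[0]
    assert slope == pytest.approx(-1.0, abs=0.15)


def test_symmetry_preserved_in_time():
    cfg = ring_config(N=3)
    s = build_reduced_system(cfg, SelkovKinetics(), D0=2.0)
    w_init = np.tile([1.1, 0.7], (3, 1))
    t, u, w = simulate_reduced(s, 0.3, w_init, horizon=20.0)
    assert np.max(np.abs(w[0] - w[1])) < 1e-10
    assert np.max(np.abs(w[0] - w[2])) < 1e-10


def test_selkov_fixed_point_and_local_stability():
    kin = SelkovKinetics(alpha=0.5, eps_s=0.15, mu=2.3)
    w = kin.fixed_points()[0]
    assert np.abs(kin.f(w)).max() < 1e-12
    # just above the upper Hopf point: stable
    lam = np.linalg.eigvals(kin.jac(w))
    assert lam.real.max() < 0
    # inside the oscillatory window: unstable spiral
    kin2 = SelkovKinetics(alpha=0.5, eps_s=0.15, mu=2.0)
    lam2 = np.linalg.eigvals(kin2.jac(kin2.fixed_points()[0]))
    assert lam2.real.max() > 0
    assert np.abs(lam2.imag).max() > 0
    with pytest.raises(ValueError):
        kin.f(np.array([-0.5, 1.0]))


def test_isolated_cell_limit_cycle_above_threshold():
    """Direct integration: above the Hopf point the oscillation amplitude
    saturates instead of decaying."""
    from scipy.integrate import solve_ivp

    kin = SelkovKinetics(alpha=0.5, eps_s=0.15, mu=2.0)
    w0 = kin.fixed_points()[0] * 1.02
    sol = solve_ivp(lambda t, y: kin.f(y), (0, 600), w0, rtol=1e-9,
                    atol=1e-11, dense_output=True)
    late = sol.sol(np.linspace(400, 600, 800))[0]
    early = sol.sol(np.linspace(100, 300, 800))[0]
    amp_late = late.max() - late.min()
    amp_early = early.max() - early.min()
    assert amp_late > 0.1
    assert amp_late == pytest.approx(amp_early, rel=0.2)  # saturated


def test_hopf_scan_matches_direct_simulation():
    """The eigenvalue crossing brackets the onset of sustained oscillation."""
    cfg = ring_config(N=2, radius=0.5, kappa=2e-3, gamma0=0.2)

    def mk(mu):
        return build_reduced_system(cfg, SelkovKinetics(mu=mu), D0=1.0)

    grid = np.linspace(1.9, 2.2, 7)
    rep = hopf_scan(mk, grid)
    assert len(rep.crossings) == 1
    mu_c = rep.crossings[0]
    for mu, expect_osc in ((mu_c - 0.05, False), (mu_c + 0.05, True)):
        s = mk(mu)
        y0 = reduced_fixed_point(s)
        y0[0] += 0.01
        t, u, w = simulate_reduced(s, y0[0], y0[1:].reshape(2, 2),
                                   horizon=600.0, n_out=1500)
        late = w[0, 0, 900:]
        amp = late.max() - late.min()
        assert (amp > 0.05) == expect_osc


def test_hopf_scan_pure_decay_no_crossing():
    cfg = ring_config(N=2, kappa=2e-3, gamma0=0.5)

    def mk(lam):
        return build_reduced_system(cfg, LinearDecayKinetics(lam=lam), D0=1.0)

    rep = hopf_scan(mk, np.linspace(0.5, 2.0, 5))
    assert rep.crossings == []
    assert np.all(rep.max_real[np.isfinite(rep.max_real)] < 0)


def test_symmetric_two_cell_jacobian_block_symmetry():
    cfg = ring_config(N=2, kappa=2e-3)
    s = build_reduced_system(cfg, SelkovKinetics(), D0=1.0)
    y = reduced_fixed_point(s)
    J = system_jacobian(s, y)
    # swapping the two identical cells leaves the Jacobian invariant
    P = np.eye(5)
    P[[1, 2, 3, 4]] = P[[3, 4, 1, 2]]
    np.testing.assert_allclose(J, P @ J @ P.T, atol=1e-6)


# ---------------------------------------------------------------------------
# Kuramoto
# ---------------------------------------------------------------------------

def test_kuramoto_synchronises_identical_oscillators():
    ks = KuramotoSystem(N=12, kappa_hat=4.0, alpha=1.0, gamma0=0.3,
                        freq_scale=0.0)
    t, theta, z, abar = kuramoto_simulate(ks, 60.0, seed=2)
    assert np.all(abar <= 1.0 + 1e-9)
    assert abar[-1] > 0.99


def test_kuramoto_decoupled_limit():
    ks = KuramotoSystem(N=5, kappa_hat=0.0, gamma0=0.4, freq_scale=1.0)
    t, theta, z, abar = kuramoto_simulate(ks, 10.0, seed=3)
    omega, theta0 = ks.sample(3)
    np.testing.assert_allclose(theta[:, -1] - theta[:, 0], omega * 10.0,
                               atol=1e-6)
    assert abs(z[-1]) < 1e-2  # medium decays


def test_kuramoto_W_identity_matches_direct_integrator():
    """The W-coupled integrator at W = I reproduces an independently coded
    direct integrator of the unweighted medium-coupled model."""
    from scipy.integrate import solve_ivp

    N = 6
    ks = KuramotoSystem(N=N, kappa_hat=2.0, alpha=0.8, gamma0=0.5,
                        omega0=0.3, freq_scale=0.5)
    horizon = 20.0
    t, theta, z, abar = kuramoto_simulate(ks, horizon, seed=5)
    omega, theta0 = ks.sample(5)

    def direct_rhs(t, y):
        th = y[:N]
        zz = y[N] + 1j * y[N + 1]
        dth = omega + ks.kappa_hat * abs(zz) * np.sin(np.angle(zz) - th)
        dz = (ks.alpha * ks.kappa_hat / N) * (np.exp(1j * th) - zz).sum() \
            - (ks.gamma0 + 1j * ks.omega0) * zz
        return np.concatenate([dth, [dz.real, dz.imag]])

    y0 = np.concatenate([theta0, [0.1, 0.0]])
    ref = solve_ivp(direct_rhs, (0, horizon), y0, rtol=1e-9, atol=1e-11,
                    t_eval=t)
    np.testing.assert_allclose(theta, ref.y[:N], atol=1e-6)
    np.testing.assert_allclose(z.real, ref.y[N], atol=1e-6)
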