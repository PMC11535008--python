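"""Steady-state solvers vs exact radial solutions, FD oracles and limits."""

import math

import numpy as np
import pytest

from singtrap import (Compartment, CompartmentConfiguration,
                      ConfigurationError, DomainSpec, FixtureConfig,
                      assemble_matrix_2d, bessel_F, evaluate_field,
                      exact_annulus_2d, exact_shell_3d, fd_solve_2d,
                      generate_configuration, make_greens_provider,
                      model2_effective_2d, model2_inner_coefficient_3d,
                      receptor_number, solve_model1_2d, solve_model1_3d,
                      solve_model3, trap_strength)
from singtrap.qs import LinearDecayKinetics, SelkovKinetics
from singtrap.steady import solve_two_step_gamma0, solve_model1_2d_from_c0
from singtrap.validation import fd_radial_steady

from conftest import concentric_config


# ---------------------------------------------------------------------------
# 2D matrix assembly and model I
# ---------------------------------------------------------------------------

def test_single_compartment_matrix_entry(disk_provider):
    """N=1: M is 1x1 with entry Psi + 2 pi D R - log(ell)."""
    dom = disk_provider.domain
    x1 = np.array([0.2, 0.1])
    kappa = 4.0
    # max ell must be 1 by definition of eps
    with pytest.raises(ConfigurationError):
        CompartmentConfiguration(
            dom, 0.05, [Compartment(x1, 0.8, kappa, "I", c0=2.0)])
    cfg = CompartmentConfiguration(
        dom, 0.05, [Compartment(x1, 1.0, kappa, "I", c0=2.0)])
    M, psi = assemble_matrix_2d(cfg, disk_provider)
    expect = 1.0 / (kappa * 1.0) + 2 * math.pi * disk_provider.R(x1) \
        - math.log(1.0)
    assert M[0, 0] == pytest.approx(expect, rel=1e-12)
    sol = solve_model1_2d(cfg, disk_provider)
    assert sol.A[0] == pytest.approx(-2.0 / (1 + cfg.nu * M[0, 0]), rel=1e-12)


def test_mirror_symmetric_matrix(disk_provider):
    dom = disk_provider.domain
    cfg = CompartmentConfiguration(dom, 0.04, [
        Compartment(np.array([0.5, 0.0]), 1.0, 3.0, "I", c0=1.0),
        Compartment(np.array([-0.5, 0.0]), 1.0, 3.0, "I", c0=1.0)])
    M, _ = assemble_matrix_2d(cfg, disk_provider)
    assert M[0, 0] == pytest.approx(M[1, 1], rel=1e-12)
    assert M[0, 1] == pytest.approx(M[1, 0], rel=1e-12)


def test_exact_annulus_convergence():
    """Concentric Dirichlet compartment: asymptotic field converges to the
    Bessel closed form; < 2% at eps = 0.01 and monotone in eps."""
    errs = []
    for eps in (0.04, 0.02, 0.01):
        cfg = concentric_config(eps=eps)
        sol = solve_model1_2d(cfg)
        ex = exact_annulus_2d(1.0, eps, math.inf, 1.0, 1.0, 1.0)
        ua = evaluate_field(sol, np.array([0.5, 0.0]))
        errs.append(abs(ua - float(ex(0.5))) / abs(float(ex(0.5))))
    assert errs[0] > errs[1] > errs[2]
    assert errs[2] < 0.02


def test_dirichlet_limit(disk_provider):
    """kappa = 1e8 and kappa = inf agree to 1e-6."""
    dom = disk_provider.domain
    sols = []
    for kappa in (1e8, math.inf):
        cfg = CompartmentConfiguration(dom, 0.03, [
            Compartment(np.array([0.3, -0.2]), 1.0, kappa, "I", c0=1.5)])
        sols.append(solve_model1_2d(cfg, disk_provider).A[0])
    assert sols[0] == pytest.approx(sols[1], abs=1e-6)


# ---------------------------------------------------------------------------
# zero-degradation branch
# ---------------------------------------------------------------------------

def test_gamma0_solvability_and_two_step(disk0_provider):
    fix = FixtureConfig(seed=5, N=5, eps=0.02, gamma0=0.0, dirichlet=True)
    cfg = generate_configuration(fix)
    sol = solve_model1_2d(cfg, disk0_provider)
    assert abs(sol.A.sum()) < 1e-12
    A2, ui2 = solve_two_step_gamma0(cfg, disk0_provider)
    np.testing.assert_allclose(sol.A, A2, atol=1e-10)
    assert sol.u_inf == pytest.approx(ui2, abs=1e-10)


def test_uniform_boundary_values_give_uniform_field(disk0_provider):
    dom = disk0_provider.domain
    cfg = CompartmentConfiguration(dom, 0.03, [
        Compartment(np.array([0.4, 0.0]), 1.0, math.inf, "I", c0=2.5),
        Compartment(np.array([-0.4, 0.1]), 1.0, math.inf, "I", c0=2.5)])
    sol = solve_model1_2d(cfg, disk0_provider)
    assert np.max(np.abs(sol.A)) < 1e-12
    assert sol.u_inf == pytest.approx(2.5, abs=1e-12)
    assert evaluate_field(sol, np.array([0.1, 0.6])) == pytest.approx(2.5)


def test_leading_order_consistency(disk0_provider):
    """O(nu) expansion of the non-perturbative solve: A_j ~ u_inf - c_j and
    u_inf ~ mean(c) with O(nu) error."""
    dom = disk0_provider.domain
    c_vals = [1.0, 2.0]
    cfg = CompartmentConfiguration(dom, 1e-4, [
        Compartment(np.array([0.45, 0.0]), 1.0, math.inf, "I", c0=c_vals[0]),
        Compartment(np.array([-0.45, 0.0]), 1.0, math.inf, "I", c0=c_vals[1])])
    sol = solve_model1_2d(cfg, disk0_provider)
    cbar = np.mean(c_vals)
    assert sol.u_inf == pytest.approx(cbar, abs=5 * cfg.nu)
    np.testing.assert_allclose(sol.A, sol.u_inf - np.array(c_vals),
                               atol=5 * cfg.nu)


def test_spatial_average_equals_u_inf(disk0_provider):
    """gamma0 = 0: the domain average of the outer field is u_inf."""
    from singtrap import singular_quadrature

    dom = disk0_provider.domain
    cfg = CompartmentConfiguration(dom, 0.02, [
        Compartment(np.array([0.4, 0.0]), 1.0, math.inf, "I", c0=2.0),
        Compartment(np.array([-0.4, 0.0]), 0.7, math.inf, "I", c0=0.5)])
    sol = solve_model1_2d(cfg, disk0_provider)
    # integrate the outer field term by term, adapting the quadrature to
    # the log singularity of each Green's term
    mean = sol.u_inf
    for k, xc in enumerate(cfg.centers):
        pts, w = singular_quadrature(dom, xc, n_ang=96)
        integral = float((disk0_provider.G0(pts, xc) * w).sum())
        mean -= 2 * math.pi * cfg.nu * dom.D * sol.A[k] * integral / dom.volume
    assert mean == pytest.approx(sol.u_inf, abs=1e-6)


# ---------------------------------------------------------------------------
# 3D
# ---------------------------------------------------------------------------

def test_exact_shell_order_of_accuracy():
    """Two-term 3D error shrinks by >= 4x when eps halves."""
    errs = []
    for eps in (0.04, 0.02):
        cfg = concentric_config(eps=eps, kind="sphere3d")
        sol = solve_model1_3d(cfg)
        ex = exact_shell_3d(1.0, eps, math.inf, 1.0, 1.0, 1.0)
        ua = evaluate_field(sol, np.array([0.5, 0.0, 0.0]))
        errs.append(abs(ua - float(ex(0.5))) / float(ex(0.5)))
    assert errs[0] / errs[1] >= 4.0


def test_trap_strength_limits():
    c = Compartment(np.zeros(3), 0.7, math.inf, "I")
    assert trap_strength(c, 1.0) == 0.7
    c2 = Compartment(np.zeros(3), 0.7, 5.0, "I")
    lam = trap_strength(c2, 1.0)
    assert 0 < lam < 0.7
    assert lam == pytest.approx(5.0 * 0.49 / (3.5 + 1.0))


def test_3d_gamma0_uniform_limit(sphere_provider):
    """Equal c, kappa, ell: u_inf = c and the two-term field is uniform."""
    dom = DomainSpec("sphere3d", (1.0,), D=1.0, gamma0=0.0)
    prov = make_greens_provider(dom)
    cfg = CompartmentConfiguration(dom, 0.03, [
        Compartment(np.array([0.45, 0.0, 0.0]), 1.0, 4.0, "I", c0=1.2),
        Compartment(np.array([-0.45, 0.0, 0.0]), 1.0, 4.0, "I", c0=1.2)])
    sol = solve_model1_3d(cfg, prov)
    assert sol.u_inf == pytest.approx(1.2, abs=1e-10)
    val = evaluate_field(sol, np.array([0.0, 0.5, 0.0]))
    assert val == pytest.approx(1.2, abs=1e-10)


def test_3d_u_inf_is_lambda_weighted_mean():
    dom = DomainSpec("sphere3d", (1.0,), D=1.0, gamma0=0.0)
    prov = make_greens_provider(dom)
    cfg = CompartmentConfiguration(dom, 0.03, [
        Compartment(np.array([0.4, 0.0, 0.0]), 1.0, math.inf, "I", c0=2.0),
        Compartment(np.array([-0.4, 0.1, 0.0]), 0.6, 3.0, "I", c0=0.5)])
    sol = solve_model1_3d(cfg, prov)
    lam = sol.Lambda
    expect = (lam * (sol.c0 - cfg.eps * sol.chi)).sum() / lam.sum()
    assert sol.u_inf == pytest.approx(expect, rel=1e-12)


# ---------------------------------------------------------------------------
# model II
# ---------------------------------------------------------------------------

def test_bessel_F_properties():
    x = np.linspace(1e-6, 10, 2000)
    F = bessel_F(x)
    assert np.all(np.diff(F) > 0)
    assert bessel_F(1e-4) == pytest.approx(0.5e-8, rel=1e-3)
    # cross-check against an independent Bessel route
    from scipy.special import iv

    assert float(bessel_F(1.0)) == pytest.approx(iv(1, 1.0) / iv(0, 1.0),
                                                 abs=1e-12)


def test_model2_effective_small_argument():
    """betabar*ell -> 0: Psi ~ D/(kappa ell) + 2 D/(gbar ell^2)."""
    D = 1.3
    comp = Compartment(np.zeros(2), 0.5, 2.0, "II", Dbar=1e8, gbar=4e-8 * 1e8,
                       Ibar=0.0)
    # betabar = sqrt(gbar/Dbar) = 2e-4; betabar*ell = 1e-4
    c0, psi = model2_effective_2d(comp, D)
    expect = D / (2.0 * 0.5) + 2.0 * D / ((4e-8 * 1e8) * 0.25)
    assert psi == pytest.approx(expect, rel=1e-6)
    assert c0 == 0.0


def test_model2_zero_source():
    comp = Compartment(np.zeros(2), 0.5, 2.0, "II", Dbar=0.7, gbar=1.1,
                       Ibar=0.0)
    c0, _ = model2_effective_2d(comp, 1.0)
    assert c0 == 0.0


def test_receptor_number_quadrature_identity(disk_provider):
    """The closed-form receptor count equals direct quadrature of the
    interior Bessel profile."""
    from scipy.integrate import quad
    from scipy.special import i0

    dom = disk_provider.domain
    eps = 0.04
    comp = Compartment(np.array([0.3, 0.0]), 1.0, 5.0, "II",
                       Dbar=0.8, gbar=1.2, Ibar=0.6)
    cfg = CompartmentConfiguration(dom, eps, [comp])
    sol = solve_model1_2d(cfg, disk_provider)
    Nj = receptor_number(sol, 0)
    # direct: N = 2 pi eps^2 int_0^ell V(rho) rho drho
    bb = math.sqrt(comp.gbar / comp.Dbar)
    Phibar = cfg.nu * sol.A[0] * dom.D / (comp.Dbar * float(bessel_F(bb)))
    V = lambda rho: comp.Ibar / comp.gbar + Phibar * i0(bb * rho) / i0(bb)
    integral, _ = quad(lambda rho: V(rho) * rho, 0.0, 1.0, epsabs=1e-14)
    assert Nj == pytest.approx(2 * math.pi * eps**2 * integral, rel=1e-8)


def test_two_identical_synapses_equal_counts(disk_provider):
    dom = disk_provider.domain
    mk = lambda x: Compartment(np.array(x), 1.0, 5.0, "II", Dbar=0.8,
                               gbar=1.2, Ibar=0.6)
    cfg = CompartmentConfiguration(dom, 0.04, [mk([0.4, 0.0]), mk([-0.4, 0.0])])
    sol = solve_model1_2d(cfg, disk_provider)
    assert receptor_number(sol, 0) == pytest.approx(receptor_number(sol, 1),
                                                    rel=1e-12)


def test_model2_3d_flux_continuity():
    """The returned inner coefficients satisfy all three interface flux
    relations to machine precision."""
    comp = Compartment(np.zeros(3), 0.8, 3.0, "II", Dbar=0.6, gbar=2.0,
                       Ibar=1.0)
    D = 1.4
    A, B = model2_inner_coefficient_3d(comp, D)
    ell, bb = comp.ell, math.sqrt(comp.gbar / comp.Dbar)
    dU = -D * A / ell**2
    dV = comp.Dbar * B * (bb * math.cosh(bb * ell) / ell
                          - math.sinh(bb * ell) / ell**2)
    U_l = A / ell
    V_l = comp.Ibar / comp.gbar + B * math.sinh(bb * ell) / ell
    robin = comp.kappa * (U_l - V_l)
    assert dU == pytest.approx(dV, abs=1e-10)
    assert dU == pytest.approx(robin, abs=1e-10)


def test_model2_3d_reaction_dominated_limit():
    """betabar*ell >> 1 (fast interior kinetics at fixed Dbar):
    A_j -> Lambda_j Ibar/gbar with relative error D Lambda/(Dbar betabar
    ell^2)."""
    comp = Compartment(np.zeros(3), 1.0, 0.1, "II", Dbar=1.0, gbar=100.0,
                       Ibar=0.7)   # betabar*ell = 10
    D = 1.0
    A, _ = model2_inner_coefficient_3d(comp, D)
    lam = trap_strength(comp, D)
    assert A == pytest.approx(lam * comp.Ibar / comp.gbar, rel=0.01)


def test_model2_3d_zero_source():
    comp = Compartment(np.zeros(3), 1.0, 3.0, "II", Dbar=0.5, gbar=1.0,
                       Ibar=0.0)
    A, B = model2_inner_coefficient_3d(comp, 1.0)
    assert A == 0.0 and B == 0.0


# ---------------------------------------------------------------------------
# model III
# ---------------------------------------------------------------------------

def test_model3_linear_decay_unique_zero(disk_provider):
    dom = disk_provider.domain
    cfg = CompartmentConfiguration(dom, 0.05, [
        Compartment(np.array([0.3, 0.0]), 1.0, 2.0, "III"),
        Compartment(np.array([-0.3, 0.2]), 1.0, 2.0, "III")])
    fps = solve_model3(cfg, disk_provider, LinearDecayKinetics(lam=1.0))
    assert len(fps) == 1
    np.testing.assert_allclose(fps[0].w, 0.0, atol=1e-8)


def test_model3_symmetric_cells_symmetric_fixed_point(disk_provider):
    dom = disk_provider.domain
    cfg = CompartmentConfiguration(dom, 0.05, [
        Compartment(np.array([0.5, 0.0]), 1.0, 0.002, "III"),
        Compartment(np.array([-0.5, 0.0]), 1.0, 0.002, "III")])
    kin = SelkovKinetics()
    fps = solve_model3(cfg, disk_provider, kin)
    assert fps, "no fixed point found"
    for fp in fps:
        np.testing.assert_allclose(fp.w[0], fp.w[1], atol=1e-8)
        assert fp.residual < 1e-10


def test_model3_selkov_vs_grid_search(disk_provider):
    """Single cell: the root matches a brute-force grid + polish search."""
    from scipy.optimize import minimize

    dom = disk_provider.domain
    cfg = CompartmentConfiguration(dom, 0.05, [
        Compartment(np.array([0.1, 0.0]), 1.0, 0.002, "III")])
    kin = SelkovKinetics(mu=2.0)
    fps = solve_model3(cfg, disk_provider, kin)
    assert len(fps) >= 1

    # independent objective: squared residual of the coupled system
    from singtrap.steady import _solve_2d, _effective_c0_psi
    vol = cfg.compartment_volume(0)
    _, psi = _effective_c0_psi(cfg)

    def sq_res(w):
        A, _, _, _ = _solve_2d(cfg, disk_provider, np.array([w[0]]), psi)
        f = kin.f(w)
        r0 = vol * f[0] + 2 * math.pi * dom.D * cfg.nu * A[0]
        r1 = vol * f[1]
        return r0**2 + r1**2

    best, bval = None, np.inf
    for w0 in np.linspace(0.05, 3.0, 18):
        for w1 in np.linspace(0.05, 3.0, 18):
            v = sq_res([w0, w1])
            if v < bval:
                best, bval = np.array([w0, w1]), v
    polished = minimize(sq_res, best, method="Nelder-Mead",
                        options={"xatol": 1e-12, "fatol": 1e-24})
    np.testing.assert_allclose(fps[0].w[0], polished.x, atol=1e-5)


# ---------------------------------------------------------------------------
# composite field evaluation
# ---------------------------------------------------------------------------

def test_outer_boundary_no_flux(disk_provider):
    cfg = CompartmentConfiguration(disk_provider.domain, 0.03, [
        Compartment(np.array([0.3, 0.0]), 1.0, math.inf, "I", c0=1.0)])
    sol = solve_model1_2d(cfg, disk_provider)
    n_hat = np.array([math.cos(2.2), math.sin(2.2)])
    h = 1e-4
    u1 = evaluate_field(sol, (1.0 - 2 * h) * n_hat)
    u2 = evaluate_field(sol, (1.0 - h) * n_hat)
    assert abs((u2 - u1) / h) < 1e-2


def test_inner_outer_mismatch_shrinks_with_eps(disk_provider):
    """The composite matching gap at the switch radius decreases with eps."""
    gaps = []
    for eps in (0.08, 0.04, 0.02):
        cfg = concentric_config(eps=eps)
        sol = solve_model1_2d(cfg, disk_provider)
        rho_sw = 5.0 * eps
        from singtrap.steady import _inner_value, _outer_value

        inner = _inner_value(sol, 0, 5.0)
        outer = _outer_value(sol, np.array([[rho_sw, 0.0]]))[0]
        gaps.append(abs(inner - outer))
    assert gaps[0] > gaps[1] > gaps[2]


def test_interior_queries(disk_provider):
    """Model I interiors are undefined (NaN); outside-domain points raise."""
    cfg = concentric_config(eps=0.05)
    sol = solve_model1_2d(cfg, disk_provider)
    assert math.isnan(evaluate_field(sol, np.array([0.01, 0.0])))
    with pytest.raises(ValueError):
        evaluate_field(sol, np.array([1.5, 0.0]))


def test_fd_multi_compartment_agreement():
    """3-compartment rectangle at eps = 0.02: asymptotics within 3% of the
    embedded-boundary FD solve at probes far from the compartments."""
    dom = DomainSpec("rect2d", (1.0, 1.0), D=1.0, gamma0=1.0)
    comps = [Compartment(np.array([0.3, 0.3]), 1.0, math.inf, "I", c0=1.0),
             Compartment(np.array([0.7, 0.35]), 0.9, math.inf, "I", c0=2.0),
             Compartment(np.array([0.5, 0.72]), 0.8, math.inf, "I", c0=0.5)]
    cfg = CompartmentConfiguration(dom, 0.02, comps)
    gf = fd_solve_2d(cfg, n=421)
    prov = make_greens_provider(dom)
    sol = solve_model1_2d(cfg, prov)
    probes = np.array([[0.1, 0.1], [0.9, 0.9], [0.5, 0.5], [0.1, 0.8],
                       [0.85, 0.15]])
    ua = evaluate_field(sol, probes)
    uf = gf.probe(probes)
    assert np.max(np.abs(ua - uf) / np.abs(uf)) < 0.03


def test_separation_validation(disk_provider):
    with pytest.raises(ConfigurationError):
        CompartmentConfiguration(disk_provider.domain, 0.05, [
            Compartment(np.array([0.1, 0.0]), 1.0, 1.0, "I"),
            Compartment(np.array([0.3, 0.0]), 1.0, 1.0, "I")])
    with pytest.raises(ConfigurationError):
        CompartmentConfiguration(disk_provider.domain, 0.05, [
            Compartment(np.array([0.9, 0.0]), 1.0, 1.0, "I")])
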