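# Methods

## Scope and assumptions

All solvers treat a bounded domain Ω (unit disk or rectangle in 2D, unit
sphere or box in 3D; lengths normalised so the smallest inscribed
dimension is 1) containing N circular/spherical compartments of radius
εℓⱼ, with max ℓⱼ = 1 defining ε. The asymptotics assume the compartments
are **small and well separated**: pairwise centre distances and
centre-to-boundary distances must be O(1). Configuration validation
enforces a separation of at least `separation_mult * eps` (default
multiplier 10) and refuses configurations that violate it; accuracy
degrades gracefully, not catastrophically, as separations shrink toward
that bound.

Parameter conventions follow the rescaled (O(1)) form of the boundary
conditions: the library takes κⱼ, Ī ⱼ, γ̄ⱼ *after* the rescalings
κ → κ/ε, Ī → Ī/ε², γ̄ → γ̄/ε² that make the total surface flux and the
interior turnover O(1). A bulk source ℐ₀ > 0 (allowed only with γ₀ > 0)
is removed internally by the shift u → u − ℐ₀/γ₀, cⱼ → cⱼ − ℐ₀/γ₀ and
restored on evaluation.

## Green's functions (`singtrap.domains`)

The outer problem is expressed through the Neumann Green's function of
the modified Helmholtz operator at rate γ₀ + s; its regular part R, the
pseudo-Green's function G₀ (zero-rate branch, ∫G₀ = 0), and the rate
derivative H = ∂ₛG|₍ₛ₌₀₎ are all evaluated analytically:

- **Disk / sphere**: the free-space screened kernel (K₀(βd)/2πD or
  e^{−βd}/4πDd, β = √((γ₀+s)/D)) plus a reflection series in modified
  Bessel (2D) or modified spherical Bessel × Legendre (3D) functions whose
  coefficients −K′ₙ(β)/I′ₙ(β) enforce the no-flux outer boundary. Terms
  decay geometrically like (r r′)ⁿ. Beyond the order where the Bessel
  pair over/underflows in double precision the terms approach a
  rate-independent limit, and the remaining tail is added in closed form
  from the Legendre/cosine generating functions; the residual of this
  tail is O(β² tⁿ/n²) at the switch order n and is far below the target
  tolerance for interior points. The pseudo-Green's functions use the
  standard closed forms (log-image form for the disk; image + generating
  function form for the sphere), with the additive constant fixed
  analytically by ∫G₀ = 0 and verified by quadrature in the tests.
- **Rectangle / box**: an Ewald split of the reflected image sum. The
  short-range part is a Gaussian-screened kernel summed over the images
  within a cutoff (closed erfc form in 3D; a smooth two-sided-decaying
  1D integral in 2D, evaluated by composite Gauss–Legendre panels to near
  machine precision); the long-range part is a cosine eigen-sum whose
  terms carry e^{−ηλ} and converge in ~10 modes per axis. The split
  parameter is η = (L_min/6)²; the resulting normalisations
  ∫G = 1/(γ₀+s) and ∫G₀ = 0 hold *identically* in the split (the k-space
  zero mode and the short-range integral recombine exactly), so the
  quadrature checks in the tests probe implementation errors only.
- **H**: term-wise analytic differentiation in s of every series/Ewald
  ingredient (Bessel derivatives via the defining ODEs; erfc-form
  derivatives in closed form). A Richardson central-difference fallback
  `H_fd` is kept as a cross-check and agrees to ~1e-10.

Regular parts are refused within a configurable `boundary_margin`
(default 1e-3) of ∂Ω, since image contributions degrade there and the
theory itself assumes compartments O(1) from the boundary.

The quadrature helper `singular_quadrature` integrates functions with a
single Green's-type singularity: polar/spherical coordinates about the
singular point for disk/sphere (the angular extent is smooth, so uniform
angles converge spectrally), and a Duffy decomposition into triangles
(2D) / face pyramids (3D) for rectangle/box, with radially graded
composite Gauss–Legendre nodes. Normalisations verify to ~1e-9 with the
default node counts.

## Steady states (`singtrap.steady`)

2D solves are non-perturbative in ν = −1/log ε ("summing the
logarithms"): (I + νM)a = −c₀ with Mⱼᵢ = Ψⱼδᵢⱼ + 2πD𝒢ⱼᵢ and
𝒢ⱼⱼ = R(xⱼ,xⱼ) − log ℓⱼ/2πD. At γ₀ = 0 the far-field constant u∞ joins
the unknowns and the solvability constraint ΣAⱼ = 0 closes the system;
this is solved as a single bordered (N+1)×(N+1) linear system rather
than the two-step substitution, for conditioning, and the two routes are
asserted equal to 1e-10 in the tests. κ = ∞ is represented exactly
(Ψⱼ = 0, Λⱼ = ℓⱼ), not by a large number.

3D solves default to the two-term expansion (trap strengths Λⱼ plus the
εχⱼ interaction correction); `order="one-term"` is available for
expansion-order studies. On the zero-degradation branch χⱼ depends on
u∞, so u∞ is obtained from the solvability condition as a small exact
linear solve, which agrees with the Λ-weighted-mean formula to the
stated O(ε).

Model II compartments reduce to effective (c₀, Ψ) via
Ψ = D/(κℓ) + D/(D̄·F(β̄ℓ)), F(x) = xI₁(x)/I₀(x); F is evaluated with a
series switch at small arguments (F → x²/2). Note the model I limit
requires both D̄ → ∞ *and* γ̄ℓ² ≫ D: the printed small-argument limit of
F leaves a residual 2D/(γ̄ℓ²) term in Ψ at fixed γ̄, so the bare D̄ → ∞
statement is not asserted anywhere. Model III fixed points solve the
coupled algebraic system (kinetics + matching at cⱼ = w*ⱼ₀) by
multistart root finding: the well-mixed fixed points of the kinetics
plus a seeded Latin-hypercube set, with duplicates merged at relative
distance 1e-6. The exchanged species is index a = 0 throughout. In 3D
the leading-order balance is f̂ₐ − 4πDΛⱼ w*ⱼ₀ δₐ₀ = 0 (the sign that
follows from substituting the decaying inner solution into the flux
balance; an outflux from a compartment holding positive concentration).

Composite field evaluation switches from the outer to the inner formula
at ρ_switch = 5ℓⱼ in stretched units (configurable); the two expressions
differ by O(ε) there and the mismatch is asserted to shrink with ε.
Interiors are evaluated only for model II (the Bessel/sinh profiles);
model I/III interiors are not part of the model and return NaN.

## Ostwald ripening (`singtrap.ripening`)

The quasi-static radius ODEs use the printed leading-order rates: in 2D
dℓⱼ/dτ = (Dνφ_a/ℓⱼφ_b)(1/ℓ_harm − 1/ℓⱼ) on the slow time τ = t/ε²; the
capillary length enters the 2D rate only as a constant factor absorbed
into the time unit (trajectory shapes, conservation and coarsening order
are unaffected), while the 3D rate carries Dφ_aℓ_c/φ_b explicitly. Both
rates conserve Σℓ² / Σℓ³ identically; the adaptive integrator (RK45,
rtol 1e-10) preserves them to ~1e-10. The ODEs are singular at ℓ = 0, so
droplets are removed by a terminal event at a threshold (default 1e-3 of
the initial mean radius) and the residual mass (≤ threshold³) is logged
as `mass_leak`, not redistributed — the leading-order theory does not
specify redistribution.

One caveat on the "critical radius": the alive-droplet mean (harmonic in
2D, arithmetic in 3D) is *not* monotone between extinction events — a
Chebyshev sum-inequality argument shows it drifts down as polydispersity
grows — and increases only across extinctions, when the smallest droplet
dies. The trajectory object exposes the series; tests assert the
coarse-grained (across-event) increase and the monotone droplet count.

## Accumulation times (`singtrap.accumulation`)

T(x) = ∫₀^∞ Z(x,t)dt with Z the fractional deviation from steady state,
computed as ±(1/u(x)) d[s ũ(x,s)]/ds at s = 0. The Laplace-transformed
problem is the steady problem at rate γ₀ + s with boundary data cⱼ/s and
bulk source u₀(x), so the steady machinery applies verbatim; the s → 0
limit needs only G, H and the convolution Γ₀(x,s) = ∫G(x,x′;s)u₀(x′)dx′.
The sign is an explicit `direction` option: `fill` (zero initial data,
compartments fill the bulk) or `drain` (bulk initial data, compartments
absorb); no silent sign flips. γ₀ = 0 is refused: the Laplace-space
Green's function has a simple pole at s = 0 and the present expansion
does not apply.

Γ₀ is computed with the singularity-adapted quadrature centred at x;
when u₀ declares an annular/shell support and x lies outside it, the
integration runs over the support instead (G is smooth there), which
resolves narrow profiles exactly where a probe-centred grid would
undersample them. The 2D formula keeps the full O(1) correction (A′
through the Θ matrix and the H terms); the 3D formula is leading order
in ε, and the FD comparisons in the tests use tolerances consistent with
that order (3% for the full 2D form at ε = 0.02; O(ε) for 3D).

The 1D machinery on [0, L] (flux injection at the origin) is evaluated
analytically from the log-derivative of the transformed solution and
recovers the closed form (1/2γ₀)(1 + √(γ₀/D)x) to 1e-4 at L = 40ξ; an
eigenfunction-sum route with closed-form coefficients provides the
independent oracle.

## Quorum-sensing reduction (`singtrap.qs`)

At bulk diffusivity D = D₀/ν the model III PDE–ODE system reduces to
ODEs for the mean bulk concentration ū and the cell states wⱼ, coupled
through exchange amplitudes Aⱼ(t) solved from
[1 + D₀/(κⱼℓⱼ)]Aⱼ + 2πD₀ν Σₖ 𝒢₀ⱼₖAₖ = ū − wⱼ₀ at every right-hand-side
evaluation (no caching — correctness over speed at these sizes). The
pseudo-Green's matrix is built at diffusivity D₀, which is what makes
𝒢₀ = O(1/D₀) and hence W = (I + νQ)⁻¹ → I in the well-mixed limit, with
Q = 2πκℓD₀/(κℓ+D₀)·𝒢₀ in the identical-cell case (the 2π belongs in Q
for the identical-cell route to reproduce the general solve, which is
asserted to 1e-13).

The classical well-mixed model uses κ̂ = 2πNκℓ/|𝒰|. Its volume fraction
is exposed in two conventions: α = |𝒰|/(|Ω|−|𝒰|) (the standard
definition) and α_reduction = |𝒰|/|Ω|, consistent with the |Ω∖𝒰| ≈ |Ω|
approximation used in deriving the reduction. The two differ at O(ε²);
convergence tests use α_reduction because only then is the D₀ → ∞ limit
of the reduced system *exactly* the well-mixed model, giving the clean
1/D₀ trajectory gap (measured slope −1.000).

Cell kinetics plug in through an object with `f(w)`, `n_species` and
optional `fixed_points()`. The shipped Sel'kov form is
f₀ = αw₁ + w₁w₀² − w₀, f₁ = ε_s(μ − αw₁ − w₁w₀²), defaults α = 0.5,
ε_s = 0.15, μ = 2.3: the isolated cell has its fixed point at
(μ, μ/(α+μ²)) and oscillates for μ roughly in (0.85, 2.22), so the
default sits just above the upper Hopf point (quiescent in isolation —
the regime where diffusive coupling can create collective rhythms).
Study configurations use membrane permeabilities κ ~ 2·10⁻³ so that the
per-cell exchange rate 2πκℓD₀/((κℓ+D₀)|𝒰ⱼ|) is O(1), the regime where
kinetics and diffusive coupling genuinely compete; with κ = O(1) the
exchange rate is O(1/ε²) and the cells are slaved to the bulk.

`hopf_scan` tracks the leading eigenvalue real part of a
central-difference Jacobian at the reduced fixed point over a parameter
grid and bisects sign changes; crossings are validated against the onset
of sustained oscillation in direct simulation (amplitude criterion).

The Kuramoto variant integrates
dθⱼ/dt = ωⱼ + κ̂a Σₖ Wⱼₖ sin(ψ − θₖ) and
dz/dt = (ακ̂/N) Σⱼₖ Wⱼₖ(e^{iθₖ} − z) − (γ₀ + iω₀)z,
with seeded frequencies/phases; W = I reproduces the unweighted
medium-coupled model bit-for-bit (identity matmul is exact), verified
against an independently coded direct integrator.

## Switching boundaries (`singtrap.switching`)

Volume transmission is solved by two nested constant-boundary solves:
the summed conditional mean ū = ū₀ + ū₁ solves the zero-degradation
Dirichlet problem with unknown interface constants φⱼ (pseudo-Green's
branch); ū₁ − (β/(α+β))ū solves a *homogeneous* modified-Helmholtz
problem at rate α + β with surface values (α/(α+β))φⱼ — this substitution
eliminates the spatially varying source βū exactly, so no volume
quadrature is needed; finally φ is fixed by the inhomogeneous Neumann
condition through the inner-expansion log coefficients, an N×N linear
system whose condition number is checked (failure reports "no bounded
steady state", which occurs in degenerate rate regimes).

Two conventions matter and both were fixed against ground truth. First,
the firing flux is a *release*: D∇u·nⱼ = −𝒥ⱼ with nⱼ pointing out of the
varicosity, so 𝒥ⱼ > 0 pushes transmitter into the bulk and the fields
are positive. Second, conditioning multiplies the pathwise flux by the
stationary firing occupancy ρ₁ = β/(α+β): the conditional mean
ū₁ = E[u·1_{N=1}] satisfies D∇ū₁·nⱼ = −ρ₁𝒥ⱼ. Both a direct solve of the
coupled conditional-mean BVP and Monte-Carlo simulation of the switching
PDE confirm this closure (agreement ~0.5 standard errors; omitting ρ₁
produces a threefold discrepancy).

The Monte-Carlo oracle integrates the radial switching PDE
(Crank–Nicolson with pre-factorised operators per environment state,
exponential switching times) for a single centred varicosity; conditional
means are time averages of u·1_{N=n} after a 40% burn-in, with standard
errors from rep-to-rep scatter. The radial geometry keeps the oracle's
discretisation error far below the Monte-Carlo error, so the 2-standard-
error comparison tests the asymptotics, not the grid. Synchronous
firing only (one global two-state chain); independent varicosity
switching (a 2^N chain) is out of scope.

## Oracles and the synthetic generator (`singtrap.validation`)

- Exact radial solutions: 2D annulus u = A[I₀(βr) + (I₁(β)/K₁(β))K₀(βr)]
  and 3D shell u = A[cosh(β(1−r)) − sinh(β(1−r))/β]/r, with A fixed by
  the Robin condition; both satisfy the outer no-flux condition
  identically by construction and report the Robin residual (~1e-16).
- Radial FD (steady and Crank–Nicolson time-dependent) with Robin/
  Dirichlet inner and reflecting outer conditions; observed order 2.0.
- Embedded-boundary Cartesian FD on rectangles with Dirichlet circles via
  Shortley–Weller shortened arms (arm fractions clamped at 1e-3 to avoid
  ill-conditioning); boundary-fitted grids were rejected as needless
  complexity since the concentric annulus certifies the Robin/Dirichlet
  treatment and Richardson triples certify the order (~2). The oracle
  requires ≥ 8 grid cells across each compartment and refuses less.
- Direct FD solves of the Green's PDE with a grid-normalised mollified
  source (Cartesian for rectangles, cell-centred finite-volume polar grid
  for the disk, where the zero-area inner face handles r = 0 naturally);
  agreement with the analytic evaluators is ~1e-4 away from the source.
- Trap capacitances: sphere a, hemisphere 2a(1−1/√3), prolate
  √(a²−b²)/arccosh(a/b), oblate √(a²−b²)/arccos(b/a) — the oblate branch
  is the standard electrostatics result (an arccosh of an argument < 1 is
  not real); the ℓⱼ → Cⱼ substitution is available to the 3D solvers.
- The fixture generator rejection-samples well-separated seeded
  configurations (deterministic per seed, clean failure when the packing
  budget is exhausted) with radius heterogeneity re-normalised so
  max ℓⱼ = 1.

## What the synthetic configurations do and do not emulate

Generated fixtures reproduce the geometric assumptions of the theory —
small, disjoint, well-separated circular/spherical compartments away
from the boundary — with uniformly drawn centres, radii, reactivities and
boundary values. They do not emulate compartment shape irregularity,
clustering/correlated placement, compartments near ∂Ω, polydispersity
beyond the configured range, or measurement noise: passing tests show
the asymptotic machinery is correct in its stated regime, not that real
micrographs satisfy that regime.

## Problem sizes

Default test/validation sizes: quadratures with ~10⁴ (2D) / ~10⁵ (3D)
nodes; FD grids up to 421² (steady oracle) and 361² (Green's oracle);
radial time-domain integrations with ~1600 nodes and dt = 2.5e-4; 200
Monte-Carlo reps of horizon 20 for the switching comparison; ripening
with N = 5 droplets; reduced QS systems with N = 2–4 cells. The full
suite and the acceptance script each run in about 1–2 minutes on one
CPU.

## Known limitations

- Green's functions are provided for the four supported geometries only;
  no general-purpose BEM/FEM fallback, no unbounded domains.
- Near-boundary evaluation (within ~1e-3 of ∂Ω) of regular parts is
  refused; field values very close to ∂Ω lose a few digits.
- The 3D accumulation-time formula is leading order in ε (relative error
  O(ε) against the FD oracle); the 2D formula carries the full O(1)
  correction.
- γ₀ = 0 accumulation times are not supported (pole at s = 0).
- Model I/III compartment interiors are not modelled.
- Ripening assumes fixed centres (no translation, coalescence or
  nucleation) and enforces well-separation only at t = 0; radii growing
  beyond twice the initial maximum void the dilute assumption.
- The active-suppression (two-species switching solute) droplet model and
  second-moment equations for switching environments are out of scope.
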