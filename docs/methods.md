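# Methods

## Physical model

`stenoflow` computes steady laminar flow of blood through a rigid,
axisymmetric tube with a smooth (cosine) constriction. The governing
equations are the incompressible Navier–Stokes equations in cylindrical
coordinates for the meridional velocity `(u, v)` and pressure `p`,

    div(U) = 0,
    rho (U . grad) U = -grad p + div( mu (grad U + grad U^T) ),

with body forces neglected and no swirl. Blood is treated either as a
Newtonian fluid with the plasma viscosity `mu = 3.45 mPa.s`, or as a
shear-thinning generalized-Newtonian fluid with the Carreau law

    mu(gdot) = mu_inf + (mu_0 - mu_inf) (1 + (lambda gdot)^2)^((n-1)/2),

using a standard whole-blood parameter set (`mu_inf = 3.45 mPa.s`,
`mu_0 = 56 mPa.s`, `lambda = 3.313 s`, `n = 0.3568`) and density
`rho = 1050 kg/m^3`. The scalar shear rate is the second invariant
`gdot = sqrt(2 D:D)` of the axisymmetric rate-of-strain tensor,
including the hoop component `v/r` (replaced by its limit `dv/dr` on the
axis). The Carreau law is regular at `gdot = 0` (it tends to `mu_0`), so
no shear-rate floor is needed.

The Newtonian viscosity is deliberately set to the plasma value: with
the reference conditions (diameter `D = 10 mm`, mean velocity
`Um = 0.0986 m/s`) this is the only constant viscosity consistent with
`Re = rho Um D / mu = 300`, the Reynolds number at which all reference
cases are run.

## Geometry and grid

The wall is `r_w(x) = R - (R - Rt)/2 (1 + cos(2 pi x / Ls))` for
`|x| <= Ls/2` and `R` outside, i.e. a C1 cosine bump of length `Ls`
centred at `x = 0` with throat radius `Rt`. Severity is the area
blockage `eta = 1 - (Rt/R)^2`. Reference cases use `R = 5 mm`,
`Ls = 4R` and `eta in {0, 0.25, 0.5, 0.625, 0.75}`.

The mesh is a boundary-fitted structured block: shared axial face
positions, and radial faces at fixed fractions of the local wall radius.
Radial fractions follow a tanh stretching toward the wall (default
strength 2.2, making the wall-adjacent cell about 0.11 of the uniform
spacing — the wall shear stress is extracted from that cell). Axial
faces come from integrating a smooth node-density function that is 4x
denser over the stenosis bump and 2.2x denser in the wake out to `14R`,
where the recirculation bubble reattaches. The domain runs from `-6R`
to `30R`: the severest (Newtonian, `eta = 0.75`) bubble reattaches near
`14R`, and the zero-gradient outflow plane must sit well downstream of
reattachment; all profiles are reported over the window `[-3R, 9R]`.

All face areas and cell volumes carry the axisymmetric `r` weight (kept
per unit radian). A useful consequence: the faces on the axis have zero
revolved area, so the symmetry condition is satisfied identically with
no special casing.

## Discretization and SIMPLE iteration

Finite volumes with colocated variables. Convection uses an implicit
first-order upwind flux plus an explicit deferred correction to linear
(second-order) upwind; diffusion uses the over-relaxed orthogonal
decomposition with explicit cross-diffusion on the (mildly) non-orthogonal
faces along the bump; the transposed part of the stress, which matters
when `mu` varies, is explicit. The radial momentum equation carries the
axisymmetric sources (`+ int p dA` from the radial pressure gradient
identity, and the implicit hoop drag `-2 mu v / r`). Face mass fluxes use
Rhie–Chow momentum interpolation, which suppresses pressure
checkerboarding on the colocated arrangement.

Pressure–velocity coupling is SIMPLE: momentum under-relaxation 0.7,
pressure correction under-relaxation 0.3, viscosity under-relaxation 0.7.
A systematic sweep showed more aggressive settings (e.g. 0.7/0.5 or
0.8/0.5) diverge on the severe-stenosis case, so the conservative
defaults stand. Momentum and pressure-correction systems are pentadiagonal
and solved directly (sparse LU) each outer iteration; all stages are
deterministic, so identical configurations reproduce bit-identical
residual histories and fields. Convergence requires the normalized
momentum residuals (L1, scaled by `rho Q Um` per radian) and the
continuity residual (pre-correction mass imbalance scaled by `rho Q`)
to drop below 1e-6.

Boundary conditions: prescribed inflow (by default the fully developed
profile of the active rheology, imposed through exact face-integrated
fluxes and normalized so the discrete flow rate matches `Q` exactly;
a uniform profile is available by configuration), no-slip wall with the
viscous flux based on the wall-normal gradient, symmetry axis, and a
zero-gradient outlet whose fluxes are rescaled each iteration to conserve
mass. The pressure level is pinned by a homogeneous Dirichlet value for
the pressure correction on the outlet plane; reported wall pressures are
re-gauged to zero at `x = 9R`.

Initialization uses the developed inflow profile scaled per column by
`(R / r_w)^2` (mass-conserving seed). Finer grids can warm-start from an
interpolated coarser solution (grid sequencing); tolerances are
unchanged, so the converged state is unaffected.

### Verification behaviour worth knowing

* On uniform straight-tube grids the discrete operator reproduces the
  Poiseuille parabola *exactly* in the interior; truncation error is
  confined to the wall row (one-sided linear wall gradient) and the
  inlet/outlet columns.
* On the stretched grids used in production the local truncation error
  is formally first order while the solution error converges at second
  order (the usual finite-volume supraconvergence); the straight-tube L2
  velocity error drops by ~4x per refinement in the test suite.
* The wall-shear extraction `tau_w = mu_w u_t / d_n` is first-order in
  the wall-cell height; with the tanh-stretched wall spacing its bias is
  ~0.1–0.5% at default resolution.

## Semi-analytic oracles

Fully developed generalized-Newtonian pipe flow is computed independently
of the solver: in such a flow `tau(r) = |dp/dx| r / 2` exactly, and since
`mu(g) g` is strictly increasing for the Carreau parameters the local
shear rate follows by bracketed bisection; `u(r) = int_r^R gdot ds`, and
an outer Brent iteration on `|dp/dx|` closes the flow rate to 1e-8
relative. The Newtonian member reduces to the Poiseuille closed form
identically. These oracles validate the solver on straight tubes
(including the external validation-tube conditions `R = 3.1 mm`,
`Q = 5.98e-5 m^3/s`, `rho = 1000 kg/m^3`) and provide the developed
inflow profiles.

## Metrics

* **WSS**: `tau_w = mu_w du_t/dn` per wall face, with `mu_w` evaluated at
  the wall shear rate for Carreau; reported as magnitude vs `x`, peak
  taken over sampled faces without smoothing (peaks sit just upstream of
  the throat where the accelerated jet thins the boundary layer).
* **Wall pressure / pressure drop**: cell pressures extrapolated to the
  wall with the converged cell gradient, windowed to `[-3R, 9R]` with
  linearly interpolated endpoints, gauged to zero at `9R`;
  `Delta p = p(-3R) - p(9R)`.
* **Separation-vortex length**: distance between the separation and
  reattachment points, located by sign changes of the signed wall shear
  downstream of the throat with sub-cell linear interpolation, in units
  of `R`; zero when no sign change exists. If a bubble is attached at
  the throat itself the throat is taken as the separation point; multiple
  zones return the longest and flag the count.
* **Diameter sensitivity**: the linearized Poiseuille relation
  `d(Delta p)/Delta p = -4 dD/D` at fixed flow rate, cross-validated by
  two straight-tube solves at `R` and `0.99R`.

## Default resolution and grid convergence

The default grid is 160 x 32 cells with the clustering described above.
This was chosen by a refinement study (160x32 -> 240x48 -> 320x64, both
rheologies, severest case): the pressure drop, WSS peak and vortex length
all change by well under 1% across these levels, i.e. the reported
metrics are grid-converged at the default. The automated acceptance
checks re-verify this: straight-tube pressure drop and WSS change by
< 2%, and all three severe-case metrics by < 5%, when the default
resolution is doubled.

## What the reference suite emulates — and what it does not

The ten-case suite generates its own inputs (no external data): an
idealized, rigid, axisymmetric cosine stenosis under steady inflow at
Re = 300. Relative to real arterial stenoses this omits pulsatility,
wall compliance and motion, eccentric/irregular plaque shapes, vessel
curvature and side branches, and any transition to turbulence (the jet
at `eta = 0.75` is kept laminar by construction). Passing tests
therefore demonstrate correct solutions of this canonical model — the
standard testbed for rheology effects on separation, pressure drop and
WSS — not predictive accuracy for any patient geometry.

## Known limitations and observed discrepancies

* With both models the severe-stenosis (`eta = 0.75`) *absolute*
  pressure drop over `[-3R, 9R]` is nearly the same (~76–78 Pa): the
  drop is dominated by the accelerated jet, where shear rates push the
  Carreau viscosity onto its plasma plateau. Because the Carreau
  straight-tube baseline (9.8 Pa) is ~1.5x the Newtonian one (6.5 Pa),
  the amplification *ratio* is ~7.8 for Carreau but ~12 for the
  Newtonian model. The commonly quoted "about 8-fold for both models"
  is reproduced here only by the Carreau rheology; the acceptance suite
  checks both and documents the Newtonian disagreement rather than
  masking it. The ratio is grid-converged, insensitive to resolution.
* The "normal-case WSS of about 0.5 Pa" sometimes quoted as the
  baseline for the ~15x WSS amplification is not consistent with either
  developed-flow value at these conditions (0.27 Pa Newtonian / 0.41 Pa
  Carreau, both exact oracle results). The amplification check therefore
  uses the Carreau baseline — the closest to that figure — and a wide
  (+-30%) band.
* The Newtonian `eta = 0.75` recirculation bubble reattaches near `14R`;
  its length is reported faithfully even though it extends beyond the
  `[-3R, 9R]` plotting window.
* Steady solutions only. At `eta = 0.75`, Re = 300 the real flow may be
  unsteady in practice; the computed state is the converged steady
  solution of the model equations.
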