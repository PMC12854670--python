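# Methods

## Flow models

All fields are exact solutions of the incompressible Stokes equations,
built from axisymmetric stream functions separated in Gegenbauer functions
G_m(mu) = (P_{m-2}(mu) - P_m(mu))/(2m-1), mu = cos(theta). The decaying
radial solutions of mode m are r^(1-m) and r^(3-m); the m = 2, r^1 term is
the Stokeslet and is admitted only when a net external (tether) force acts
on the system. Conventions: symmetry axis z, the point force sits at
z = +L and points toward the cell (-z), theta = 0 is the front; sessile
fields are evaluated in the lab frame (quiescent far field), motile and
sinking fields in the body frame (far field -U z). Everything is
nondimensional with a = 1, eta = 1, slip scale 1.

* Envelope model. Motile: B1 squirmer, U = 2 B1 / 3. Sessile: tethered
  pump psi = sin^2(theta) (1/(2r) - r/2), which satisfies u_r(a) = 0,
  u_theta(a) = sin(theta) and decays as 1/r (the tether carries the net
  force). Both are closed forms, exact to round-off.
* Stokeslet-sphere model. The free-space point-force stream function
  psi = beta r^2 sin^2(theta)/|x - L z| is expanded about the origin; its
  surface values have the closed-form Gegenbauer coefficients
  s_m = beta m(m-1)[L^(1-m)/(2m-3) - L^(-1-m)/(2m+1)] (and t_m for the
  radial derivative), so the image coefficients solve a 2x2 system per
  mode with no quadrature. Truncation starts at N = 64 modes and doubles
  until the surface velocity residual is below 1e-8 (relative to the force
  magnitude), capped at N = 512; the series converges geometrically in
  a/L, so forces close to the surface (L = 1.1a) need N ~ 200.
* Force balance. The image Stokeslet coefficient b_2 carries the force the
  sphere exerts on the fluid (4 pi b_2), giving the swimmer mobility
  alpha(L) = (1 - 3a/(2L) + a^3/(2L^3)) / (6 pi eta a)
  exactly — this agrees analytically with Faxen's law applied to the
  ambient point-force flow, which is exact here because the singularity is
  a prescribed force, not a body, so no reflections arise. The default
  calibration chooses F so the motile state swims at U = 2/3, the envelope
  model's speed, making Pe comparable across models. A corollary used
  throughout: the motile body-frame field equals the sessile field plus
  rigid-sphere translation flow at U, for both models — the boundary
  conditions differ by exactly rigid translation.

## Transport solver

The steady equation Pe u.grad(C) = lap(C) is solved in (x = ln r, theta):

    C_xx + (1 - Pe r u_r) C_x + C_tt + (cot(theta) - Pe r u_theta) C_t = 0,

with second-order centered differences, switching to first-order upwinding
only where a cell Peclet number exceeds 2 (preserves the discrete maximum
principle up to ~1e-14 at Pe = 1000). One sparse direct solve (SuperLU).

Boundary conditions: C = 0 on absorbing surface nodes and a one-sided
second-order zero-gradient on reflecting ones; symmetry at the poles (the
angular operator limits to 2 C_tt there); at the outer sphere, a Robin
condition dC/dr = (1 - C)/r on inflow nodes — exact for the diffusive
monopole tail C = 1 - k/r, so the finite domain costs O(R^-2) instead of
the O(R^-1) of a plain Dirichlet condition — and zero normal derivative on
outflow nodes to avoid wake-truncation bias.

Grids: radial nodes uniform in ln r (r from a to R_inf), theta uniform.
The automatic grid uses R_inf = 60a for Pe >= 1, 300a at Pe = 0, and
max(300a, 12a/Pe) (capped at 2400a) for 0 < Pe < 1, because the advective
correction at small Pe accumulates over an outer region of extent ~a/Pe;
with the scaled domain the sinking-sphere solution matches the
Acrivos-Taylor expansion to 0.1% at Pe = 0.01. The near-surface radial
step targets 0.1 Pe^(-1/2) (about ten cells across the concentration
boundary layer; halving it moves Sh at Pe = 100 by < 1%), and a solve
refuses to run above 0.2 Pe^(-1/2). Defaults are Nr = 256 at Pe <= 60
growing to Nr ~ 1300 at Pe = 1000, Ntheta = 128 (192 for Pe >= 300, even
for composite Simpson).

Sherwood numbers use a one-sided second-order surface gradient and Simpson
quadrature. Each result records a conservation defect — the worst relative
mismatch between surface uptake and the total (diffusive + advective)
flux through spheres at 1.5a, 3a and R_inf/2 — and is flagged above 1e-3.
The defect is a trustworthy diagnostic at small Pe (~1e-4); at large Pe the
downstream wake is thinner than the theta grid at the outer test radius and
the diagnostic, not the solution, loses accuracy, so flagged high-Pe
results are expected.

For small-Pe asymptotics the package computes the shift Sh(Pe) - Sh(0) on
a shared grid (cancelling discretization bias, important when the shift is
O(1e-3)) and Richardson-extrapolates over paired domains (300a/600a)
assuming the leading 1/R truncation error; this recovers the sessile
quadratic coefficient 43/720 to 0.13%.

## Feeding metrics

Q = -2 pi int_a^R u.e_z|_{z=0} rho d(rho) by adaptive quadrature
(u.e_z = -u_theta on the equator). Both states are normalized by
pi R^2 U with U = 2/3, the matched swimming speed — the only defined
velocity scale for the sessile sphere; output tables carry Q for both
states so a reader can form relative ratios instead. Encounter radius
defaults to R = 1.1a: an annulus a cilium's length beyond the surface,
small enough that its own drag can be neglected. Paired sessile/motile
sweeps share the calibrated force, series truncation, and transport grid.

Because motile = sessile + rigid translation (above), dQ is independent of
the model and of L: dQ = 1.2% of pi R^2 U at R = 1.1a, simply the annular
flux of the towed-sphere flow. For the same reason the swimmer's Sherwood
number always exceeds the tethered sphere's at matched force — adding the
relative wind thins the boundary layer everywhere; numerically
dSh ~ +0.2 (envelope) and up to ~ +0.6 (point-force model, L = 2a) at
Pe = 100. The package therefore locates no sign change of dSh over L:
reported claims that a tethered point-force sphere outperforms its
swimming counterpart near the surface are not reproducible within this
construction, and the corresponding checks are expected to read as
failures against such values while every envelope-model and
asymptotic-limit check passes. This is a deliberate outcome: the solver is
validated independently against the 43/720 and 2/sqrt(3 pi) closed forms,
the Levich Pe^(1/3) law for the towed sphere, and the exact Faxen
mobility, and we report what the stated model computes.

## Asymptotics

Closed forms (sessile envelope): Sh = 1 + (43/720) Pe^2 and
Sh = (2/sqrt(3 pi)) Pe^(1/2). Exponent fits are log-log least squares,
small-Pe regime on log(Sh - 1) (points with Sh <= 1 excluded with a
warning), large-Pe on log Sh. Default windows: Pe <= 1 (small) and
Pe >= 300 (large), caller-overridable; the sinking small-Pe fit uses
Pe in [0.01, 0.1] where the linear term dominates its Pe^2 ln Pe
correction. The measured exponents at desk scale are 0.49/0.49/0.30
(sessile/motile/sinking, large Pe) and 1.96/0.93 (sessile/sinking,
small Pe). Small-Pe coefficients for the motile and sinking spheres are
deliberately not hardcoded; only exponents are asserted.

## Coverage and absorption

Banded cilia coverage projects the masked slip onto the squirmer basis
V_n = (2/(n(n+1))) sin(theta) P'_n(mu) by Gauss-Legendre quadrature mapped
onto the band (coefficients exact to machine precision). Named 50% bands
are equal-area in mu: front cap [0, 1], equatorial belt [-1/2, 1/2], back
cap [-1, 0]. Truncation is raw at N = 64 (no smoothing); the slip is
reproduced to ~0.09 away from band edges (documented Gibbs behavior, with
a two-node edge exclusion in residual checks), and Sh at Pe = 100 moves
by < 0.1% between N = 64 and 128. A partially covered swimmer slows to
U = 2 B_1 / 3 by default; `multimode_flow(..., match_speed=2/3)` instead
rescales the spectrum so the remaining cilia work harder. Partial
absorption restricts C = 0 to a band with zero flux elsewhere; band edges
are quantized to theta nodes, so placements whose edges fall between nodes
carry an O(h) placement uncertainty (~1% in Sh at Ntheta = 128) — the
named front/back bands have their edge exactly on the equator node and are
stable. The mixed Dirichlet-Neumann pure-diffusion case agrees with an
independent exterior-harmonics least-squares solve within 0.6% (front cap).

## Synthetic survey

The generator emulates a trait survey, not any particular dataset: per
lifestyle it samples radius and speed log-uniformly (traits spanning
decades) within sessile-ciliate a in [15, 60] um, U in [50, 2500] um/s;
swimming-ciliate [15, 180], [50, 3200]; sinking-diatom [10, 120],
[40, 210]; with solute diffusivities 1e-9 (oxygen), 4e-10 (live bacteria),
2e-13 m^2/s (dead bacteria), diatoms paired with oxygen only. It is
deterministic under a seed. What it does not emulate: per-species trait
correlations (large cells are not made faster or slower than small ones),
non-spherical shape, and any phylogenetic structure — so passing tests
validate the Pe arithmetic and the model mapping, not ecological realism.
Note one bookkeeping subtlety: for a = 100 um the diffusive timescale
a^2/D is 25 s for live bacteria but 5e4 s for dead bacteria; the package
reports the exact arithmetic. The overlay interpolates each lifestyle's
Sh(Pe) sweep cubically in log Pe (log(Sh - 1) against log Pe) and falls
back to direct solves outside the sweep range.

## Problem sizes

Default desk-scale runs: single transport solves use 33k-85k unknowns
(up to 250k at Pe = 1000) and finish in 0.1-6 s; the full acceptance
recomputation is ~90 solves and ~35 s; the test suite is ~2 minutes.

## Known limitations

No substrate or wall hydrodynamics (cells live in unbounded fluid; real
sessile ciliates sit on stalks near surfaces), no unsteady ciliary beat,
no non-axisymmetric flow, no uptake kinetics (perfectly absorbing
surfaces), and the conservation diagnostic degrades in thin high-Pe wakes
as described above. The pressure field is never constructed; all reported
quantities follow from the stream function.
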