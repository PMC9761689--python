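# Methods

## Problem and representation

Two non-intersecting dielectric particles sit on the z axis, centers a
distance R apart, in an electrolyte described by the linearized
Poisson–Boltzmann (Debye–Hückel) equation: ΔΦ = κ²Φ in the solvent
(relative permittivity ε_sol, inverse Debye length κ), and the Poisson
equation inside each particle (ε_i, fixed point charges). Each surface is a
patchwise-smooth radial graph r_i = a_i(θ_i, φ) in its particle's spherical
frame; the two frames are pure translations of one another (no rotation),
and mirrored partners are built by θ → π − θ.

All lengths are κ-scaled (r̃ = κr). The interior homogeneous field is a
regular solid-harmonic series (radial factor r̃ⁿ — the interior problem is
unscreened), the exterior field a screened-harmonic series with radial
kernel k_n(x) = K_{n+1/2}(x)/√x. The companion regular kernel
i_n(x) = I_{n+1/2}(x)/√x appears in the two-center translation. With these
normalizations the Yukawa kernel satisfies exactly
e^{−d}/d = Σ_p (2p+1) i_p(r_<) k_p(r_>) P_p(cos γ), which fixes every
constant in the translation theory; any overall factor in the kernel
definitions is absorbed by the expansion coefficients and cancels in all
observables. Associated Legendre polynomials use the plain
(1 − μ²)^{m/2} dᵐP_n/dμᵐ definition with no Condon–Shortley sign,
consistently everywhere (basis, translation, coupling coefficients).

## Two-center re-expansion

The exterior harmonic k_l(r̃_j) P_l^m(μ_j) trig(mφ) of one particle,
restricted to a sphere of scaled radius r̃ about the other center, is itself
a surface-harmonic series in the local frame (the azimuthal order m is
conserved by a z-translation):

    k_l(r̃_j) P_l^m(μ_j) = Σ_n b_nml(r̃, R̃) P_n^m(μ_i).

The coefficient takes exact finite-sum product forms in the two radial
regimes, with the Gaunt-type coupling G_lnp^m = ∫ P_l^m P_n^m P_p dμ
(non-zero only for |l−n| ≤ p ≤ l+n with l+n+p even):

* r̃ < R̃ (sphere below the partner center — the classical regime):
  b = (−1)^l √(π/2) (2n+1)(n−m)!/(n+m)! · [Σ_p (2p+1)/2 · G_lnp^m k_p(R̃)] · i_n(r̃)
* r̃ > R̃ (sphere *enclosing* the partner center):
  b =        √(π/2) (2n+1)(n−m)!/(n+m)! · [Σ_p (2p+1)/2 · G_lnp^m i_p(R̃)] · k_n(r̃)

The second form follows from uniqueness of exterior Helmholtz expansions:
outside the ball of radius R̃ about the local center, the translated field
is a decaying solution regular in that region, so its radial dependence is
pure k_n. This is what removes the conventional r < R restriction and lets
surfaces reach past the partner center (wide disks at small separations).
The translation toward −z carries the extra parity factor (−1)^{n+l}.

Properties worth noting:

* Every coefficient carries the overall screening factor e^{−R̃}/R̃ through
  k_p(R̃), so the coupling blocks of the linear system decay accordingly.
* On the crossing sphere r̃ = R̃ the restricted function is singular at one
  point and the coefficients diverge for l ≥ 1; field evaluations within
  2% of R̃ are flagged. Surfaces that cross the ring are still handled —
  quadrature nodes never sit exactly on it — but the harmonic series
  converges at the geometric rate (r̃/R̃)^n (or its inverse), which is why
  flat wide shapes need larger truncation degrees than compact ones.
* Truncation follows the diagonal rule: only coefficients with
  n + l − m ≤ n_max are retained. Because both regime formulas are exact
  finite sums, no inner-series truncation is needed; the retained
  coefficients are exact. A direct projection-quadrature oracle
  (`b_projection`) cross-checks the closed forms in the tests.

## Galerkin system

Both transmission conditions — continuity of Φ and of the normal dielectric
flux ε ∂Φ/∂n with the *unit* surface normal (the 1/|∇(r − a)| factor is
kept inside the integrand) — are projected onto the test set
cos(m′φ) P_{n′}^{m′}, sin(m′φ) P_{n′}^{m′} with weight sin θ, patchwise over
each smooth surface patch. Per particle this yields the block rows

    A L + B M + C G_i + D H_i + E G_j + F H_j = M⃗   (continuity)
    G L + H M + I G_i + J H_i + K G_j + L H_j = N⃗   (flux)

and the combined system has dimension 4(n_max+1)². Only E, F, K, L depend
on R. The source terms use the exact Coulomb field of the point charges on
the surface (no multipole truncation); multipole coefficients are available
separately for the sphere closed forms.

Quadrature is per-patch Gauss–Legendre in μ = cos θ (patch edges coincide
with shape edges, so integrands are smooth), with a uniform periodic φ grid
when a shape is not axisymmetric. Each entry is refined on a ladder of
orders until two successive refinements agree to (abs 1e−10, rel 1e−6) —
the tolerances used for all reported numbers; the base order grows with
n_max so high-degree products stay resolved. The refinement decision is
entry-local, so raising n_max reproduces previously computed entries of the
R-independent blocks bit-identically (at fixed ladder) while adding rows
and columns.

Azimuthal shortcuts: for a fully symmetric scene only m = 0 cosine terms
are kept (dimension 4(n_max+1)); for axisymmetric shapes with off-axis
charges the matrix stays m-diagonal and cos/sin parities share the same
blocks, so only the per-m sub-blocks are built. A `force_full` flag
disables the shortcut for testing.

Conditioning: the raw system mixes radial factors of vastly different
magnitude and exceeds condition 1e16 by n_max ≈ 16. The assembled system is
therefore equilibrated — trial columns divided by their surface magnitude
(radial factor at a reference radius times the harmonic norm), test rows by
the harmonic norm. This is an exact reparametrization (undone when
coefficients are reported) that leaves the Galerkin solution unchanged; the
reported condition number refers to the equilibrated system and still grows
steadily with n_max, reaching ~1e11 at n_max = 21 for the cone benchmark.

## Solvers

`solve_direct` uses LU factorization and reports the 2-norm condition
number and residual. `solve_regularized` solves the Tikhonov normal system
(AᵀA + αE)x = Aᵀb over the geometric grid α_i = α₀qᶦ (defaults α₀ = 0.8⁵,
q = 0.8, M = 100, i.e. 0.8⁶ … 0.8¹⁰⁵) through a single SVD when E = I
(Cholesky per α for a general symmetric positive-definite E), keeping the
solution with the smallest discrepancy ‖Ax − b‖; ties within 1e−12
relative resolve to the largest α. Because the residual decreases
monotonically in α, this selection effectively applies the grid's smallest
α as a fixed spectral filter — which is precisely what stabilizes the
energy at large n_max while leaving well-conditioned systems untouched
(the classical successive-difference quasi-optimality rule was tested and
badly over-regularizes these systems; it is not used). A penalized
least-squares criterion is available behind a flag. `solve_auto` switches
to the regularized path when the condition number exceeds 1e10.

## Energy and observables

W = ½ Σ_k q_k Φ_reg(x_k), where Φ_reg at a charge excludes only that
charge's own divergent Coulomb term: intra-particle Coulomb cross terms and
the full regular reaction series (which contains the partner's screened
influence) are kept. This is the only finite reading of the energy
functional for point charges. W_Born is recomputed from two isolated
single-particle solves at the same n_max (exact and cheap, rather than an
R → ∞ extrapolation); W_int = W − W_Born. Potentials anywhere use the
interior representation inside a particle and the sum of both exterior
series in the solvent; grid exports mask points within a configurable
clearance (default 2 Å) of any surface. Forces are central finite
differences of W(R) with an optional Richardson step; no analytic force
expressions are provided.

## Screening expansion

Writing the system as (D + O)x = b with D the particle-local part and O the
coupling part, the Neumann series x⁽⁰⁾ = D⁻¹b, x⁽ᵏ⁾ = −D⁻¹O x⁽ᵏ⁻¹⁾ orders
coefficients and energy in powers of the small parameter e^{−κR}/(κR):
order 0 reproduces the isolated-particle solves (W⁽⁰⁾ = W_Born), order 1
the DLVO-type pair term, and the order-K residual scales as the (K+1)-th
power. Convergence is guarded by a power-iteration estimate of the spectral
radius of D⁻¹O (refusal at 0.99, warning at 0.9); for physical two-body
scenes the radius stays below ~0.55 even near contact.

## Verification strategy

Every layer is checked against an independent oracle: radial kernels
against mpmath and the Wronskian i_n k_n′ − i_n′ k_n = −1/x²; Legendre
functions against scipy (Condon–Shortley phase stripped); coupling
coefficients against symbolic integration; re-expansion coefficients
against direct projection quadrature in both regimes and directions;
translated fields against direct two-center evaluation (including r > R);
sphere scenes against the per-harmonic 2×2 closed forms, the Born energy
and the DLVO limit; the screening series against the full solve. The
two-cone benchmark energies at n_max = 6, 10, 16, 21 reproduce the
published analytical-theory values to 0.02 kBT.

## Fixtures and the synthetic-data scope

Built-in scenes mirror the benchmark conditions: cones (z0 = 10 Å, central
10 e charges, ε_in = 2, Debye length 8.071 Å, ε_sol = 80, R ∈ {25, 50} Å),
wide cylinders (z0 = 10 Å, h = 50 Å — surfaces crossing r = R at R = 25 Å),
two spheres (closed-form limits), harmonically perturbed spheres
(seed-reproducible non-symmetric surfaces), and an approaching ± pair of
small cylinders carrying *synthetic* arginine/glutamate-like charge sets
(correct net charges ±1 e on amino-acid length scales; real force-field
coordinates are not shipped) swept over R = 8.54…14.94 Å in 0.1 Å steps.
These fixtures exercise realistic geometry, screening and dielectric
contrast, but not atomistic molecular surfaces or conformational detail:
passing tests demonstrate correctness of the DH-level continuum solver, not
fidelity to any specific molecular system.

## Numerical choices and limitations

* n_max is user-set; the translation table reports the magnitude of the
  last retained diagonal (n + l − m = n_max) as a truncation diagnostic.
* Convergence of the energy with n_max is fast for compact shapes
  (stabilized near n_max ≈ 9–10 for the cone pair) but the square Galerkin
  system has isolated irregular truncation degrees (14 and 18 for the cone
  benchmark) where the energy deviates by up to tens of kBT before
  returning to the plateau; these are genuine properties of the discrete
  system (robust to quadrature refinement, equilibration and
  extended-precision solves). The plateau itself carries a residual
  discretization wobble of ~0.01 kBT between n_max = 16 and 21, consistent
  with the slow algebraic convergence induced by the cone's edge
  singularity.
* Shapes must be radial graphs a(θ, φ) — no overhangs, meshes or atomistic
  molecular surfaces; fixed free surface charge is not supported (σ = 0).
* Scenes are limited to two particles; frames are translation-only (no
  rotation operators).
* The nonlinear PB equation and charge renormalization are out of scope;
  results for highly charged systems are DH-level.
* The coupling-coefficient cache can be persisted to a versioned on-disk
  table (`enable_disk_cache`); by default caching is per-process.
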