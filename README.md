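# debyepair

Semi-analytical continuum electrostatics for **two dielectric particles of
arbitrary shape** in an electrolyte, at the Debye–Hückel (linearized
Poisson–Boltzmann) level.

Implicit-solvent electrostatics of interacting biomolecules and colloids is
usually computed on grids (DelPhi, APBS). For particles with an analytic
surface parametrization `r_i = a_i(θ, φ)` the problem can instead be solved
spectrally: grid-free, with no box boundary conditions, no discretization
self-energy, and at a cost almost independent of the separation — which
makes smooth potential-of-mean-force profiles possible. This package is
aimed at people modelling screened electrostatic interactions of
nanoscale objects (proteins in simplified envelopes, colloids, membranes
approximated by disks) who need energies, potentials and separation
profiles that are exact at the DH level.

## Model

Inside particle *i* (dielectric ε_i, point charges q_k) the potential obeys
the Poisson equation; in the solvent (ε_sol, inverse Debye length κ) the
linearized PB equation ΔΦ = κ²Φ. With r̃ = κr, the fields are expanded in
real surface harmonics `P_n^m(cos θ){cos, sin}(mφ)`:

    Φ_in,i  = Φ̂_in,i + Σ_nm [L_nm cos mφ + M_nm sin mφ] r̃_i^n P_n^m(μ_i)
    Φ_out,i = Σ_nm [G_nm cos mφ + H_nm sin mφ] k_n(r̃_i) P_n^m(μ_i)

with Φ̂ the Coulomb field of the embedded charges and
`k_n(x) = K_{n+1/2}(x)/√x` the decaying screened radial kernel. The partner
particle's exterior field is re-expanded across centers (separation R along
z) via coefficients b_nml(r̃, R̃) that take exact finite-sum forms in *both*
radial regimes — including r̃ > R̃, the regime classical r < R translation
theorems cannot reach, which is what allows closely packed flat or sharp
shapes. Continuity of Φ and of the dielectric flux ε ∂Φ/∂n across each
surface is enforced by Galerkin projection onto the surface harmonics,
giving a dense linear system of dimension 4(n_max+1)² (a few dozen to a few
hundred unknowns). The total electrostatic energy is
W = ½ Σ_k q_k Φ_reg(x_k) with the divergent point self-terms excluded, and
splits into an R-independent Born part plus a screened interaction
W_int → 0 as R → ∞. A Neumann-series split of the system orders everything
in powers of e^{-κR}/R (order 0 = Born, order 1 = DLVO, higher orders =
mutual polarization), and a Tikhonov-regularized solve with a geometric
α-grid (α = 0.8⁶ … 0.8¹⁰⁵) stabilizes large truncation degrees.

Units: lengths in Å, charges in e, energies in kBT (default 298.15 K),
potentials in kBT/e. The Coulomb constant is derived from CODATA values at
run time.

## Worked example

Two facing dielectric cones (height 20 Å, opening angle π/2, ε_in = 2) with
central +10 e charges, 50 Å apart in physiological saline (ε_sol = 80,
Debye length 8.071 Å):

```python
import debyepair as dp

solvent = dp.SolventModel(eps_sol=80.0, debye_length=8.071)
cone = dp.make_cone(10.0)
p1 = dp.ParticleModel(cone, 2.0, dp.ChargeSet([[0, 0, 0]], [10.0]))
p2 = dp.ParticleModel(dp.mirror(cone), 2.0, dp.ChargeSet([[0, 0, 0]], [10.0]))
scene = dp.Scene((p1, p2), solvent, R=50.0)

for n_max in (6, 10, 16):
    er = dp.total_energy(dp.solve_scene(scene, n_max))
    print(n_max, round(er.W, 2), round(er.W_Born, 2), round(er.W_int, 4))
```

prints

```
6 -3106.19 -3106.27 0.0758
10 -3109.41 -3109.49 0.0773
16 -3110.18 -3110.26 0.0781
```

W is the total electrostatic energy in kBT: ≈ −3106 kBT at n_max = 6,
converging to ≈ −3110.2 by n_max = 16. Almost all of it is the (negative)
solvation energy of the two isolated charged cones (W_Born); the screened
repulsion of the two +10 e charges across six Debye lengths contributes
only ≈ +0.08 kBT (W_int). See `examples/` for more: sphere/DLVO limits,
the re-expansion oracle, screening orders, a PMF profile, and regularized
high-order solves.

A thin CLI covers the same pipeline from the shell:

```bash
debyepair fixture cones --out-dir fixtures
debyepair solve fixtures/cones_R50.yaml
debyepair profile fixtures/cones_R50.yaml --r-min 30 --r-max 80 --r-step 5
debyepair map fixtures/cones_R50.yaml --plane x=0 --spacing 0.5
```

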