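"""Total electrostatic energy of two facing dielectric cones.

Two cones (height 20 A, opening angle pi/2, a +10 e point charge at each
center, interior dielectric 2) sit 50 A apart in physiological saline
(eps_sol = 80, Debye length 8.071 A).  The energy converges rapidly with
the truncation degree n_max of the surface-harmonic expansion.
"""

import debyepair as dp

solvent = dp.SolventModel(eps_sol=80.0, debye_length=8.071)
cone = dp.make_cone(10.0)
p1 = dp.ParticleModel(cone, eps_in=2.0, charges=dp.ChargeSet([[0, 0, 0]], [10.0]))
p2 = dp.ParticleModel(dp.mirror(cone), eps_in=2.0, charges=dp.ChargeSet([[0, 0, 0]], [10.0]))
scene = dp.Scene((p1, p2), solvent, R=50.0)

print("n_max   W [kBT]      W_Born [kBT]   W_int [kBT]   cond(A)")
for n_max in (4, 6, 10, 16):
    sol = dp.solve_scene(scene, n_max)
    er = dp.total_energy(sol)
    print(f"{n_max:4d}  {er.W:12.2f} {er.W_Born:13.2f} {er.W_int:12.4f}   "
          f"{sol.report.condition_number:.1e}")

print()
print("W is the total electrostatic energy (divergent point self-terms excluded);")
print("W_Born is the R-independent solvation energy of the isolated cones, and")
print("W_int = W - W_Born the screened interaction, small at this separation")
print("(6 Debye lengths).  W stabilizes near n_max ~ 9-10.")
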