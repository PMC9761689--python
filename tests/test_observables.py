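import math

import numpy as np
import pytest

import debyepair as dp
from debyepair.assembly import Scene
from debyepair.observables import interaction_site_energy, potential_on_grid, write_dx

from conftest import dh_sphere_closed_forms, dlvo_energy


class TestPotential:
    def test_single_sphere_matches_dh_closed_form(self, solvent):
        # phi(r) = C q e^{ka} e^{-kr} / (eps_sol (1+ka) r) outside a
        # dielectric sphere with a central charge, checked at 10 radii
        a, q, eps_in = 10.0, 10.0, 2.0
        p = dp.ParticleModel(dp.make_sphere(a), eps_in,
                             dp.ChargeSet([[0, 0, 0]], [q]))
        sol = dp.solve_scene(Scene((p,), solvent), 4)
        _, pref = dh_sphere_closed_forms(solvent, a, q, eps_in)
        rng = np.random.default_rng(2)
        for r in np.linspace(12.0, 60.0, 10):
            th, ph = rng.uniform(0, math.pi), rng.uniform(0, 2 * math.pi)
            pt = [r * math.sin(th) * math.cos(ph), r * math.sin(th) * math.sin(ph),
                  r * math.cos(th)]
            want = pref * math.exp(-r / solvent.debye_length) / r
            assert dp.potential_at(sol, [pt]) == pytest.approx(want, rel=1e-9)

    def test_far_field_screened_decay(self, cone_pair):
        sol = dp.solve_scene(cone_pair, 6)
        kap = cone_pair.solvent.kappa
        rs = np.array([80.0, 120.0, 160.0, 200.0])
        vals = np.array([dp.potential_at(sol, [[0.6 * r, 0, 0.8 * r]]) for r in rs])
        bounded = np.abs(vals) * rs * np.exp(kap * rs)
        assert np.all(np.isfinite(bounded))
        assert np.max(bounded) < 10 * np.max(np.abs(bounded[0]))

    def test_azimuthal_consistency_of_axisymmetric_scene(self, cone_pair):
        sol = dp.solve_scene(cone_pair, 6)
        up = dp.potential_at(sol, [[0.0, 15.0, 25.0]])
        dn = dp.potential_at(sol, [[0.0, -15.0, 25.0]])
        assert up == pytest.approx(dn, rel=1e-12)

    def test_interior_representation_continuous_with_exterior(self, solvent):
        a, q = 10.0, 10.0
        p = dp.ParticleModel(dp.make_sphere(a), 2.0, dp.ChargeSet([[0, 0, 0]], [q]))
        opts = dp.AssemblyOptions(abs_tol=1e-13, rel_tol=1e-10)
        sol = dp.solve_scene(Scene((p,), solvent), 4, options=opts)
        # the offset must be small enough that the genuine potential
        # gradient (~30 kBT/e/A on the interior side) stays below tolerance
        eps = 1e-9
        inside = dp.potential_at(sol, [[0, 0, a - eps]])
        outside = dp.potential_at(sol, [[0, 0, a + eps]])
        assert inside == pytest.approx(outside, rel=1e-7)

    def test_evaluation_at_charge_raises(self, solvent):
        p = dp.ParticleModel(dp.make_sphere(10.0), 2.0,
                             dp.ChargeSet([[0, 0, 0]], [1.0]))
        sol = dp.solve_scene(Scene((p,), solvent), 2)
        with pytest.raises(ValueError):
            dp.potential_at(sol, [[0.0, 0.0, 0.0]])


class TestEnergy:
    def test_two_sphere_dlvo_limit(self, sphere_pair, solvent):
        # Born part exact, interaction within 1% of DLVO at kR >= 5
        sol = dp.solve_scene(sphere_pair, 6)
        er = dp.total_energy(sol)
        born, _ = dh_sphere_closed_forms(solvent, 10.0, 10.0, 2.0)
        assert er.W_Born == pytest.approx(2 * born, rel=1e-12)
        want = dlvo_energy(solvent, 10.0, 10.0, 10.0, 10.0, 50.0)
        assert er.W_int == pytest.approx(want, rel=0.01)
        assert solvent.kappa * 50.0 > 5.0

    def test_self_energy_exclusion_homogeneous_limit(self):
        # eps_in = eps_sol, kappa -> 0: W reduces to the plain Coulomb
        # interaction among distinct charges (no infinite self terms)
        sv = dp.SolventModel(80.0, 1e6)
        d = 4.0
        p = dp.ParticleModel(
            dp.make_sphere(10.0), 80.0,
            dp.ChargeSet([[0, 0, -d / 2], [0, 0, d / 2]], [2.0, -3.0]),
        )
        scene = Scene((p,), sv)
        sol = dp.solve_scene(scene, 6)
        W = interaction_site_energy(scene, sol.coefficients, 6)
        want = sv.coulomb * 2.0 * (-3.0) / (80.0 * d)
        assert W == pytest.approx(want, rel=1e-5)

    def test_energy_convergence_monotone_stabilizing(self, cone_pair):
        # |W(n) - W(n+2)| decreases and W has stabilized near n_max ~ 9
        Ws = {}
        for n_max in (5, 7, 9, 11):
            sol = dp.solve_scene(cone_pair, n_max)
            Ws[n_max] = interaction_site_energy(cone_pair, sol.coefficients, n_max)
        diffs = [abs(Ws[7] - Ws[5]), abs(Ws[9] - Ws[7]), abs(Ws[11] - Ws[9])]
        assert diffs[0] > diffs[1] > diffs[2]
        assert diffs[2] < 1.0  # stabilized to ~kBT by n_max = 9-11


class TestProfileAndForce:
    def test_profile_invariants(self, solvent):
        p = dp.ParticleModel(dp.make_sphere(10.0), 2.0,
                             dp.ChargeSet([[0, 0, 0]], [10.0]))
        R = [40.0, 50.0, 50.0, 70.0]
        df = dp.energy_profile((p, p), solvent, R, n_max=4)
        # duplicate separations give identical energies; Born column constant
        assert df.W_kBT[1] == df.W_kBT[2]
        assert df.W_Born_kBT.std() == 0.0
        # screened decay of the interaction: W_int ~ e^{-kR}/R
        kap = solvent.kappa
        ratio = df.W_int_kBT[3] / df.W_int_kBT[0]
        want = math.exp(-kap * (70 - 40)) * 40 / 70
        assert ratio == pytest.approx(want, rel=0.05)

    def test_intersecting_rows_flagged_not_fatal(self, solvent):
        p = dp.ParticleModel(dp.make_sphere(10.0), 2.0,
                             dp.ChargeSet([[0, 0, 0]], [10.0]))
        df = dp.energy_profile((p, p), solvent, [15.0, 40.0], n_max=2)
        assert not df.ok[0] and np.isnan(df.W_kBT[0])
        assert df.ok[1] and np.isfinite(df.W_kBT[1])

    def test_force_matches_dlvo_derivative(self, solvent):
        # -dW/dR vs the analytic DLVO derivative, 0.1% at large kR
        p = dp.ParticleModel(dp.make_sphere(10.0), 2.0,
                             dp.ChargeSet([[0, 0, 0]], [10.0]))
        R = 60.0
        got = dp.force_along_axis((p, p), solvent, R, h=0.5, n_max=4,
                                  richardson=True)
        kap = solvent.kappa
        Wd = dlvo_energy(solvent, 10.0, 10.0, 10.0, 10.0, R)
        want = Wd * (kap + 1.0 / R)  # -d/dR of e^{-kR}/R form
        assert got == pytest.approx(want, rel=1e-3)

    def test_central_difference_is_second_order(self, solvent):
        p = dp.ParticleModel(dp.make_sphere(10.0), 2.0,
                             dp.ChargeSet([[0, 0, 0]], [10.0]))
        ref = dp.force_along_axis((p, p), solvent, 50.0, h=0.25, n_max=3,
                                  richardson=True)
        e1 = abs(dp.force_along_axis((p, p), solvent, 50.0, h=4.0, n_max=3) - ref)
        e2 = abs(dp.force_along_axis((p, p), solvent, 50.0, h=2.0, n_max=3) - ref)
        assert e2 < 0.35 * e1  # O(h^2): halving h shrinks the error ~4x


class TestMaps:
    def test_clearance_masking_and_dx_roundtrip(self, solvent, tmp_path):
        p = dp.ParticleModel(dp.make_sphere(10.0), 2.0,
                             dp.ChargeSet([[0, 0, 0]], [5.0]))
        sol = dp.solve_scene(Scene((p,), solvent), 2)
        xs = np.array([0.0])
        ys = np.linspace(-20, 20, 8)  # even count: no node at the charge
        zs = np.linspace(-20, 20, 8)
        vals = potential_on_grid(sol, xs, ys, zs, clearance=2.0)
        r = np.sqrt(ys[None, :, None] ** 2 + zs[None, None, :] ** 2)
        assert np.all(np.isnan(vals[(np.abs(r - 10.0) < 2.0)]))
        assert np.all(np.isfinite(vals[(np.abs(r - 10.0) > 3.0)]))
        path = tmp_path / "map.dx"
        write_dx(path, vals, (0.0, -20.0, -20.0), (1.0, 5.0, 5.0))
        text = path.read_text()
        assert "gridpositions counts 1 8 8" in text
        assert "items 64" in text
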