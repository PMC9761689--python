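import math

import numpy as np
import pytest

import debyepair as dp
from debyepair.assembly import AssemblyOptions, IndexPacking, Scene, assemble_global, assemble_single
from debyepair.special import dkn_table, kn_table


def sphere_harmonic_solution(solvent, a, q_multipole_L, eps_in, n, m):
    """Independent per-harmonic closed form for a dielectric sphere: the
    transmission conditions decouple per (n, m), giving a 2x2 system for
    the interior (L) and exterior (G) coefficients given the source
    multipole L_hat (potential L_hat P_n^m cos(m phi)/r^{n+1})."""
    kap = solvent.kappa
    ascl = kap * a
    kv = kn_table(n, np.array([ascl]))[:, 0]
    dkv = dkn_table(n, np.array([ascl]))[:, 0]
    A = np.array([
        [ascl**n, -kv[n]],
        [eps_in * n * ascl ** (n - 1) * kap if n > 0 else 0.0,
         -solvent.eps_sol * dkv[n] * kap],
    ])
    b = np.array([-q_multipole_L / a ** (n + 1),
                  eps_in * (n + 1) * q_multipole_L / a ** (n + 2)])
    return np.linalg.solve(A, b)


class TestIndexPacking:
    def test_block_sizes(self):
        pk = IndexPacking(6)
        assert pk.n_cos == 7 * 8 // 2
        assert pk.n_sin == 6 * 7 // 2
        assert pk.per_particle == 2 * (6 + 1) ** 2
        assert pk.dim == 4 * (6 + 1) ** 2 == 196

    def test_roundtrip_indexing(self):
        pk = IndexPacking(4)
        x = np.arange(pk.dim, dtype=float)
        coeffs = pk.unpack(x)
        assert coeffs[1]["G"][3, 2] == x[pk.index(1, "G", 3, 2)]
        assert coeffs[0]["M"][4, 1] == x[pk.index(0, "M", 4, 1)]


class TestSphereDiagonality:
    def test_blocks_diagonal_and_match_closed_forms(self, solvent):
        # on a sphere the surface harmonics are orthogonal, so every block
        # is diagonal in (n, m) and the solution equals the per-harmonic
        # closed form
        a, q, eps_in = 10.0, 10.0, 2.0
        p = dp.ParticleModel(dp.make_sphere(a), eps_in,
                             dp.ChargeSet([[0, 0, 0]], [q]))
        sys_ = assemble_single(p, solvent, 4,
                               AssemblyOptions(force_full=True))
        for name in ("A", "C"):
            blk = sys_.block(0, name)[: sys_.packing.n_cos]
            off = blk - np.diag(np.diag(blk))
            assert np.max(np.abs(off)) <= 1e-10 * np.max(np.abs(np.diag(blk)))
        rep = dp.solve_direct(sys_)
        C = solvent.coulomb
        L_hat = C * q / eps_in  # central charge: monopole only
        L0, G0 = sphere_harmonic_solution(solvent, a, L_hat, eps_in, 0, 0)
        assert rep.coefficients[0]["L"][0, 0] == pytest.approx(L0, rel=1e-10)
        assert rep.coefficients[0]["G"][0, 0] == pytest.approx(G0, rel=1e-10)

    def test_off_center_charge_all_harmonics(self, solvent):
        # off-axis charge: every (n, m) harmonic checked against the
        # decoupled closed form through the multipole source coefficients
        a, eps_in = 10.0, 2.0
        p = dp.ParticleModel(dp.make_sphere(a), eps_in,
                             dp.ChargeSet([[3.0, 0, 0]], [5.0]))
        n_max = 8
        rep = dp.solve_direct(assemble_single(p, solvent, n_max))
        mp = dp.multipoles_from_charges(p.charges, eps_in, n_max)
        for (n, m) in [(0, 0), (1, 1), (2, 0), (3, 3), (5, 2), (8, 4)]:
            L, G = sphere_harmonic_solution(solvent, a, mp.L[n, m], eps_in, n, m)
            assert rep.coefficients[0]["L"][n, m] == pytest.approx(L, rel=1e-8, abs=1e-12)
            assert rep.coefficients[0]["G"][n, m] == pytest.approx(G, rel=1e-8, abs=1e-12)


class TestGlobalSystem:
    def test_dimension(self, sphere_pair):
        sys_ = assemble_global(sphere_pair, 6,
                               AssemblyOptions(force_full=True))
        assert sys_.matrix.shape == (196, 196)

    def test_energy_symmetric_under_relabeling(self, solvent):
        pa = dp.ParticleModel(dp.make_sphere(10.0), 2.0,
                              dp.ChargeSet([[0, 0, 0]], [10.0]))
        pb = dp.ParticleModel(dp.make_sphere(7.0), 4.0,
                              dp.ChargeSet([[0, 0, 0]], [-5.0]))
        W = {}
        for key, pair in (("ab", (pa, pb)), ("ba", (pb, pa))):
            scene = Scene(pair, solvent, R=40.0)
            sol = dp.solve_scene(scene, 5)
            W[key] = dp.total_energy(sol).W
        assert W["ab"] == pytest.approx(W["ba"], rel=1e-10)

    def test_coupling_blocks_decay_with_R(self, solvent):
        p = dp.ParticleModel(dp.make_sphere(10.0), 2.0,
                             dp.ChargeSet([[0, 0, 0]], [10.0]))
        norms = {}
        for R in (40.0, 80.0):
            sys_ = assemble_global(Scene((p, p), solvent, R=R), 4)
            norms[R] = np.max(np.abs(sys_.coupling))
        kap = solvent.kappa
        bound = norms[40.0] * math.exp(-kap * 40.0) * 40.0 / 80.0
        assert norms[80.0] <= bound * 1.5

    def test_incremental_growth_bit_identical(self, solvent):
        # at fixed quadrature settings, raising n_max must reproduce the
        # shared entries of the R-independent blocks exactly
        cone = dp.make_cone(10.0)
        p = dp.ParticleModel(cone, 2.0, dp.ChargeSet([[0, 0, 0]], [10.0]))
        opts = AssemblyOptions(mu_orders=(48, 96, 192))
        lo = assemble_single(p, solvent, 4, opts)
        hi = assemble_single(p, solvent, 6, opts)
        for name in ("A", "C", "Gb" if False else "I"):
            pass
        for name in ("A", "C", "I"):
            blo = lo.block(0, name)
            bhi = hi.block(0, name)
            assert np.array_equal(blo, bhi[: blo.shape[0], : blo.shape[1]])
        assert np.array_equal(lo.block(0, "Mvec"),
                              hi.block(0, "Mvec")[: lo.packing.n_cos])

    def test_dielectric_scaling_covariance(self, solvent):
        # scaling all permittivities by c scales the source potential and
        # hence every coefficient by 1/c (the flux condition itself is
        # scale invariant)
        def coeffs(eps_in, eps_sol):
            sv = dp.SolventModel(eps_sol, solvent.debye_length)
            p = dp.ParticleModel(dp.make_cone(10.0), eps_in,
                                 dp.ChargeSet([[0, 0, 0]], [10.0]))
            return dp.solve_direct(assemble_single(p, sv, 4)).x

        x1 = coeffs(2.0, 80.0)
        x10 = coeffs(20.0, 800.0)
        assert np.allclose(10.0 * x10, x1, rtol=1e-9)

    def test_homogeneous_medium_limit_no_reaction_field(self):
        # eps_in = eps_sol and kappa -> 0: the reaction field vanishes
        sv = dp.SolventModel(80.0, 1e6)
        p = dp.ParticleModel(dp.make_sphere(10.0), 80.0,
                             dp.ChargeSet([[0, 0, 0]], [10.0]))
        rep = dp.solve_direct(assemble_single(p, sv, 2))
        scale = sv.coulomb * 10.0 / (80.0 * 10.0)  # Coulomb potential scale
        assert abs(rep.coefficients[0]["L"][0, 0]) < 1e-5 * scale

    def test_intersecting_scene_rejected(self, solvent):
        p = dp.ParticleModel(dp.make_sphere(10.0), 2.0,
                             dp.ChargeSet([[0, 0, 0]], [1.0]))
        with pytest.raises(ValueError, match="intersect"):
            assemble_global(Scene((p, p), solvent, R=15.0), 2)

    def test_nan_entries_raise(self, solvent, sphere_pair):
        sys_ = assemble_global(sphere_pair, 2)
        sys_.base[0, 0] = np.nan
        with pytest.raises(FloatingPointError):
            dp.solve_direct(sys_)


class TestTwoSphereClosedSystem:
    def test_matches_dedicated_two_sphere_relations(self, solvent):
        # the assembled two-sphere system must reproduce, entry-wise on the
        # m = 0 slice, the dedicated two-center sphere theory: self rows
        # diagonal, coupling rows = b_{n0l}(a~, R~) weighted by the test
        # normalization
        a, R, n_max = 10.0, 50.0, 3
        p = dp.ParticleModel(dp.make_sphere(a), 2.0,
                             dp.ChargeSet([[0, 0, 0]], [10.0]))
        scene = Scene((p, p), solvent, R=R)
        sys_ = assemble_global(scene, n_max)
        kap = solvent.kappa
        table = dp.TranslationTable(n_max, kap * R, direction=+1, m_list=[0])
        E = sys_.block(0, "E")
        # undo the row/column equilibration to compare raw Galerkin entries
        pk = sys_.packing
        rows = sys_.col_scale[pk.off_L: pk.off_L + pk.n_cos] * 0 + 1
        for n in range(n_max + 1):
            for l in range(n_max + 1):
                if n + l > n_max:
                    continue
                norm_row = 2.0 * math.pi * 2.0 / (2 * n + 1)
                want = -norm_row * float(table.b(n, 0, l, kap * a))
                col_scale = sys_.col_scale[pk.per_particle + pk.off_G + l]
                row_scale = norm_row * 2 * math.pi / (2 * math.pi)  # harmonic norm^2
                got = E[n, l] * col_scale * row_scale
                assert got == pytest.approx(want, rel=1e-8, abs=1e-30)
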