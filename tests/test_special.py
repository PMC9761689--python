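import math

import mpmath
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from numpy.polynomial.legendre import leggauss
from scipy.special import lpmv

from debyepair.special import (
    assoc_legendre,
    din_table,
    dkn_table,
    gaunt_coupling,
    in_table,
    kn_table,
    legendre_table,
    radial_kernel_i,
    radial_kernel_k,
    surface_harmonic,
)


class TestRadialKernels:
    def test_k0_closed_form(self):
        # k_0(x) = sqrt(pi/2) e^{-x}/x
        x = 1.0
        assert radial_kernel_k(0, x) == pytest.approx(
            math.sqrt(math.pi / 2) * math.exp(-1.0), rel=1e-14
        )

    @pytest.mark.parametrize("n,x", [(2, 3.0), (1, 0.7), (10, 12.0)])
    def test_k_three_term_recurrence(self, n, x):
        k = kn_table(n + 1, np.array([x]))[:, 0]
        assert k[n + 1] == pytest.approx(k[n - 1] + (2 * n + 1) / x * k[n], rel=1e-12)

    def test_recurrences_on_log_grid(self):
        # both kernels satisfy f_{n+1} = f_{n-1} -+ (2n+1)/x f_n to 1e-12
        # relative on x in [1e-3, 1e3], n <= 60
        x = np.logspace(-3, 3, 25)
        k = kn_table(61, x)
        lhs = k[2:]
        rhs = k[:-2] + (2 * np.arange(1, 61)[:, None] + 1) / x[None, :] * k[1:-1]
        assert np.all(np.abs(lhs - rhs) <= 1e-12 * np.abs(lhs))
        x2 = np.logspace(-3, 1.5, 15)  # i_n overflows beyond x ~ 700 anyway
        i = in_table(61, x2)
        lhs = i[2:]
        rhs = i[:-2] - (2 * np.arange(1, 61)[:, None] + 1) / x2[None, :] * i[1:-1]
        ok = np.abs(lhs - rhs) <= 1e-12 * np.maximum(np.abs(i[:-2]), np.abs(lhs))
        assert np.all(ok)

    def test_positive_and_decreasing(self):
        x = np.linspace(0.1, 20.0, 40)
        k = kn_table(8, x)
        assert np.all(k > 0)
        assert np.all(np.diff(k, axis=1) < 0)

    def test_scaled_high_order_vs_mpmath(self):
        # scaled mode defers the exponential; high-precision oracle
        n, x = 40, 0.5
        got = radial_kernel_k(n, x, scaled=True)
        mpmath.mp.dps = 40
        want = float(mpmath.exp(x) * mpmath.besselk(n + 0.5, x) / mpmath.sqrt(x))
        assert got == pytest.approx(want, rel=1e-10)
        assert np.isfinite(radial_kernel_k(200, 1e4, scaled=True))

    def test_interior_kernel_regular_at_origin(self):
        # i_0(x) = sqrt(2/pi) sinh x / x -> finite limit as x -> 0+
        small = np.array([1e-6, 1e-5, 1e-4])
        vals = in_table(0, small)[0]
        assert np.allclose(vals, math.sqrt(2 / math.pi), rtol=1e-6)

    def test_interior_recurrence(self):
        n, x = 1, 2.0
        i = in_table(n + 1, np.array([x]))[:, 0]
        assert i[n + 1] == pytest.approx(i[n - 1] - (2 * n + 1) / x * i[n], rel=1e-12)

    def test_wronskian_identity(self):
        # i_n(x) k_n'(x) - i_n'(x) k_n(x) = -1/x^2 (derived from the Bessel
        # Wronskian I_v K_v' - I_v' K_v = -1/x)
        x = np.array([1.7])
        i = in_table(5, x)
        k = kn_table(6, x)
        di = din_table(5, x, i)
        dk = dkn_table(5, x, k)
        for n in range(6):
            w = i[n, 0] * dk[n, 0] - di[n, 0] * k[n, 0]
            assert w == pytest.approx(-1.0 / 1.7**2, rel=1e-10)

    @pytest.mark.parametrize("fn", [radial_kernel_k, radial_kernel_i])
    def test_domain_errors(self, fn):
        with pytest.raises(ValueError):
            fn(0, -1.0)
        with pytest.raises(ValueError):
            fn(-1, 1.0)

    @given(n=st.integers(0, 30), x=st.floats(0.01, 50.0))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_kernels_match_scipy_orders(self, n, x):
        from scipy.special import iv, kv

        assert radial_kernel_k(n, x) == pytest.approx(
            float(kv(n + 0.5, x)) / math.sqrt(x), rel=1e-12
        )
        assert radial_kernel_i(n, x) == pytest.approx(
            float(iv(n + 0.5, x)) / math.sqrt(x), rel=1e-12
        )


class TestLegendre:
    def test_p11_at_zero(self):
        assert assoc_legendre(1, 1, 0.0) == pytest.approx(1.0)  # no CS sign

    def test_pn_at_one(self):
        assert assoc_legendre(2, 0, 1.0) == pytest.approx(1.0)

    def test_orthogonality_integral(self):
        # int P_3^2(u)^2 du = 2 (3+2)! / ((2*3+1)(3-2)!) = 240/7
        xg, wg = leggauss(24)
        val = np.sum(wg * assoc_legendre(3, 2, xg) ** 2)
        assert val == pytest.approx(240.0 / 7.0, rel=1e-12)

    def test_m_greater_than_n_is_zero(self):
        assert assoc_legendre(2, 5, 0.3) == 0.0

    def test_domain_error(self):
        with pytest.raises(ValueError):
            assoc_legendre(2, 1, 1.5)

    @given(n=st.integers(0, 15), m=st.integers(0, 15), mu=st.floats(-1.0, 1.0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_no_condon_shortley_vs_scipy(self, n, m, mu):
        if m > n:
            return
        want = (-1.0) ** m * float(lpmv(m, n, mu))  # strip scipy's CS phase
        assert assoc_legendre(n, m, mu) == pytest.approx(want, rel=1e-9, abs=1e-10)

    def test_derivative_identity(self):
        # (1-u^2) dP/du = (n+m) P_{n-1}^m - n u P_n^m
        mu = np.linspace(-0.95, 0.95, 11)
        P, dP = legendre_table(6, 2, mu, derivative=True)
        for n in range(3, 7):
            lhs = (1 - mu**2) * dP[n - 2]
            rhs = (n + 2) * P[n - 3] - n * mu * P[n - 2]
            assert np.allclose(lhs, rhs, rtol=1e-11, atol=1e-11)


class TestSurfaceHarmonics:
    def test_sin_m0_rejected(self):
        with pytest.raises(ValueError):
            surface_harmonic(2, 0, "sin")

    def test_gram_matrix_diagonal(self):
        # basis functions with distinct (n, m, parity) are orthogonal under
        # weight sin(theta) on the sphere, n_max <= 20
        n_max = 20
        xg, wg = leggauss(2 * (n_max + 1))
        nphi = 4 * n_max + 5
        phi = np.linspace(0, 2 * math.pi, nphi, endpoint=False)
        wphi = 2 * math.pi / nphi
        theta = np.arccos(xg)
        fns = []
        for n in range(0, n_max + 1, 5):
            for m in range(0, n + 1, 4):
                fns.append(surface_harmonic(n, m, "cos"))
                if 1 <= m:
                    fns.append(surface_harmonic(n, m, "sin"))
        T, P = np.meshgrid(theta, phi, indexing="ij")
        vals = np.stack([f(T, P) for f in fns])
        gram = np.einsum("aqf,bqf,q->ab", vals, vals, wg) * wphi
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-10 * np.max(np.diag(gram))


class TestGauntCoupling:
    def test_parity_selection_rule(self):
        assert gaunt_coupling(2, 1, 2, 0) == 0.0  # l+n+p odd
        assert gaunt_coupling(1, 1, 5, 1) == 0.0  # triangle violated

    def test_cached_value_bit_identical(self):
        a = gaunt_coupling(4, 3, 5, 2)
        b = gaunt_coupling(4, 3, 5, 2)
        assert a == b  # bitwise: cached

    def test_out_of_range_indices(self):
        with pytest.raises(ValueError):
            gaunt_coupling(1, 1, 1, 2)  # m > min(l, n)
        with pytest.raises(ValueError):
            gaunt_coupling(-1, 1, 1, 0)

    def test_against_symbolic_oracle(self):
        # independent symbolic integration of the defining product integral
        import sympy

        x = sympy.Symbol("x")
        rng = np.random.default_rng(12345)
        checked = 0
        while checked < 25:
            l, n = rng.integers(0, 8, 2)
            m = int(rng.integers(0, min(l, n) + 1))
            p = int(rng.integers(abs(l - n), l + n + 1))
            expr = (
                sympy.assoc_legendre(int(l), m, x)
                * sympy.assoc_legendre(int(n), m, x)
                * sympy.legendre(p, x)
            )  # the two CS phases cancel in the product
            want = float(sympy.integrate(sympy.expand(expr), (x, -1, 1)))
            got = gaunt_coupling(int(l), int(n), p, m)
            assert got == pytest.approx(want, rel=1e-10, abs=1e-12)
            checked += 1

    def test_against_fine_quadrature_sample(self):
        # random sample checked against an independent (much finer) rule
        rng = np.random.default_rng(7)
        xg, wg = leggauss(200)
        for _ in range(200):
            l, n = rng.integers(0, 15, 2)
            m = int(rng.integers(0, min(l, n) + 1))
            p = int(rng.integers(0, 31))
            Pl = legendre_table(int(l), m, xg)[int(l) - m]
            Pn = legendre_table(int(n), m, xg)[int(n) - m]
            Pp = legendre_table(int(p), 0, xg)[int(p)]
            integrand = Pl * Pn * Pp
            want = float(np.sum(wg * integrand))
            scale = float(np.max(np.abs(integrand))) + 1.0
            got = gaunt_coupling(int(l), int(n), int(p), m)
            assert got == pytest.approx(want, rel=1e-10, abs=1e-13 * scale)
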