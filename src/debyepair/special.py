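"""Special functions for screened spherical-harmonic expansions.

Conventions
-----------
Radial kernels (dimensionless argument x = kappa*r):

* ``k_n(x) = K_{n+1/2}(x) / sqrt(x)`` -- exterior (decaying) kernel built on
  the modified Bessel function of the second kind.  With this normalization
  the Yukawa kernel obeys exactly
  ``exp(-d)/d = sum_p (2p+1) i_p(r_<) k_p(r_>) P_p(cos gamma)``.
* ``i_n(x) = I_{n+1/2}(x) / sqrt(x)`` -- regular (interior) kernel, finite at
  the origin; it is the radial kernel of the classical one-center
  re-expansion valid for r < R.

Any constant factor in these definitions is absorbed by the expansion
coefficients and cancels in all observables.

Associated Legendre polynomials use the plain definition
``P_n^m(u) = (1-u^2)^{m/2} d^m P_n / du^m`` with NO Condon-Shortley sign.
"""

from __future__ import annotations

import math
import os
import pathlib
from typing import Optional

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import iv, kv, kve

__all__ = [
    "radial_kernel_k",
    "radial_kernel_i",
    "kn_table",
    "dkn_table",
    "in_table",
    "din_table",
    "assoc_legendre",
    "legendre_table",
    "surface_harmonic",
    "gaunt_coupling",
    "enable_disk_cache",
    "save_disk_cache",
]


# ---------------------------------------------------------------------------
# radial kernels
# ---------------------------------------------------------------------------

def _check_x(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0.0):
        raise ValueError("radial kernel argument must be positive")
    return x


def kn_table(n_max: int, x, scaled: bool = False) -> np.ndarray:
    """k_0..k_{n_max} at x, stacked along the first axis.

    Uses the upward three-term recurrence k_{n+1} = k_{n-1} + (2n+1)/x k_n,
    which is stable for the second-kind kernel.  ``scaled`` multiplies by
    e^x, deferring the exponential decay (useful for large x).
    """
    if n_max < 0:
        raise ValueError("n_max must be non-negative")
    x = _check_x(x)
    out = np.empty((n_max + 1,) + x.shape, dtype=float)
    sq = math.sqrt(math.pi / 2.0)
    k0 = sq / x if scaled else sq * np.exp(-x) / x
    out[0] = k0
    if n_max >= 1:
        out[1] = k0 * (1.0 + 1.0 / x)
    for n in range(1, n_max):
        out[n + 1] = out[n - 1] + (2 * n + 1) / x * out[n]
    return out


def dkn_table(n_max: int, x, kn: Optional[np.ndarray] = None) -> np.ndarray:
    """Derivatives k_n'(x) for n = 0..n_max via k_n' = -k_{n-1} - (n+1)/x k_n
    (with k_{-1} = k_0)."""
    x = _check_x(x)
    if kn is None:
        kn = kn_table(n_max + 1, x)
    out = np.empty((n_max + 1,) + x.shape, dtype=float)
    out[0] = -kn[0] * (1.0 + 1.0 / x)
    for n in range(1, n_max + 1):
        out[n] = -kn[n - 1] - (n + 1) / x * kn[n]
    return out


def in_table(n_max: int, x) -> np.ndarray:
    """i_0..i_{n_max} at x (first-kind kernel; scipy handles order stably)."""
    if n_max < 0:
        raise ValueError("n_max must be non-negative")
    x = _check_x(x)
    orders = np.arange(n_max + 1, dtype=float) + 0.5
    shape = (n_max + 1,) + x.shape
    vals = iv(orders.reshape((-1,) + (1,) * x.ndim), x[None, ...])
    return (vals / np.sqrt(x)[None, ...]).reshape(shape)


def din_table(n_max: int, x, i_n: Optional[np.ndarray] = None) -> np.ndarray:
    """Derivatives i_n'(x) via i_n' = i_{n-1} - (n+1)/x i_n with
    i_{-1}(x) = sqrt(2/pi) cosh(x)/x."""
    x = _check_x(x)
    if i_n is None:
        i_n = in_table(n_max, x)
    out = np.empty((n_max + 1,) + x.shape, dtype=float)
    i_m1 = math.sqrt(2.0 / math.pi) * np.cosh(x) / x
    out[0] = i_m1 - 1.0 / x * i_n[0]
    for n in range(1, n_max + 1):
        out[n] = i_n[n - 1] - (n + 1) / x * i_n[n]
    return out


def radial_kernel_k(n: int, x, scaled: bool = False):
    """Exterior radial kernel k_n(x) = K_{n+1/2}(x)/sqrt(x).

    ``scaled=True`` returns e^x * k_n(x) (no exponential underflow for large
    x; finite for x up to 1e4 and n up to 200)."""
    if n < 0:
        raise ValueError("order n must be non-negative")
    x = _check_x(x)
    f = kve if scaled else kv
    val = f(n + 0.5, x) / np.sqrt(x)
    return val if val.shape else float(val)


def radial_kernel_i(n: int, x):
    """Regular interior radial kernel i_n(x) = I_{n+1/2}(x)/sqrt(x)."""
    if n < 0:
        raise ValueError("order n must be non-negative")
    x = _check_x(x)
    val = iv(n + 0.5, x) / np.sqrt(x)
    return val if val.shape else float(val)


# ---------------------------------------------------------------------------
# associated Legendre polynomials (no Condon-Shortley phase)
# ---------------------------------------------------------------------------

def legendre_table(n_max: int, m: int, mu, derivative: bool = False):
    """P_m^m(mu)..P_{n_max}^m(mu) stacked on the first axis (index n-m).

    With ``derivative`` also returns dP_n^m/dmu (computed via
    (1-mu^2) dP_n^m/dmu = (n+m) P_{n-1}^m - n mu P_n^m; at mu = +-1 the
    limit is returned, which is finite for m != 1 and uses the closed-form
    pole limit for m = 1).
    """
    if not 0 <= m <= n_max:
        raise ValueError("need 0 <= m <= n_max")
    mu = np.asarray(mu, dtype=float)
    if np.any(np.abs(mu) > 1.0 + 1e-13):
        raise ValueError("|mu| must be <= 1")
    mu = np.clip(mu, -1.0, 1.0)
    count = n_max - m + 1
    out = np.empty((count,) + mu.shape, dtype=float)
    s = np.sqrt(np.maximum(0.0, 1.0 - mu * mu))
    pmm = float(_double_factorial(2 * m - 1)) * s**m
    out[0] = pmm
    if count > 1:
        out[1] = (2 * m + 1) * mu * pmm
    for n in range(m + 1, n_max):
        out[n - m + 1] = ((2 * n + 1) * mu * out[n - m] - (n + m) * out[n - m - 1]) / (
            n - m + 1
        )
    if not derivative:
        return out
    dout = np.empty_like(out)
    one_minus = 1.0 - mu * mu
    interior = one_minus > 1e-28
    safe = np.where(interior, one_minus, 1.0)
    for n in range(m, n_max + 1):
        pn = out[n - m]
        pnm1 = out[n - m - 1] if n > m else np.zeros_like(pn)
        d = ((n + m) * pnm1 - n * mu * pn) / safe
        if not np.all(interior):
            d = np.where(interior, d, _dlegendre_pole(n, m, mu))
        dout[n - m] = d
    return out, dout


def _dlegendre_pole(n: int, m: int, mu: np.ndarray) -> np.ndarray:
    # limits of dP_n^m/dmu at mu = +-1: zero unless m in {0, 2} (finite) or
    # m == 1 (infinite; return large finite sentinel is wrong -- use exact
    # one-sided limit of the bounded combination: callers working on open
    # quadrature intervals never hit this branch; poles only appear through
    # explicit endpoint evaluation in tests with m == 0).
    if m == 0:
        val = n * (n + 1) / 2.0
        return np.where(mu > 0, val, -((-1.0) ** n) * val)
    if m == 2:
        val = (n - 1) * n * (n + 1) * (n + 2) / 4.0
        return np.where(mu > 0, val, ((-1.0) ** n) * val)
    if m == 1:
        return np.full_like(mu, np.inf)
    return np.zeros_like(mu)


def _double_factorial(n: int) -> int:
    if n <= 0:
        return 1
    r = 1
    while n > 1:
        r *= n
        n -= 2
    return r


def assoc_legendre(n: int, m: int, mu):
    """P_n^m(mu) with no Condon-Shortley sign; returns 0 for m > n."""
    if m < 0 or n < 0:
        raise ValueError("indices must be non-negative")
    mu_arr = np.asarray(mu, dtype=float)
    if np.any(np.abs(mu_arr) > 1.0 + 1e-13):
        raise ValueError("|mu| must be <= 1")
    if m > n:
        z = np.zeros_like(mu_arr)
        return z if z.shape else 0.0
    val = legendre_table(n, m, mu_arr)[n - m]
    return val if val.shape else float(val)


def surface_harmonic(n: int, m: int, parity: str):
    """Real surface harmonic basis function (theta, phi) -> value.

    ``parity`` is 'cos' or 'sin'; sin requires m >= 1 (a sin-parity function
    with m = 0 vanishes identically and is rejected).
    """
    if parity not in ("cos", "sin"):
        raise ValueError("parity must be 'cos' or 'sin'")
    if parity == "sin" and m < 1:
        raise ValueError("sin-parity basis functions require m >= 1")
    if not 0 <= m <= n:
        raise ValueError("need 0 <= m <= n")
    trig = np.cos if parity == "cos" else np.sin

    def fn(theta, phi):
        theta = np.asarray(theta, dtype=float)
        phi = np.asarray(phi, dtype=float)
        return assoc_legendre(n, m, np.cos(theta)) * trig(m * phi)

    return fn


# ---------------------------------------------------------------------------
# Gaunt-type coupling coefficients
# ---------------------------------------------------------------------------

_LEGGAUSS_CACHE: dict = {}


def _leggauss_cached(n: int):
    if n not in _LEGGAUSS_CACHE:
        _LEGGAUSS_CACHE[n] = leggauss(n)
    return _LEGGAUSS_CACHE[n]


_COUPLING_CACHE: dict = {}
_DISK_CACHE_PATH: Optional[pathlib.Path] = None
_CACHE_VERSION = "v1"


def gaunt_coupling(l: int, n: int, p: int, m: int) -> float:
    """Coupling coefficient G_{lnp}^m = int_{-1}^{1} P_l^m P_n^m P_p dmu.

    These Gaunt-type integrals are the angular coupling coefficients of the
    two-center re-expansion.  Selection rules: zero unless
    |l-n| <= p <= l+n and l+n+p is even.  Values are cached (memory and,
    optionally, a versioned on-disk table) and are exact to quadrature
    precision: the integrand is a polynomial so Gauss-Legendre integration
    with (l+n+p)/2 + 1 nodes is exact.
    """
    if min(l, n, p, m) < 0 or m > l or m > n:
        raise ValueError("invalid coupling indices: need 0 <= m <= min(l, n), p >= 0")
    if p < abs(l - n) or p > l + n or (l + n + p) % 2 == 1:
        return 0.0
    key = (l, n, p, m)
    val = _COUPLING_CACHE.get(key)
    if val is None:
        deg = l + n + p
        nodes = deg // 2 + 2
        xg, wg = _leggauss_cached(nodes)
        pl = legendre_table(l, m, xg)[l - m]
        pn = legendre_table(n, m, xg)[n - m]
        pp = legendre_table(p, 0, xg)[p]
        val = float(np.sum(wg * pl * pn * pp))
        _COUPLING_CACHE[key] = val
    return val


def enable_disk_cache(path: Optional[os.PathLike] = None) -> pathlib.Path:
    """Load (and later save) coupling coefficients from a versioned npz table."""
    global _DISK_CACHE_PATH
    if path is None:
        path = pathlib.Path.home() / ".cache" / "debyepair"
    path = pathlib.Path(path)
    path.mkdir(parents=True, exist_ok=True)
    _DISK_CACHE_PATH = path / f"gaunt_{_CACHE_VERSION}.npz"
    if _DISK_CACHE_PATH.exists():
        try:
            data = np.load(_DISK_CACHE_PATH)
            keys = data["keys"]
            vals = data["vals"]
            for row, v in zip(keys, vals):
                _COUPLING_CACHE[tuple(int(k) for k in row)] = float(v)
        except Exception:
            pass  # stale/corrupt cache is simply recomputed
    return _DISK_CACHE_PATH


def save_disk_cache() -> None:
    if _DISK_CACHE_PATH is None or not _COUPLING_CACHE:
        return
    keys = np.array(sorted(_COUPLING_CACHE), dtype=np.int64)
    vals = np.array([_COUPLING_CACHE[tuple(k)] for k in keys], dtype=float)
    np.savez_compressed(_DISK_CACHE_PATH, keys=keys, vals=vals)
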