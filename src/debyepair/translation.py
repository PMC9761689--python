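"""Two-center re-expansion of exterior screened-harmonic fields.

An exterior field of particle j,
``Phi_out,j = sum_{l,m} [G_lm cos(m phi) + H_lm sin(m phi)] k_l(r_j~) P_l^m(mu_j)``,
is rewritten in the frame of particle i (a pure z-translation by the scaled
center distance R~ = kappa R) as
``Phi_out,j = sum_{n,m} [ (sum_l b_nml G_lm) cos(m phi)
                        + (sum_l b_nml H_lm) sin(m phi) ] P_n^m(mu_i)``.

Because the translation is along z the azimuthal order m is conserved.  The
re-expansion coefficient b_nml(r~, R~) is the degree-n surface-harmonic
projection of the translated source harmonic on the sphere of scaled radius
r~ about center i.  It takes exact finite-sum product forms in the two
radial regimes (derived from the Yukawa-kernel addition theorem and the
uniqueness of interior/exterior Helmholtz expansions; see docs/methods.md):

* r~ < R~ (sphere entirely below the source center):
  ``b = (-1)^l sqrt(pi/2) (2n+1) (n-m)!/(n+m)!
        [sum_p (2p+1)/2 G_lnp^m k_p(R~)] i_n(r~)``
* r~ > R~ (sphere enclosing the source center):
  ``b =        sqrt(pi/2) (2n+1) (n-m)!/(n+m)!
        [sum_p (2p+1)/2 G_lnp^m i_p(R~)] k_n(r~)``

with the Gaunt-type coupling ``G_lnp^m = int P_l^m P_n^m P_p dmu``.  The
second form is what lifts the conventional r < R restriction: it is valid on
spheres that reach beyond the partner center.  On the crossing sphere
r~ = R~ itself the restricted function is singular at one point and the
coefficients for l >= 1 diverge; evaluations there are flagged.

Truncation follows the diagonal rule: only coefficients with
n + l - m <= n_max are retained.
"""

from __future__ import annotations

import math
from typing import Dict, Iterable, Optional, Tuple

import numpy as np
from numpy.polynomial.legendre import leggauss

from .special import (
    dkn_table,
    din_table,
    gaunt_coupling,
    in_table,
    kn_table,
    legendre_table,
)

__all__ = ["TranslationTable", "b_coefficient", "b_projection", "translate_exterior"]

VALIDITY_MARGIN = 0.02  # relative |r~-R~| band flagged as near-singular


class TranslationTable:
    """Precomputed re-expansion coefficient factors for fixed (R~, n_max).

    ``direction=+1`` places the source center at +R on the z axis of the
    evaluation frame; ``direction=-1`` at -R.  All index-dependent pieces
    independent of r~ are precomputed once; evaluating at a radius only
    costs the radial kernels.
    """

    def __init__(
        self,
        n_max: int,
        R_scaled: float,
        direction: int = +1,
        m_list: Optional[Iterable[int]] = None,
        truncate: bool = True,
    ):
        if n_max < 0:
            raise ValueError("n_max must be non-negative")
        if R_scaled <= 0:
            raise ValueError("scaled separation must be positive")
        if direction not in (+1, -1):
            raise ValueError("direction must be +1 or -1")
        self.n_max = int(n_max)
        self.R_scaled = float(R_scaled)
        self.direction = int(direction)
        self.truncate = bool(truncate)
        self._beta_in: Dict[int, np.ndarray] = {}
        self._beta_out: Dict[int, np.ndarray] = {}
        kR = kn_table(2 * n_max, np.array([self.R_scaled]))[:, 0]
        iR = in_table(2 * n_max, np.array([self.R_scaled]))[:, 0]
        for m in m_list if m_list is not None else range(n_max + 1):
            self._build_m(m, kR, iR)

    def _build_m(self, m: int, kR: np.ndarray, iR: np.ndarray) -> None:
        n_max = self.n_max
        cnt = n_max - m + 1
        b_in = np.zeros((cnt, cnt))
        b_out = np.zeros((cnt, cnt))
        for n in range(m, n_max + 1):
            pref = (
                math.sqrt(math.pi / 2.0)
                * (2 * n + 1)
                * math.factorial(n - m)
                / math.factorial(n + m)
            )
            for l in range(m, n_max + 1):
                if self.truncate and n + l - m > n_max:
                    continue
                s_in = s_out = 0.0
                for p in range(abs(l - n), l + n + 1, 2):
                    G = gaunt_coupling(l, n, p, m)
                    if G == 0.0:
                        continue
                    w = 0.5 * (2 * p + 1) * G
                    s_in += w * kR[p]
                    s_out += w * iR[p]
                if self.direction == +1:
                    sign_in, sign_out = (-1.0) ** l, 1.0
                else:
                    sign_in, sign_out = (-1.0) ** n, (-1.0) ** (n + l)
                b_in[n - m, l - m] = sign_in * pref * s_in
                b_out[n - m, l - m] = sign_out * pref * s_out
        self._beta_in[m] = b_in
        self._beta_out[m] = b_out

    # -- evaluation ---------------------------------------------------------

    def _ensure_m(self, m: int) -> None:
        if m not in self._beta_in:
            kR = kn_table(2 * self.n_max, np.array([self.R_scaled]))[:, 0]
            iR = in_table(2 * self.n_max, np.array([self.R_scaled]))[:, 0]
            self._build_m(m, kR, iR)

    def b_block(self, m: int, r_scaled, derivative: bool = False):
        """b_nml (and optionally db/dr~) for all retained (n, l) at the given
        radii: arrays of shape r.shape + (Nn, Nl) with Nn = Nl = n_max-m+1."""
        self._ensure_m(m)
        r = np.asarray(r_scaled, dtype=float)
        scalar = r.ndim == 0
        r = np.atleast_1d(r)
        if np.any(r <= 0):
            raise ValueError("radii must be positive")
        inner = r < self.R_scaled
        n_max = self.n_max
        i_tab = in_table(n_max, r)  # (n_max+1, N)
        k_tab = kn_table(n_max + 1, r)
        rad = np.where(inner[None, :], i_tab[m:], k_tab[m : n_max + 1])  # (Nn, N)
        beta = np.where(
            inner[:, None, None], self._beta_in[m][None], self._beta_out[m][None]
        )  # (N, Nn, Nl)
        B = beta * rad.T[:, :, None]
        if not derivative:
            return B if not scalar else B[0]
        di = din_table(n_max, r, i_tab)
        dk = dkn_table(n_max, r, k_tab)
        drad = np.where(inner[None, :], di[m:], dk[m : n_max + 1])
        dB = beta * drad.T[:, :, None]
        return (B, dB) if not scalar else (B[0], dB[0])

    def b(self, n: int, m: int, l: int, r_scaled):
        """Single coefficient b_nml(r~, R~) (zero when m > min(n, l))."""
        if not 0 <= m:
            raise ValueError("m must be non-negative")
        if n < 0 or l < 0:
            raise ValueError("degrees must be non-negative")
        if m > min(n, l):
            r = np.asarray(r_scaled, dtype=float)
            return np.zeros(r.shape) if r.shape else 0.0
        if self.truncate and n + l - m > self.n_max:
            raise ValueError(
                f"(n={n}, l={l}, m={m}) violates the truncation n+l-m <= n_max={self.n_max}"
            )
        B = self.b_block(m, r_scaled)
        return B[..., n - m, l - m]

    def db(self, n: int, m: int, l: int, r_scaled):
        if m > min(n, l):
            r = np.asarray(r_scaled, dtype=float)
            return np.zeros(r.shape) if r.shape else 0.0
        _, dB = self.b_block(m, r_scaled, derivative=True)
        return dB[..., n - m, l - m]

    def truncation_diagnostic(self, m: int, r_scaled) -> float:
        """Magnitude of the largest retained last-diagonal (n+l-m = n_max)
        coefficient at the given radii; an indicator of truncation error."""
        B = np.atleast_3d(self.b_block(m, np.atleast_1d(np.asarray(r_scaled, float))))
        n_idx = np.arange(m, self.n_max + 1)
        mask = (n_idx[:, None] + n_idx[None, :] - m) == self.n_max
        return float(np.max(np.abs(B[:, mask]))) if mask.any() else 0.0


def b_coefficient(
    n: int, m: int, l: int, r_scaled: float, R_scaled: float, n_max: int,
    direction: int = +1,
) -> float:
    """Truncated re-expansion coefficient b_nml(r~, R~) (one-shot helper)."""
    if m > min(n, l):
        return 0.0
    if n + l - m > n_max:
        raise ValueError("index constraint n+l-m <= n_max violated")
    table = TranslationTable(n_max, R_scaled, direction=direction, m_list=[m])
    return float(table.b(n, m, l, float(r_scaled)))


def b_projection(
    n: int, m: int, l: int, r_scaled: float, R_scaled: float,
    direction: int = +1, order: int = 64, levels: int = 14,
) -> float:
    """Independent quadrature oracle for b_nml: direct surface-harmonic
    projection of the translated source harmonic on the sphere r~.

    Panel Gauss-Legendre refined geometrically toward the near pole (where
    the integrand peaks when r~ is comparable to R~).  Used for
    cross-validation; production evaluation uses the closed forms.
    """
    r, R = float(r_scaled), float(R_scaled)
    peak = 1.0 if direction == +1 else -1.0
    edges = [-1.0] + [peak * (1.0 - 2.0 * 0.5**k) for k in range(1, levels)] + [1.0]
    if peak < 0:
        edges = sorted(-e for e in edges)
    xg, wg = leggauss(order)
    total = 0.0
    norm = (2 * n + 1) * math.factorial(n - m) / (2.0 * math.factorial(n + m))
    for lo, hi in zip(edges[:-1], edges[1:]):
        mu = 0.5 * (hi - lo) * xg + 0.5 * (hi + lo)
        w = 0.5 * (hi - lo) * wg
        rj = np.sqrt(r * r + R * R - 2.0 * direction * r * R * mu)
        muj = (r * mu - direction * R) / rj
        f = kn_table(l, rj)[l] * legendre_table(l, m, muj)[l - m]
        total += float(np.sum(w * f * legendre_table(n, m, mu)[n - m]))
    return norm * total


def translate_exterior(
    coeffs: Tuple[np.ndarray, np.ndarray],
    r_scaled,
    theta,
    phi,
    table: TranslationTable,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Evaluate the translated exterior field of the partner particle.

    ``coeffs = (G, H)`` are (n_max+1, n_max+1) arrays of exterior
    coefficients (lower triangle, H used for m >= 1).  Returns
    ``(value, d value/d r~, valid)`` at the given points of frame i, where
    ``valid`` flags points safely away from the singular crossing sphere
    |r~ - R~| >= VALIDITY_MARGIN * R~.
    """
    G, H = coeffs
    r = np.atleast_1d(np.asarray(r_scaled, dtype=float))
    th = np.broadcast_to(np.asarray(theta, dtype=float), r.shape)
    ph = np.broadcast_to(np.asarray(phi, dtype=float), r.shape)
    mu = np.cos(th)
    val = np.zeros_like(r)
    dval = np.zeros_like(r)
    n_max = table.n_max
    for m in range(n_max + 1):
        if not np.any(G[m:, m]) and (m == 0 or not np.any(H[m:, m])):
            continue
        B, dB = table.b_block(m, r, derivative=True)  # (N, Nn, Nl)
        gl = G[m:, m]  # G_{l m}, l = m..n_max
        cg = B @ gl  # (N, Nn)
        dcg = dB @ gl
        if m >= 1:
            hl = H[m:, m]
            ch = B @ hl
            dch = dB @ hl
        P = legendre_table(n_max, m, mu)  # (Nn, N)
        ang_c = np.cos(m * ph)
        contr = np.einsum("nk,kn->k", P, cg)
        dcontr = np.einsum("nk,kn->k", P, dcg)
        val += contr * ang_c
        dval += dcontr * ang_c
        if m >= 1:
            ang_s = np.sin(m * ph)
            val += np.einsum("nk,kn->k", P, ch) * ang_s
            dval += np.einsum("nk,kn->k", P, dch) * ang_s
    valid = np.abs(r - table.R_scaled) >= VALIDITY_MARGIN * table.R_scaled
    return val, dval, valid
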