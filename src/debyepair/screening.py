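"""Asymptotic expansion in ascending order of Debye screening.

The only blocks of the global system that depend on the separation R are
the coupling blocks (E, F, K, L), and each of their entries carries the
factor e^{-kappa R}/R through the re-expansion coefficients.  Writing the
system as (D + O) x = b with D the particle-local part and O the coupling
part, the Neumann matrix series

    x = sum_k x^(k),   x^(0) = D^{-1} b,   x^(k) = -D^{-1} O x^(k-1)

orders the potential coefficients by powers of the small parameter
e^{-kappa R}/R: the k-th increment is O((e^{-kappa R}/R)^k).  The energy is
an affine function of the interior coefficients, so the same split yields
the k-screened energy terms W^(k); W^(0) is the Born (isolated-particle)
energy and W^(1) the singly screened (DLVO-type) pair term.
"""

from __future__ import annotations

import dataclasses
import math
from typing import List, Optional

import numpy as np
import pandas as pd
import scipy.linalg

from .assembly import BlockSystem
from .special import legendre_table

__all__ = ["ScreeningSeries", "screening_expansion", "screened_energy_terms"]

SPECTRAL_RADIUS_LIMIT = 0.99
SPECTRAL_RADIUS_WARN = 0.9


@dataclasses.dataclass
class ScreeningSeries:
    """Per-order coefficient increments and energy terms.

    ``increments[k]`` is the k-screened increment of the full coefficient
    vector (plain convention, not the normalized-basis unknowns);
    ``energy_terms[k]`` the k-screened energy addend (kBT).
    """

    orders: int
    increments: List[np.ndarray]
    energy_terms: List[float]
    small_parameter: float
    spectral_radius: float
    system: BlockSystem

    def partial_coefficients(self, K: Optional[int] = None):
        K = self.orders if K is None else K
        x = sum(self.increments[: K + 1])
        return self.system.packing.unpack(x)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": np.arange(self.orders + 1), "W_k_kBT": self.energy_terms}
        )


def _energy_functional(system: BlockSystem):
    """W = c0 + f.x with x the plain coefficient vector: c0 collects the
    intra-particle Coulomb cross terms, f projects the interior series onto
    the charge locations (1/2 sum q_k Phi_series(x_k))."""
    scene = system.scene
    pk = system.packing
    kappa = scene.solvent.kappa
    C = scene.solvent.coulomb
    f = np.zeros(pk.dim)
    c0 = 0.0
    for ip, particle in enumerate(scene.particles):
        ch = particle.charges
        if not len(ch):
            continue
        pos, q = ch.positions, ch.charges
        if len(ch) > 1:
            d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
            iu = np.triu_indices(len(ch), k=1)
            c0 += C / particle.eps_in * float(np.sum(q[iu[0]] * q[iu[1]] / d[iu]))
        r = np.linalg.norm(pos, axis=1)
        mu = np.where(r > 0, pos[:, 2] / np.where(r > 0, r, 1.0), 1.0)
        phiq = np.arctan2(pos[:, 1], pos[:, 0])
        x = kappa * r
        for k, (n, m) in enumerate(pk.cos_pairs):
            P = legendre_table(max(n, m), m, mu)[n - m]
            f[ip * pk.per_particle + pk.off_L + k] = 0.5 * float(
                np.sum(q * x**n * P * np.cos(m * phiq))
            )
        for k, (n, m) in enumerate(pk.sin_pairs):
            P = legendre_table(max(n, m), m, mu)[n - m]
            f[ip * pk.per_particle + pk.off_M + k] = 0.5 * float(
                np.sum(q * x**n * P * np.sin(m * phiq))
            )
    return c0, f


def _spectral_radius(solve_D, O: np.ndarray, iters: int = 60, seed: int = 0) -> float:
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(O.shape[0])
    v /= np.linalg.norm(v)
    rho = 0.0
    for _ in range(iters):
        w = solve_D(O @ v)
        nw = np.linalg.norm(w)
        if nw == 0:
            return 0.0
        rho, v = nw, w / nw
    return float(rho)


def screening_expansion(system: BlockSystem, K: int) -> ScreeningSeries:
    """Neumann-series expansion of the assembled system to order K.

    Raises when the spectral radius of D^{-1} O reaches 1 (particles too
    close for the expansion; use the full solve)."""
    if K < 0:
        raise ValueError("expansion order K must be >= 0")
    D, O, b = system.base, system.coupling, system.rhs
    lu = scipy.linalg.lu_factor(D)
    solve_D = lambda v: scipy.linalg.lu_solve(lu, v)
    rho = _spectral_radius(solve_D, O) if np.any(O) else 0.0
    if rho >= SPECTRAL_RADIUS_LIMIT:
        raise ValueError(
            f"Neumann series diverges (spectral radius {rho:.3f} >= "
            f"{SPECTRAL_RADIUS_LIMIT}); the particles are too close for the "
            "screening expansion -- use the full solve"
        )
    if rho >= SPECTRAL_RADIUS_WARN:
        import warnings

        warnings.warn(
            f"screening expansion close to divergence (spectral radius {rho:.3f})"
        )
    c0, f = _energy_functional(system)
    increments: List[np.ndarray] = []
    energies: List[float] = []
    y = solve_D(b)
    increments.append(system.unscale(y))
    energies.append(c0 + float(f @ increments[0]))
    for k in range(1, K + 1):
        y = -solve_D(O @ y)
        increments.append(system.unscale(y))
        energies.append(float(f @ increments[k]))
    scene = system.scene
    if scene.R is not None:
        kR = scene.solvent.kappa * scene.R
        small = math.exp(-kR) / kR  # dimensionless: scaled separation
    else:
        small = 0.0
    return ScreeningSeries(
        orders=K,
        increments=increments,
        energy_terms=energies,
        small_parameter=small,
        spectral_radius=rho,
        system=system,
    )


def screened_energy_terms(series: ScreeningSeries) -> List[float]:
    """The k-screened energy addends W^(k), k = 0..K (kBT).  Their partial
    sums converge to the full-solve total energy as K grows."""
    return list(series.energy_terms)
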