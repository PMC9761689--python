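"""Galerkin assembly of the transmission-condition linear systems.

For each particle the two transmission conditions (potential continuity and
dielectric flux continuity across the surface r_i = a_i(theta, phi)) are
projected onto the real surface-harmonic test set
``cos(m' phi) P_{n'}^{m'}(mu)`` / ``sin(m' phi) P_{n'}^{m'}(mu)`` with weight
sin(theta), yielding per-particle block rows

    A L_i + B M_i + C G_i + D H_i + E G_j + F H_j = Mvec   (continuity)
    G L_i + H M_i + I G_i + J H_i + K G_j + L H_j = Nvec   (flux)

The sixteen named blocks and the two right-hand vectors follow the standard
lettering; only E, F, K, L couple the two particles and they carry the
overall e^{-kappa R}/R screening factor through the re-expansion
coefficients.  Combining the rows of both particles gives the global square
system of dimension 4 (n_max+1)^2 (full azimuthal content); a configuration
with a single particle reduces to the 2 (n_max+1)^2 self system.

Surface integrals are evaluated patchwise with Gauss-Legendre quadrature in
mu = cos(theta) (and a uniform periodic grid in phi when the scene is not
azimuthally symmetric), refined per entry until successive refinements agree
to (abs 1e-10, rel 1e-6).  The refinement decision is entry-local, so
raising n_max adds rows and columns while previously computed entries of the
R-independent blocks are reproduced bit-identically.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from numpy.polynomial.legendre import leggauss

from .constants import SolventModel
from .sources import ParticleModel, coulomb_gradient, coulomb_potential
from .special import dkn_table, kn_table, legendre_table
from .translation import TranslationTable

__all__ = [
    "AssemblyOptions",
    "Scene",
    "IndexPacking",
    "BlockSystem",
    "assemble_global",
    "assemble_single",
]


@dataclasses.dataclass(frozen=True)
class AssemblyOptions:
    """Quadrature and truncation controls.

    ``abs_tol``/``rel_tol`` are the per-entry convergence thresholds between
    successive quadrature refinements.  ``mu_orders`` are the per-patch
    Gauss-Legendre orders tried in sequence.  ``force_full`` disables the
    azimuthal shortcut (assembling all m even for symmetric scenes).
    """

    abs_tol: float = 1e-10
    rel_tol: float = 1e-6
    mu_orders: Optional[Tuple[int, ...]] = None  # default: scaled with n_max
    phi_factor: int = 6  # phi nodes per unit of (n_max+1) at the base level
    force_full: bool = False
    check_intersection: bool = True

    def orders_for(self, n_max: int) -> Tuple[int, ...]:
        """Per-patch Gauss-Legendre refinement ladder.  The base order grows
        with n_max so the highest-degree test/trial products stay resolved
        (guarding against aliasing-induced accidental agreement)."""
        if self.mu_orders is not None:
            return self.mu_orders
        base = max(32, 2 * n_max + 16)
        return (base, 2 * base, 4 * base)


@dataclasses.dataclass(frozen=True)
class Scene:
    """One or two dielectric particles in electrolyte.

    Particle 1 sits at the origin; particle 2 (if present) at (0, 0, R),
    R in Angstrom.  Each particle's shape and charges are expressed in its
    own frame.
    """

    particles: Tuple[ParticleModel, ...]
    solvent: SolventModel
    R: Optional[float] = None

    def __post_init__(self):
        if len(self.particles) not in (1, 2):
            raise ValueError("a scene holds one or two particles")
        if len(self.particles) == 2:
            if self.R is None or self.R <= 0:
                raise ValueError("two-particle scenes need a positive separation R")

    @property
    def axisymmetric(self) -> bool:
        return all(p.axisymmetric for p in self.particles)

    def check_intersection(self, n_samples: int = 720) -> None:
        """Sampled non-intersection test: no sampled surface point of one
        particle may fall inside the other."""
        if len(self.particles) != 2:
            return
        th = np.linspace(1e-4, math.pi - 1e-4, n_samples)
        ph = np.linspace(0.0, 2 * math.pi, 8, endpoint=False)
        T, P = np.meshgrid(th, ph, indexing="ij")
        for i, j, zshift in ((0, 1, -self.R), (1, 0, self.R)):
            a = self.particles[i].shape.radius(T, P)
            pts = np.stack(
                [a * np.sin(T) * np.cos(P), a * np.sin(T) * np.sin(P),
                 a * np.cos(T) + zshift], axis=-1,
            ).reshape(-1, 3)
            if np.any(self.particles[j].shape.contains(pts)):
                raise ValueError(
                    f"particle surfaces intersect at separation R={self.R}"
                )


class IndexPacking:
    """Bijection between harmonic indices and linear positions.

    Per-particle block order: [L(cos), M(sin), G(cos), H(sin)], each block
    m-major then n = m..n_max.  Global order: particle 1 blocks, then
    particle 2.  ``m_list`` restricts the azimuthal orders kept (the
    azimuthal shortcut); the full packing has dimension 4 (n_max+1)^2.
    """

    def __init__(self, n_max: int, m_list: Optional[Sequence[int]] = None,
                 n_particles: int = 2):
        self.n_max = int(n_max)
        self.m_list = tuple(m_list) if m_list is not None else tuple(range(n_max + 1))
        if any(m < 0 or m > n_max for m in self.m_list):
            raise ValueError("m values must satisfy 0 <= m <= n_max")
        self.n_particles = int(n_particles)
        self.cos_pairs = [(n, m) for m in self.m_list for n in range(m, n_max + 1)]
        self.sin_pairs = [(n, m) for m in self.m_list if m >= 1
                          for n in range(m, n_max + 1)]
        self.n_cos = len(self.cos_pairs)
        self.n_sin = len(self.sin_pairs)
        self.per_particle = 2 * (self.n_cos + self.n_sin)
        self.dim = self.n_particles * self.per_particle
        self._cos_pos = {nm: k for k, nm in enumerate(self.cos_pairs)}
        self._sin_pos = {nm: k for k, nm in enumerate(self.sin_pairs)}

    # block offsets within one particle
    @property
    def off_L(self) -> int:
        return 0

    @property
    def off_M(self) -> int:
        return self.n_cos

    @property
    def off_G(self) -> int:
        return self.n_cos + self.n_sin

    @property
    def off_H(self) -> int:
        return 2 * self.n_cos + self.n_sin

    def index(self, particle: int, family: str, n: int, m: int) -> int:
        base = particle * self.per_particle
        if family == "L":
            return base + self.off_L + self._cos_pos[(n, m)]
        if family == "M":
            return base + self.off_M + self._sin_pos[(n, m)]
        if family == "G":
            return base + self.off_G + self._cos_pos[(n, m)]
        if family == "H":
            return base + self.off_H + self._sin_pos[(n, m)]
        raise ValueError("family must be one of L, M, G, H")

    def cos_slice_for_m(self, m: int) -> np.ndarray:
        return np.array([k for k, (n, mm) in enumerate(self.cos_pairs) if mm == m])

    def sin_slice_for_m(self, m: int) -> np.ndarray:
        return np.array([k for k, (n, mm) in enumerate(self.sin_pairs) if mm == m])

    def unpack(self, x: np.ndarray) -> List[Dict[str, np.ndarray]]:
        """Split a solution vector into per-particle triangular coefficient
        arrays L, M, G, H of shape (n_max+1, n_max+1)."""
        out = []
        for p in range(self.n_particles):
            coeffs = {f: np.zeros((self.n_max + 1, self.n_max + 1)) for f in "LMGH"}
            for (n, m) in self.cos_pairs:
                coeffs["L"][n, m] = x[self.index(p, "L", n, m)]
                coeffs["G"][n, m] = x[self.index(p, "G", n, m)]
            for (n, m) in self.sin_pairs:
                coeffs["M"][n, m] = x[self.index(p, "M", n, m)]
                coeffs["H"][n, m] = x[self.index(p, "H", n, m)]
            out.append(coeffs)
        return out


@dataclasses.dataclass
class BlockSystem:
    """Assembled global system split into the particle-local part and the
    R-dependent coupling part (zero for a single particle)."""

    base: np.ndarray  # block-diagonal over particles (A..D, G..J rows)
    coupling: np.ndarray  # E, F, K, L blocks
    rhs: np.ndarray
    packing: IndexPacking
    scene: Scene
    n_max: int
    diagnostics: Dict[str, object] = dataclasses.field(default_factory=dict)
    col_scale: Optional[np.ndarray] = None  # basis normalization factors

    def __post_init__(self):
        if self.col_scale is None:
            self.col_scale = np.ones(self.packing.dim)

    def unscale(self, x: np.ndarray) -> np.ndarray:
        """Map solved (normalized-basis) unknowns to the plain-convention
        expansion coefficients of the field series."""
        return x / self.col_scale

    @property
    def matrix(self) -> np.ndarray:
        return self.base + self.coupling

    def block(self, particle: int, name: str) -> np.ndarray:
        """Extract a named block (A..L cos/sin families are concatenated in
        the packing order; coupling blocks act on the partner's columns)."""
        pk = self.packing
        rows_bc1 = slice(particle * pk.per_particle,
                         particle * pk.per_particle + pk.n_cos + pk.n_sin)
        rows_bc2 = slice(particle * pk.per_particle + pk.n_cos + pk.n_sin,
                         (particle + 1) * pk.per_particle)
        other = 1 - particle
        cols = {
            "A": (particle, pk.off_L, pk.n_cos), "B": (particle, pk.off_M, pk.n_sin),
            "C": (particle, pk.off_G, pk.n_cos), "D": (particle, pk.off_H, pk.n_sin),
            "E": (other, pk.off_G, pk.n_cos), "F": (other, pk.off_H, pk.n_sin),
            "G": (particle, pk.off_L, pk.n_cos), "H": (particle, pk.off_M, pk.n_sin),
            "I": (particle, pk.off_G, pk.n_cos), "J": (particle, pk.off_H, pk.n_sin),
            "K": (other, pk.off_G, pk.n_cos), "L": (other, pk.off_H, pk.n_sin),
        }
        if name in ("Mvec", "Nvec"):
            return self.rhs[rows_bc1 if name == "Mvec" else rows_bc2]
        if name not in cols:
            raise KeyError(name)
        p, off, width = cols[name]
        rows = rows_bc1 if name in "ABCDEF" else rows_bc2
        src = self.coupling if name in ("E", "F", "K", "L") else self.base
        c0 = p * pk.per_particle + off
        return src[rows, c0 : c0 + width]


# ---------------------------------------------------------------------------
# node data and per-patch integration
# ---------------------------------------------------------------------------

class _PatchNodes:
    """Quadrature nodes and surface data on one smooth patch at one level."""

    def __init__(self, particle: ParticleModel, solvent: SolventModel,
                 patch, mu_order: int, phi_nodes: Optional[int]):
        kappa = solvent.kappa
        mu_lo, mu_hi = math.cos(patch.theta_hi), math.cos(patch.theta_lo)
        xg, wg = leggauss(mu_order)
        self.mu = 0.5 * (mu_hi - mu_lo) * xg + 0.5 * (mu_hi + mu_lo)
        self.wmu = 0.5 * (mu_hi - mu_lo) * wg
        self.theta = np.arccos(self.mu)
        if phi_nodes:
            self.phi = np.linspace(patch.phi_lo, patch.phi_hi, phi_nodes,
                                   endpoint=False)
            self.wphi = np.full(phi_nodes, (patch.phi_hi - patch.phi_lo) / phi_nodes)
            T, P = np.meshgrid(self.theta, self.phi, indexing="ij")
            W = np.outer(self.wmu, self.wphi)
        else:  # axisymmetric: phi handled analytically
            T, P = self.theta[:, None], np.zeros((len(self.theta), 1))
            W = self.wmu[:, None]
        self.T, self.P, self.W = T, P, W
        shape = particle.shape
        self.a = shape.radius(T, P)
        self.at = kappa * shape.dtheta(T, P)
        self.ap = kappa * shape.dphi(T, P)
        self.ascl = kappa * self.a
        self.ct = -self.at / self.ascl**2
        s = np.sin(T)
        self.cp = np.where(s > 1e-14, -self.ap / (self.ascl * np.where(s > 1e-14, s, 1.0)) ** 2, 0.0)
        # unit-normal factor 1/|grad(r - a)|: the flux condition uses the
        # true unit normal, so every normal-derivative integrand carries it
        slope_t = shape.dtheta(T, P) / self.a
        slope_p = np.where(s > 1e-14, shape.dphi(T, P) / (self.a * np.where(s > 1e-14, s, 1.0)), 0.0)
        self.nrm = 1.0 / np.sqrt(1.0 + slope_t**2 + slope_p**2)
        # source terms (own charges)
        pts = np.stack([self.a * np.sin(T) * np.cos(P),
                        self.a * np.sin(T) * np.sin(P),
                        self.a * np.cos(T)], axis=-1).reshape(-1, 3)
        if len(particle.charges):
            self.phi_hat = coulomb_potential(
                particle.charges, particle.eps_in, pts, solvent.temperature
            ).reshape(self.a.shape)
            grad = coulomb_gradient(
                particle.charges, particle.eps_in, pts, solvent.temperature
            ).reshape(self.a.shape + (3,))
            rhat = np.stack([np.sin(T) * np.cos(P), np.sin(T) * np.sin(P),
                             np.cos(T)], axis=-1)
            that = np.stack([np.cos(T) * np.cos(P), np.cos(T) * np.sin(P),
                             -np.sin(T)], axis=-1)
            phat = np.stack([-np.sin(P), np.cos(P), np.zeros_like(T)], axis=-1)
            nvec = (rhat - (shape.dtheta(T, P) / self.a)[..., None] * that
                    - np.where(s > 1e-14, shape.dphi(T, P) / (self.a * np.where(s > 1e-14, s, 1.0)), 0.0)[..., None] * phat)
            self.dphi_hat = np.einsum("...k,...k->...", grad, nvec) / kappa * self.nrm
        else:
            self.phi_hat = np.zeros_like(self.a)
            self.dphi_hat = np.zeros_like(self.a)
        # radial tables on the surface
        n_max_cache: Dict[int, tuple] = {}
        self._leg_cache: Dict[Tuple[int, int], tuple] = {}
        self._rad_cache: Dict[int, tuple] = {}

    def radial(self, n_max: int):
        if n_max not in self._rad_cache:
            x = self.ascl
            ns = np.arange(n_max + 1, dtype=float)
            powers = x[None, ...] ** ns.reshape((-1,) + (1,) * x.ndim)
            dpowers = np.zeros_like(powers)
            dpowers[1:] = ns[1:].reshape((-1,) + (1,) * x.ndim) * powers[:-1]
            kvals = kn_table(n_max + 1, x)
            dk = dkn_table(n_max, x, kvals)
            self._rad_cache[n_max] = (powers, dpowers, kvals[: n_max + 1], dk)
        return self._rad_cache[n_max]

    def legendre(self, n_max: int, m: int):
        key = (n_max, m)
        if key not in self._leg_cache:
            P, dP = legendre_table(n_max, m, self.mu, derivative=True)
            dPdth = dP * (-np.sin(self.theta))
            self._leg_cache[key] = (P, dPdth)
        return self._leg_cache[key]


def _axisym_patch_blocks(nodes: _PatchNodes, n_max: int, m: int,
                         table: Optional[TranslationTable]):
    """Per-patch contributions for one azimuthal order m on an axisymmetric
    shape (theta-only quadrature; the phi integral is analytic and equal for
    the cos and sin parities).  Returns the continuity and flux projections
    of the interior, exterior, coupling columns and the source terms."""
    P, dPdth = nodes.legendre(n_max, m)  # (Nn, Q)
    powers, dpowers, kv, dk = nodes.radial(n_max)
    Q = nodes.mu.shape[0]
    a, ct = nodes.ascl[:, 0], nodes.ct[:, 0]
    nrm = nodes.nrm[:, 0]
    pw = powers[m:, :, 0]
    dpw = dpowers[m:, :, 0]
    kvm = kv[m:, :, 0]
    dkm = dk[m:, :, 0]
    Vin = (pw * P).T  # (Q, Nn)
    DVin = ((dpw * P + pw * ct[None, :] * dPdth) * nrm[None, :]).T
    Vout = (kvm * P).T
    DVout = ((dkm * P + kvm * ct[None, :] * dPdth) * nrm[None, :]).T
    if table is not None:
        B, dB = table.b_block(m, a, derivative=True)  # (Q, Nn, Nl)
        Vcpl = np.einsum("qnl,nq->ql", B, P)
        DVcpl = (
            np.einsum("qnl,nq->ql", dB, P)
            + np.einsum("qnl,nq->ql", B, ct[None, :] * dPdth)
        ) * nrm[:, None]
    else:
        Vcpl = DVcpl = None
    Wtest = P * nodes.wmu[None, :]  # (Nn', Q)
    phifac = 2.0 * math.pi if m == 0 else math.pi
    out = {
        "A": phifac * Wtest @ Vin,
        "C": -phifac * Wtest @ Vout,
        "Gb": phifac * Wtest @ DVin,
        "I": -phifac * Wtest @ DVout,
        # row-wise reductions keep source entries bit-identical across n_max
        "Mv": -phifac * np.sum(Wtest * nodes.phi_hat[None, :, 0], axis=1)
        if m == 0 else np.zeros(P.shape[0]),
        "Nv": -phifac * np.sum(Wtest * nodes.dphi_hat[None, :, 0], axis=1)
        if m == 0 else np.zeros(P.shape[0]),
    }
    if table is not None:
        out["E"] = -phifac * Wtest @ Vcpl
        out["K"] = -phifac * Wtest @ DVcpl
    return out


def _entrywise_converged(levels: List[np.ndarray], abs_tol: float, rel_tol: float):
    """Pick, per entry, the first refinement level whose successor agrees to
    tolerance; fall back to the finest level.  Returns (values, n_unconverged)."""
    final = levels[-1].copy()
    decided = np.zeros(final.shape, dtype=bool)
    unconv = 0
    for k in range(len(levels) - 1):
        diff = np.abs(levels[k + 1] - levels[k])
        ok = (~decided) & (diff <= np.maximum(abs_tol, rel_tol * np.abs(levels[k + 1])))
        final[ok] = levels[k + 1][ok]
        decided |= ok
    unconv = int(np.sum(~decided))
    return final, unconv


# ---------------------------------------------------------------------------
# assembly drivers
# ---------------------------------------------------------------------------

def _assemble_axisym(scene: Scene, n_max: int, packing: IndexPacking,
                     opts: AssemblyOptions) -> BlockSystem:
    solvent = scene.solvent
    kappa = solvent.kappa
    two = len(scene.particles) == 2
    base = np.zeros((packing.dim, packing.dim))
    coupling = np.zeros_like(base)
    rhs = np.zeros(packing.dim)
    diagnostics: Dict[str, object] = {"patches": [], "unconverged_entries": 0}
    tables = [None, None]
    if two:
        Rs = kappa * scene.R
        tables = [
            TranslationTable(n_max, Rs, direction=+1, m_list=packing.m_list),
            TranslationTable(n_max, Rs, direction=-1, m_list=packing.m_list),
        ]
    for ip, particle in enumerate(scene.particles):
        eps_i = particle.eps_in
        per_patch_levels: Dict[Tuple[int, str], List[np.ndarray]] = {}
        for patch in particle.shape.patches:
            level_data: Dict[str, List[np.ndarray]] = {}
            for order in opts.orders_for(n_max):
                nodes = _PatchNodes(particle, solvent, patch, order, None)
                for m in packing.m_list:
                    blocks = _axisym_patch_blocks(nodes, n_max, m, tables[ip])
                    for key, val in blocks.items():
                        level_data.setdefault((m, key), []).append(val)
            for (m, key), levels in level_data.items():
                vals, unconv = _entrywise_converged(levels, opts.abs_tol, opts.rel_tol)
                diagnostics["unconverged_entries"] += unconv
                acc = per_patch_levels.setdefault((m, key), [])
                acc.append(vals)
            diagnostics["patches"].append(
                {"particle": ip, "patch": patch.name, "orders": list(opts.orders_for(n_max))}
            )
        # scatter accumulated (patch-summed) blocks into the global matrix
        other = 1 - ip
        for m in packing.m_list:
            csel = packing.cos_slice_for_m(m)
            ssel = packing.sin_slice_for_m(m) if m >= 1 else None
            summ = {key: sum(per_patch_levels[(m, key)]) for key in
                    {k for (mm, k) in per_patch_levels if mm == m}}
            p0 = ip * packing.per_particle
            rows1c = p0 + packing.off_L + csel  # continuity rows live in the
            rows2c = p0 + packing.off_G + csel  # L/G slots of the row packing
            colsL = p0 + packing.off_L + csel
            colsG = p0 + packing.off_G + csel
            base[np.ix_(rows1c, colsL)] += summ["A"]
            base[np.ix_(rows1c, colsG)] += summ["C"]
            base[np.ix_(rows2c, colsL)] += eps_i * summ["Gb"]
            base[np.ix_(rows2c, colsG)] += solvent.eps_sol * summ["I"]
            if particle.axisymmetric:
                rhs[rows1c] += summ["Mv"]
                rhs[rows2c] += eps_i * summ["Nv"]
            if two:
                colsGj = other * packing.per_particle + packing.off_G + csel
                coupling[np.ix_(rows1c, colsGj)] += summ["E"]
                coupling[np.ix_(rows2c, colsGj)] += solvent.eps_sol * summ["K"]
            if ssel is not None and len(ssel):
                rows1s = p0 + packing.off_M + ssel
                rows2s = p0 + packing.off_H + ssel
                colsM = p0 + packing.off_M + ssel
                colsH = p0 + packing.off_H + ssel
                base[np.ix_(rows1s, colsM)] += summ["A"]
                base[np.ix_(rows1s, colsH)] += summ["C"]
                base[np.ix_(rows2s, colsM)] += eps_i * summ["Gb"]
                base[np.ix_(rows2s, colsH)] += solvent.eps_sol * summ["I"]
                if two:
                    colsHj = other * packing.per_particle + packing.off_H + ssel
                    coupling[np.ix_(rows1s, colsHj)] += summ["F"] if "F" in summ else summ["E"]
                    coupling[np.ix_(rows2s, colsHj)] += (
                        solvent.eps_sol * (summ["L"] if "L" in summ else summ["K"])
                    )
        # non-axisymmetric charge sets source all m and the sin parity
        if len(particle.charges) and not particle.axisymmetric:
            _add_offaxis_rhs(scene, ip, n_max, packing, opts, rhs)
    _check_finite(base, coupling, rhs)
    return BlockSystem(base, coupling, rhs, packing, scene, n_max, diagnostics)


def _add_offaxis_rhs(scene: Scene, ip: int, n_max: int, packing: IndexPacking,
                     opts: AssemblyOptions, rhs: np.ndarray) -> None:
    """Source projections for off-axis charges inside an axisymmetric shape:
    the matrix stays m-diagonal but the right-hand side gains all azimuthal
    orders and the sin parity."""
    particle = scene.particles[ip]
    solvent = scene.solvent
    phi_n = 4 * (n_max + 1) + 8
    p0 = ip * packing.per_particle
    for patch in particle.shape.patches:
        levels_c: Dict[Tuple[int, str], List[np.ndarray]] = {}
        for order in opts.orders_for(n_max):
            nodes = _PatchNodes(particle, solvent, patch, order, phi_n)
            for m in packing.m_list:
                P, _ = nodes.legendre(n_max, m)
                Wtest = P * nodes.wmu[None, :]
                cphi = np.cos(m * nodes.phi) * nodes.wphi
                sphi = np.sin(m * nodes.phi) * nodes.wphi
                mv_c = -np.sum(Wtest * (nodes.phi_hat @ cphi)[None, :], axis=1)
                nv_c = -np.sum(Wtest * (nodes.dphi_hat @ cphi)[None, :], axis=1)
                levels_c.setdefault((m, "Mc"), []).append(mv_c)
                levels_c.setdefault((m, "Nc"), []).append(nv_c)
                if m >= 1:
                    levels_c.setdefault((m, "Ms"), []).append(
                        -np.sum(Wtest * (nodes.phi_hat @ sphi)[None, :], axis=1))
                    levels_c.setdefault((m, "Ns"), []).append(
                        -np.sum(Wtest * (nodes.dphi_hat @ sphi)[None, :], axis=1))
        for (m, key), levels in levels_c.items():
            vals, _ = _entrywise_converged(levels, opts.abs_tol, opts.rel_tol)
            csel = packing.cos_slice_for_m(m)
            if key == "Mc":
                rhs[p0 + packing.off_L + csel] += vals
            elif key == "Nc":
                rhs[p0 + packing.off_G + csel] += particle.eps_in * vals
            elif key == "Ms":
                rhs[p0 + packing.off_M + packing.sin_slice_for_m(m)] += vals
            elif key == "Ns":
                rhs[p0 + packing.off_H + packing.sin_slice_for_m(m)] += particle.eps_in * vals


def _assemble_full(scene: Scene, n_max: int, packing: IndexPacking,
                   opts: AssemblyOptions) -> BlockSystem:
    """General path: full 2D surface quadrature, all azimuthal couplings
    (needed for phi-dependent shapes)."""
    solvent = scene.solvent
    kappa = solvent.kappa
    two = len(scene.particles) == 2
    base = np.zeros((packing.dim, packing.dim))
    coupling = np.zeros_like(base)
    rhs = np.zeros(packing.dim)
    diagnostics: Dict[str, object] = {"patches": [], "unconverged_entries": 0}
    tables = [None, None]
    if two:
        Rs = kappa * scene.R
        tables = [
            TranslationTable(n_max, Rs, direction=+1, m_list=packing.m_list),
            TranslationTable(n_max, Rs, direction=-1, m_list=packing.m_list),
        ]
    for ip, particle in enumerate(scene.particles):
        eps = (particle.eps_in, solvent.eps_sol)
        other = 1 - ip
        p0, q0 = ip * packing.per_particle, (1 - ip) * packing.per_particle
        levels_acc: List[Dict[str, np.ndarray]] = []
        for li, order in enumerate(opts.orders_for(n_max)):
            phi_n = opts.phi_factor * (n_max + 1) + 8 * (li + 1)
            rows1 = np.zeros((packing.n_cos + packing.n_sin, packing.dim + 1))
            rows2 = np.zeros_like(rows1)
            for patch in particle.shape.patches:
                nodes = _PatchNodes(particle, solvent, patch, order, phi_n)
                _accumulate_full_patch(nodes, particle, scene, ip, n_max, packing,
                                       tables[ip], rows1, rows2)
            levels_acc.append({"r1": rows1, "r2": rows2})
        r1, u1 = _entrywise_converged([d["r1"] for d in levels_acc],
                                      opts.abs_tol, opts.rel_tol)
        r2, u2 = _entrywise_converged([d["r2"] for d in levels_acc],
                                      opts.abs_tol, opts.rel_tol)
        diagnostics["unconverged_entries"] += u1 + u2
        row_idx1 = np.arange(p0, p0 + packing.n_cos + packing.n_sin)
        row_idx2 = np.arange(p0 + packing.n_cos + packing.n_sin,
                             p0 + packing.per_particle)
        own_cols = np.arange(p0, p0 + packing.per_particle)
        part_cols = np.arange(q0 + packing.off_G, q0 + packing.per_particle)
        base[np.ix_(row_idx1, own_cols)] = r1[:, own_cols]
        base[np.ix_(row_idx2, own_cols)] = r2[:, own_cols]
        if two:
            coupling[np.ix_(row_idx1, part_cols)] = r1[:, part_cols]
            coupling[np.ix_(row_idx2, part_cols)] = r2[:, part_cols]
        rhs[row_idx1] = r1[:, -1]
        rhs[row_idx2] = r2[:, -1]
    _check_finite(base, coupling, rhs)
    return BlockSystem(base, coupling, rhs, packing, scene, n_max, diagnostics)


def _accumulate_full_patch(nodes: _PatchNodes, particle: ParticleModel,
                           scene: Scene, ip: int, n_max: int,
                           packing: IndexPacking, table, rows1, rows2) -> None:
    solvent = scene.solvent
    eps_i, eps_s = particle.eps_in, solvent.eps_sol
    W = nodes.W  # (Q, F)
    theta_dim, phi_dim = W.shape
    phi = nodes.phi
    p0 = ip * packing.per_particle
    q0 = (1 - ip) * packing.per_particle
    powers, dpowers, kv, dk = nodes.radial(n_max)
    # column fields: value and normal-derivative of each basis column at nodes
    for m in packing.m_list:
        P, dPdth = nodes.legendre(n_max, m)  # (Nn, Q)
        cphi, sphi = np.cos(m * phi), np.sin(m * phi)
        pw = powers[m:]  # (Nn, Q, F)
        dpw = dpowers[m:]
        kvm, dkm = kv[m:], dk[m:]
        PQ = P[:, :, None]
        dPQ = dPdth[:, :, None]
        # interior columns (normal-derivative fields carry the unit-normal
        # factor)
        nrm = nodes.nrm[None]
        val_in = pw * PQ
        dval_in = (dpw * PQ + pw * nodes.ct[None] * dPQ) * nrm
        dphi_in = pw * PQ * nodes.cp[None] * nrm  # times d/dphi of trig
        val_out = kvm * PQ
        dval_out = (dkm * PQ + kvm * nodes.ct[None] * dPQ) * nrm
        dphi_out = kvm * PQ * nodes.cp[None] * nrm
        if table is not None:
            B, dB = table.b_block(m, nodes.ascl.ravel(), derivative=True)
            B = B.reshape(nodes.ascl.shape + B.shape[1:])
            dB = dB.reshape(nodes.ascl.shape + dB.shape[1:])
            val_c = np.einsum("qfnl,nq->lqf", B, P)
            dval_c = (
                np.einsum("qfnl,nq->lqf", dB, P)
                + np.einsum("qfnl,nqf->lqf", B, nodes.ct[None] * dPQ)
            ) * nodes.nrm[None]
            dphi_c = np.einsum("qfnl,nqf->lqf", B, PQ * nodes.cp[None] * nrm)
        # project against all test rows (m', parity')
        for mp in packing.m_list:
            Pt, _ = nodes.legendre(n_max, mp)
            cphit, sphit = np.cos(mp * phi), np.sin(mp * phi)
            for par_t, trig_t, rsel in (
                ("cos", cphit, packing.off_L + packing.cos_slice_for_m(mp)),
                ("sin", sphit, (packing.off_M + packing.sin_slice_for_m(mp))
                 if mp >= 1 else None),
            ):
                if rsel is None:
                    continue
                Wt = (Pt[:, :, None] * W[None]) * trig_t[None, None, :]  # (Nn',Q,F)

                def proj(field, trig):
                    return np.einsum("aqf,bqf,f->ab", Wt, field, trig)

                for parity, trig, dtrig, colL, colG in (
                    ("cos", cphi, -m * sphi,
                     p0 + packing.off_L + packing.cos_slice_for_m(m),
                     p0 + packing.off_G + packing.cos_slice_for_m(m)),
                    ("sin", sphi, m * cphi,
                     (p0 + packing.off_M + packing.sin_slice_for_m(m)) if m >= 1 else None,
                     (p0 + packing.off_H + packing.sin_slice_for_m(m)) if m >= 1 else None),
                ):
                    if colL is None:
                        continue
                    rows1[np.ix_(rsel, colL)] += proj(val_in, trig)
                    rows1[np.ix_(rsel, colG)] += -proj(val_out, trig)
                    rows2[np.ix_(rsel, colL)] += eps_i * (
                        proj(dval_in, trig) + proj(dphi_in, dtrig)
                    )
                    rows2[np.ix_(rsel, colG)] += -eps_s * (
                        proj(dval_out, trig) + proj(dphi_out, dtrig)
                    )
                    if table is not None:
                        colGj = (q0 + packing.off_G + packing.cos_slice_for_m(m)
                                 if parity == "cos"
                                 else q0 + packing.off_H + packing.sin_slice_for_m(m))
                        rows1[np.ix_(rsel, colGj)] += -np.einsum(
                            "aqf,lqf,f->al", Wt, val_c, trig)
                        rows2[np.ix_(rsel, colGj)] += -eps_s * (
                            np.einsum("aqf,lqf,f->al", Wt, dval_c, trig)
                            + np.einsum("aqf,lqf,f->al", Wt, dphi_c, dtrig)
                        )
                # right-hand side (independent of the trial index m: add once)
                if m == packing.m_list[0]:
                    rows1[rsel, -1] += -np.einsum("aqf,qf->a", Wt, nodes.phi_hat)
                    rows2[rsel, -1] += -eps_i * np.einsum("aqf,qf->a", Wt, nodes.dphi_hat)


def _check_finite(*arrays) -> None:
    for arr in arrays:
        if not np.all(np.isfinite(arr)):
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise FloatingPointError(f"non-finite entry during assembly at {tuple(bad)}")


def assemble_global(scene: Scene, n_max: int,
                    options: Optional[AssemblyOptions] = None) -> BlockSystem:
    """Assemble the global transmission system for a one- or two-particle
    scene.  Azimuthally symmetric scenes use the m = 0 shortcut (the higher
    orders decouple and carry no source); axisymmetric shapes with off-axis
    charges keep all m but stay m-diagonal; general shapes use the full 2D
    quadrature path."""
    opts = options or AssemblyOptions()
    if n_max < 0:
        raise ValueError("n_max must be non-negative")
    if opts.check_intersection:
        scene.check_intersection()
    shapes_axisym = all(p.shape.axisymmetric for p in scene.particles)
    if scene.axisymmetric and not opts.force_full:
        packing = IndexPacking(n_max, m_list=[0], n_particles=len(scene.particles))
        system = _assemble_axisym(scene, n_max, packing, opts)
    else:
        packing = IndexPacking(n_max, n_particles=len(scene.particles))
        system = (_assemble_axisym if shapes_axisym else _assemble_full)(
            scene, n_max, packing, opts
        )
    _normalize_columns(system)
    return system


def _harmonic_norm2(n: int, m: int) -> float:
    """Squared surface norm of the real harmonic cos/sin(m phi) P_n^m."""
    phifac = 2.0 * math.pi if m == 0 else math.pi
    return phifac * 2.0 * math.factorial(n + m) / ((2 * n + 1) * math.factorial(n - m))


def _normalize_columns(system: BlockSystem) -> None:
    """Equilibrate the system without changing the Galerkin solution:
    columns are scaled by the trial-function surface magnitude (radial
    factor at a reference radius times the harmonic norm; undone by
    ``unscale``) and rows by the test-harmonic norm.  This keeps the direct
    solve usable to larger n_max, where the raw system's conditioning
    degrades rapidly."""
    pk = system.packing
    kappa = system.scene.solvent.kappa
    scale = np.ones(pk.dim)
    rscale = np.ones(pk.dim)
    for ip, particle in enumerate(system.scene.particles):
        x_hi = kappa * particle.shape.a_max
        x_lo = kappa * particle.shape.a_min
        kv = kn_table(pk.n_max, np.array([x_lo]))[:, 0]
        p0 = ip * pk.per_particle
        for k, (n, m) in enumerate(pk.cos_pairs):
            h = math.sqrt(_harmonic_norm2(n, m))
            scale[p0 + pk.off_L + k] = x_hi**n * h
            scale[p0 + pk.off_G + k] = kv[n] * h
            rscale[p0 + pk.off_L + k] = _harmonic_norm2(n, m)  # bc1 rows
            rscale[p0 + pk.off_G + k] = _harmonic_norm2(n, m)  # bc2 rows
        for k, (n, m) in enumerate(pk.sin_pairs):
            h = math.sqrt(_harmonic_norm2(n, m))
            scale[p0 + pk.off_M + k] = x_hi**n * h
            scale[p0 + pk.off_H + k] = kv[n] * h
            rscale[p0 + pk.off_M + k] = _harmonic_norm2(n, m)
            rscale[p0 + pk.off_H + k] = _harmonic_norm2(n, m)
    system.base /= scale[None, :]
    system.coupling /= scale[None, :]
    system.base /= rscale[:, None]
    system.coupling /= rscale[:, None]
    system.rhs = system.rhs / rscale
    system.col_scale = scale


def assemble_single(particle: ParticleModel, solvent: SolventModel, n_max: int,
                    options: Optional[AssemblyOptions] = None) -> BlockSystem:
    """Single-particle (isolated) system: the self blocks and source only."""
    scene = Scene(particles=(particle,), solvent=solvent)
    return assemble_global(scene, n_max, options)
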