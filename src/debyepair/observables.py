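"""Potentials, energies, profiles and forces from a solved scene.

The total electrostatic energy is W = 1/2 sum_k q_k Phi_reg(x_k), where
Phi_reg at a charge of particle i excludes that charge's own divergent
Coulomb self-term but keeps the Coulomb field of the particle's other
charges and the full regular reaction series (which already contains the
screened influence of the partner particle).  The R-independent Born part
is computed from two isolated single-particle solves, so
W_int = W - W_Born -> 0 as R -> infinity.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .assembly import AssemblyOptions, BlockSystem, Scene, assemble_global, assemble_single
from .solver import SolveReport, solve_auto, solve_direct, solve_regularized
from .sources import coulomb_potential
from .special import kn_table, legendre_table

__all__ = [
    "FieldSolution",
    "EnergyReport",
    "solve_scene",
    "potential_at",
    "total_energy",
    "energy_profile",
    "force_along_axis",
    "potential_on_grid",
    "write_dx",
]


@dataclasses.dataclass
class FieldSolution:
    """Solved potential coefficients for a scene."""

    scene: Scene
    n_max: int
    coefficients: List[Dict[str, np.ndarray]]
    report: SolveReport
    options: AssemblyOptions

    @property
    def centers(self) -> np.ndarray:
        if len(self.scene.particles) == 2:
            return np.array([[0.0, 0.0, 0.0], [0.0, 0.0, self.scene.R]])
        return np.zeros((1, 3))


def _solver_dispatch(system: BlockSystem, mode: str, solver_kwargs: dict) -> SolveReport:
    if mode == "direct":
        return solve_direct(system)
    if mode == "regularized":
        return solve_regularized(system, **solver_kwargs)
    if mode == "auto":
        return solve_auto(system, **solver_kwargs)
    raise ValueError(f"unknown solver mode {mode!r}")


def solve_scene(
    scene: Scene,
    n_max: int,
    mode: str = "direct",
    options: Optional[AssemblyOptions] = None,
    **solver_kwargs,
) -> FieldSolution:
    """Assemble and solve a scene at the given truncation degree."""
    opts = options or AssemblyOptions()
    system = assemble_global(scene, n_max, opts)
    report = _solver_dispatch(system, mode, solver_kwargs)
    return FieldSolution(scene, n_max, report.coefficients, report, opts)


# ---------------------------------------------------------------------------
# series evaluation
# ---------------------------------------------------------------------------

def _interior_series(coeffs: Dict[str, np.ndarray], n_max: int, kappa: float,
                     r, theta, phi):
    """sum_nm [L cos + M sin] (kappa r)^n P_n^m(cos theta) at points."""
    r = np.asarray(r, dtype=float)
    mu = np.cos(np.asarray(theta, dtype=float))
    phi = np.asarray(phi, dtype=float)
    x = kappa * r
    out = np.zeros(np.broadcast(r, mu, phi).shape)
    powers = x[None, ...] ** np.arange(n_max + 1).reshape((-1,) + (1,) * x.ndim)
    for m in range(n_max + 1):
        L = coeffs["L"][m:, m]
        Mc = coeffs["M"][m:, m] if m >= 1 else None
        if not np.any(L) and (Mc is None or not np.any(Mc)):
            continue
        P = legendre_table(n_max, m, mu)
        ang = np.cos(m * phi)
        term = np.einsum("n,n...,n...->...", L, powers[m:], P)
        out = out + term * ang
        if m >= 1 and np.any(Mc):
            out = out + np.einsum("n,n...,n...->...", Mc, powers[m:], P) * np.sin(m * phi)
    return out


def _exterior_series(coeffs: Dict[str, np.ndarray], n_max: int, kappa: float,
                     r, theta, phi):
    """sum_nm [G cos + H sin] k_n(kappa r) P_n^m(cos theta) at points."""
    r = np.asarray(r, dtype=float)
    mu = np.cos(np.asarray(theta, dtype=float))
    phi = np.asarray(phi, dtype=float)
    x = kappa * r
    kv = kn_table(n_max, x)
    out = np.zeros(np.broadcast(r, mu, phi).shape)
    for m in range(n_max + 1):
        G = coeffs["G"][m:, m]
        H = coeffs["H"][m:, m] if m >= 1 else None
        if not np.any(G) and (H is None or not np.any(H)):
            continue
        P = legendre_table(n_max, m, mu)
        out = out + np.einsum("n,n...,n...->...", G, kv[m:], P) * np.cos(m * phi)
        if m >= 1 and np.any(H):
            out = out + np.einsum("n,n...,n...->...", H, kv[m:], P) * np.sin(m * phi)
    return out


def _local_spherical(points: np.ndarray, center: np.ndarray):
    d = points - center
    r = np.linalg.norm(d, axis=-1)
    with np.errstate(invalid="ignore"):
        mu = np.where(r > 0, d[..., 2] / np.where(r > 0, r, 1.0), 1.0)
    theta = np.arccos(np.clip(mu, -1.0, 1.0))
    phi = np.mod(np.arctan2(d[..., 1], d[..., 0]), 2 * math.pi)
    return r, theta, phi


def potential_at(solution: FieldSolution, points) -> np.ndarray:
    """Total dimensionless potential (kBT/e) at Cartesian points (Angstrom,
    frame of particle 1).

    Inside particle i the interior representation (particular Coulomb field
    plus regular harmonic series) is used; in the solvent the sum of the
    exterior screened series of all particles.  Evaluation at a charge
    location raises."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    scene = solution.scene
    kappa = scene.solvent.kappa
    out = np.zeros(len(pts))
    inside_any = np.zeros(len(pts), dtype=bool)
    for ip, particle in enumerate(scene.particles):
        center = solution.centers[ip]
        r, th, ph = _local_spherical(pts, center)
        inside = particle.shape.contains(pts - center)
        if np.any(inside):
            coeffs = solution.coefficients[ip]
            local = pts[inside] - center
            phi_hat = (
                coulomb_potential(particle.charges, particle.eps_in, local,
                                  scene.solvent.temperature)
                if len(particle.charges)
                else np.zeros(int(np.sum(inside)))
            )
            series = _interior_series(coeffs, solution.n_max, kappa,
                                      r[inside], th[inside], ph[inside])
            out[inside] = np.atleast_1d(phi_hat) + series
        inside_any |= inside
    solventside = ~inside_any
    if np.any(solventside):
        acc = np.zeros(int(np.sum(solventside)))
        for ip, particle in enumerate(scene.particles):
            center = solution.centers[ip]
            r, th, ph = _local_spherical(pts[solventside], center)
            acc += _exterior_series(solution.coefficients[ip], solution.n_max,
                                    kappa, r, th, ph)
        out[solventside] = acc
    return out if np.asarray(points).ndim > 1 else float(out[0])


# ---------------------------------------------------------------------------
# energies
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class EnergyReport:
    """Total electrostatic energy and its Born/interaction split (kBT)."""

    W: float
    W_Born: float
    W_int: float
    per_particle_born: Tuple[float, ...]
    report: Optional[SolveReport] = None


def interaction_site_energy(scene: Scene, coefficients: List[Dict[str, np.ndarray]],
                            n_max: int) -> float:
    """1/2 sum_k q_k Phi_reg(x_k) given interior coefficients (the divergent
    per-charge Coulomb self-terms are excluded; intra-particle cross Coulomb
    terms are kept)."""
    kappa = scene.solvent.kappa
    C = scene.solvent.coulomb
    W = 0.0
    for ip, particle in enumerate(scene.particles):
        ch = particle.charges
        if not len(ch):
            continue
        pos, q = ch.positions, ch.charges
        # intra-particle Coulomb cross terms
        if len(ch) > 1:
            d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
            iu = np.triu_indices(len(ch), k=1)
            W += C / particle.eps_in * float(np.sum(q[iu[0]] * q[iu[1]] / d[iu]))
        r, th, phv = _local_spherical(pos, np.zeros(3))
        series = _interior_series(coefficients[ip], n_max, kappa, r, th, phv)
        W += 0.5 * float(np.sum(q * series))
    return W


def born_energies(scene: Scene, n_max: int,
                  options: Optional[AssemblyOptions] = None,
                  mode: str = "direct", **solver_kwargs) -> Tuple[float, ...]:
    """Isolated (Born) energy of each particle from single-particle solves."""
    out = []
    for particle in scene.particles:
        sub = Scene(particles=(particle,), solvent=scene.solvent)
        system = assemble_single(particle, scene.solvent, n_max, options)
        rep = _solver_dispatch(system, mode, solver_kwargs)
        out.append(interaction_site_energy(sub, rep.coefficients, n_max))
    return tuple(out)


def total_energy(solution: FieldSolution, mode: str = "direct",
                 **solver_kwargs) -> EnergyReport:
    """Total electrostatic energy of the solved scene, with the Born part
    recomputed from isolated single-particle solves at the same n_max."""
    W = interaction_site_energy(solution.scene, solution.coefficients,
                                solution.n_max)
    born = born_energies(solution.scene, solution.n_max, solution.options,
                         mode, **solver_kwargs)
    Wb = float(sum(born))
    return EnergyReport(W=W, W_Born=Wb, W_int=W - Wb,
                        per_particle_born=born, report=solution.report)


def energy_profile(
    particles,
    solvent,
    R_values: Sequence[float],
    n_max: int,
    mode: str = "direct",
    options: Optional[AssemblyOptions] = None,
    **solver_kwargs,
) -> pd.DataFrame:
    """Energy-vs-separation table (R_angstrom, W_kBT, W_Born_kBT, W_int_kBT).

    The Born column is computed once (it is R-independent).  Separations at
    which the particles intersect are flagged (NaN energies, ok=False) and
    the remaining rows are still computed."""
    probe = Scene(particles=tuple(particles), solvent=solvent,
                  R=float(max(R_values)))
    born = born_energies(probe, n_max, options, mode, **solver_kwargs)
    Wb = float(sum(born))
    rows = []
    for R in R_values:
        scene = Scene(particles=tuple(particles), solvent=solvent, R=float(R))
        try:
            sol = solve_scene(scene, n_max, mode, options, **solver_kwargs)
            W = interaction_site_energy(scene, sol.coefficients, n_max)
            rows.append((R, W, Wb, W - Wb, True))
        except ValueError:
            rows.append((R, np.nan, Wb, np.nan, False))
    return pd.DataFrame(rows, columns=["R_angstrom", "W_kBT", "W_Born_kBT",
                                       "W_int_kBT", "ok"])


def force_along_axis(
    particles,
    solvent,
    R: float,
    h: float = 0.05,
    n_max: int = 8,
    mode: str = "direct",
    options: Optional[AssemblyOptions] = None,
    richardson: bool = False,
    **solver_kwargs,
) -> float:
    """Central finite-difference force -dW/dR (kBT/Angstrom) on particle 2.

    ``richardson`` combines steps h and h/2 for O(h^4) accuracy."""

    def W_at(Rv: float) -> float:
        scene = Scene(particles=tuple(particles), solvent=solvent, R=float(Rv))
        sol = solve_scene(scene, n_max, mode, options, **solver_kwargs)
        return interaction_site_energy(scene, sol.coefficients, n_max)

    def central(hh: float) -> float:
        return -(W_at(R + hh) - W_at(R - hh)) / (2.0 * hh)

    if not richardson:
        return central(h)
    f_h, f_h2 = central(h), central(h / 2.0)
    return (4.0 * f_h2 - f_h) / 3.0


# ---------------------------------------------------------------------------
# potential maps
# ---------------------------------------------------------------------------

def potential_on_grid(
    solution: FieldSolution,
    xs: np.ndarray,
    ys: np.ndarray,
    zs: np.ndarray,
    clearance: float = 2.0,
) -> np.ndarray:
    """Potential on a Cartesian grid; points within ``clearance`` (Angstrom)
    of a particle surface (either side) are NaN-masked to avoid
    surface-classification ambiguity."""
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
    mask = np.zeros(len(pts), dtype=bool)
    for ip, particle in enumerate(solution.scene.particles):
        center = solution.centers[ip]
        r, th, ph = _local_spherical(pts, center)
        a = particle.shape.radius(th, ph)
        mask |= np.abs(r - a) < clearance
        if len(particle.charges):
            d = np.linalg.norm(
                pts[:, None, :] - (particle.charges.positions + center)[None, :, :],
                axis=-1,
            )
            mask |= np.min(d, axis=1) < 1e-6  # grid node on a point charge
    vals = np.full(len(pts), np.nan)
    if np.any(~mask):
        vals[~mask] = potential_at(solution, pts[~mask])
    return vals.reshape(X.shape)


def write_dx(path, values: np.ndarray, origin, deltas) -> None:
    """Write a scalar field as an OpenDX regular grid (text format)."""
    nx, ny, nz = values.shape
    with open(path, "w") as fh:
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write("origin {:.6f} {:.6f} {:.6f}\n".format(*origin))
        fh.write(f"delta {deltas[0]:.6f} 0 0\n")
        fh.write(f"delta 0 {deltas[1]:.6f} 0\n")
        fh.write(f"delta 0 0 {deltas[2]:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(f"object 3 class array type double rank 0 items {values.size} data follows\n")
        flat = values.ravel()
        for k in range(0, len(flat), 3):
            fh.write(" ".join(f"{v:.6e}" for v in flat[k : k + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "regular positions regular connections" class field\n')
        fh.write('component "positions" value 1\n')
        fh.write('component "connections" value 2\n')
        fh.write('component "data" value 3\n')
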