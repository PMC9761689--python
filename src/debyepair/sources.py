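"""Fixed charge distributions and their Coulomb (particular) solution.

A particle carries a set of embedded point charges.  The particular interior
solution is the plain Coulomb potential of those charges in the interior
dielectric; its multipole coefficients about the particle center (in the
same real-harmonic convention as the field expansions) are exact for point
charges at evaluation radii outside the smallest origin-centered sphere
containing them.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional

import numpy as np

from .constants import DEFAULT_TEMPERATURE, coulomb_constant
from .shapes import SurfaceShape
from .special import legendre_table

__all__ = [
    "ChargeSet",
    "MultipoleSet",
    "ParticleModel",
    "multipoles_from_charges",
    "coulomb_potential",
    "coulomb_gradient",
    "read_charges",
    "write_xyzq",
]


@dataclasses.dataclass(frozen=True)
class ChargeSet:
    """Point charges: positions (N,3) in Angstrom (particle frame), charges
    (N,) in units of e."""

    positions: np.ndarray
    charges: np.ndarray

    def __post_init__(self):
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        q = np.atleast_1d(np.asarray(self.charges, dtype=float))
        if pos.shape != (q.size, 3):
            raise ValueError("positions must be (N,3) matching N charges")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "charges", q)

    def __len__(self) -> int:
        return len(self.charges)

    @property
    def total_charge(self) -> float:
        return float(np.sum(self.charges))

    @property
    def max_radius(self) -> float:
        if len(self) == 0:
            return 0.0
        return float(np.max(np.linalg.norm(self.positions, axis=1)))

    def validate_inside(self, shape: SurfaceShape) -> None:
        if len(self) and not np.all(shape.contains(self.positions)):
            raise ValueError("every charge must lie strictly inside the particle surface")


@dataclasses.dataclass(frozen=True)
class MultipoleSet:
    """Real multipole coefficients of the interior Coulomb field.

    Phi_hat(r, theta, phi) = sum_{n,m} [L_nm cos(m phi) + M_nm sin(m phi)]
                              * P_n^m(cos theta) / r^{n+1}
    with r in Angstrom and the potential in kBT/e.  ``L[n][m]`` covers
    0 <= m <= n <= n_src; ``M[n][m]`` covers 1 <= m <= n.
    """

    L: np.ndarray  # (n_src+1, n_src+1), lower triangle used
    M: np.ndarray
    n_src: int

    def evaluate(self, r, theta, phi):
        r = np.asarray(r, dtype=float)
        theta = np.asarray(theta, dtype=float)
        phi = np.asarray(phi, dtype=float)
        mu = np.cos(theta)
        out = np.zeros(np.broadcast(r, theta, phi).shape)
        for m in range(self.n_src + 1):
            P = legendre_table(self.n_src, m, mu) if m <= self.n_src else None
            for n in range(m, self.n_src + 1):
                ang = self.L[n, m] * np.cos(m * phi)
                if m >= 1:
                    ang = ang + self.M[n, m] * np.sin(m * phi)
                out = out + ang * P[n - m] / r ** (n + 1)
        return out


@dataclasses.dataclass(frozen=True)
class ParticleModel:
    """A dielectric particle: surface shape, interior permittivity, charges."""

    shape: SurfaceShape
    eps_in: float
    charges: ChargeSet

    def __post_init__(self):
        if self.eps_in <= 0:
            raise ValueError("eps_in must be positive")
        self.charges.validate_inside(self.shape)

    @property
    def axisymmetric(self) -> bool:
        """True when both the shape and the charge set are azimuthally
        symmetric (all charges on the z axis)."""
        on_axis = (
            len(self.charges) == 0
            or np.all(np.abs(self.charges.positions[:, :2]) < 1e-12)
        )
        return self.shape.axisymmetric and bool(on_axis)


def multipoles_from_charges(
    charges: ChargeSet,
    eps_in: float,
    n_src: int,
    temperature: float = DEFAULT_TEMPERATURE,
) -> MultipoleSet:
    """Multipole coefficients of the interior Coulomb field of the charge set.

    Exact for point charges (up to the truncation degree n_src) at
    evaluation radii r greater than every charge radius.
    """
    if n_src < 0:
        raise ValueError("n_src must be non-negative")
    C = coulomb_constant(temperature) / eps_in
    L = np.zeros((n_src + 1, n_src + 1))
    M = np.zeros((n_src + 1, n_src + 1))
    pos = charges.positions
    r = np.linalg.norm(pos, axis=1)
    with np.errstate(invalid="ignore"):
        mu = np.where(r > 0, pos[:, 2] / np.where(r > 0, r, 1.0), 1.0)
    phi = np.arctan2(pos[:, 1], pos[:, 0])
    for m in range(n_src + 1):
        P = legendre_table(n_src, m, mu)
        for n in range(m, n_src + 1):
            scale = (2 - (1 if m == 0 else 0)) * math.factorial(n - m) / math.factorial(n + m)
            base = C * charges.charges * r**n * scale * P[n - m]
            L[n, m] = np.sum(base * np.cos(m * phi))
            if m >= 1:
                M[n, m] = np.sum(base * np.sin(m * phi))
    return MultipoleSet(L=L, M=M, n_src=n_src)


def coulomb_potential(
    charges: ChargeSet,
    eps_in: float,
    points: np.ndarray,
    temperature: float = DEFAULT_TEMPERATURE,
):
    """Coulomb potential (kBT/e) of the charge set in a uniform medium eps_in
    at the given Cartesian points (Angstrom)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    C = coulomb_constant(temperature) / eps_in
    d = np.linalg.norm(pts[:, None, :] - charges.positions[None, :, :], axis=-1)
    if np.any(d < 1e-10):
        raise ValueError("evaluation point coincides with a point charge")
    out = C * np.sum(charges.charges[None, :] / d, axis=1)
    return out if np.asarray(points).ndim > 1 else float(out[0])


def coulomb_gradient(
    charges: ChargeSet,
    eps_in: float,
    points: np.ndarray,
    temperature: float = DEFAULT_TEMPERATURE,
) -> np.ndarray:
    """Cartesian gradient of :func:`coulomb_potential` (kBT/e/Angstrom)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    C = coulomb_constant(temperature) / eps_in
    dvec = pts[:, None, :] - charges.positions[None, :, :]
    d = np.linalg.norm(dvec, axis=-1)
    if np.any(d < 1e-10):
        raise ValueError("evaluation point coincides with a point charge")
    return -C * np.sum(charges.charges[None, :, None] * dvec / d[..., None] ** 3, axis=1)


# ---------------------------------------------------------------------------
# file readers
# ---------------------------------------------------------------------------

def read_charges(path, fmt: Optional[str] = None) -> ChargeSet:
    """Read a charge file.

    ``fmt``: 'pqr' (PDB-like whitespace-separated PQR; the per-atom radius
    column is read but ignored -- geometry comes from the surface shape) or
    'xyzq' (four columns x y z q).  Inferred from the extension when None.
    """
    path = str(path)
    if fmt is None:
        fmt = "pqr" if path.lower().endswith(".pqr") else "xyzq"
    if fmt not in ("pqr", "xyzq"):
        raise ValueError(f"unknown charge file format: {fmt!r}")
    positions, charges = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            try:
                if fmt == "pqr":
                    if parts[0] not in ("ATOM", "HETATM"):
                        continue
                    x, y, z, q = (float(v) for v in parts[-5:-1])
                else:
                    if len(parts) != 4:
                        raise ValueError("expected 4 columns")
                    x, y, z, q = (float(v) for v in parts)
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed charge line: {raw!r}") from exc
            positions.append((x, y, z))
            charges.append(q)
    if not positions:
        import warnings

        warnings.warn(f"{path}: no charges found, returning an empty set")
        return ChargeSet(np.zeros((0, 3)), np.zeros(0))
    return ChargeSet(np.array(positions), np.array(charges))


def write_xyzq(path, charges: ChargeSet) -> None:
    with open(path, "w") as fh:
        for (x, y, z), q in zip(charges.positions, charges.charges):
            fh.write(f"{x:.10g} {y:.10g} {z:.10g} {q:.10g}\n")
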