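"""Particle surface parametrizations r = a(theta, phi).

A surface is described in the particle's own spherical frame by a strictly
positive, patchwise-smooth radial function.  Patches are angular subdomains
on which the radial function (and hence the surface normal) is smooth;
integration is always performed patchwise so that derivative discontinuities
(cone rims, cylinder edges) sit on patch boundaries, never inside a
quadrature panel.

Built-in families: sphere, cone (45-degree half-angle with a flat cutting
plane), thick cylinder (disk), and a harmonically perturbed sphere used as a
generic non-symmetric test shape.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Optional, Sequence, Tuple

import numpy as np

from .special import legendre_table

__all__ = [
    "SurfaceShape",
    "Patch",
    "make_sphere",
    "make_cone",
    "make_cylinder",
    "make_perturbed_sphere",
    "make_custom",
    "mirror",
]


@dataclasses.dataclass(frozen=True)
class Patch:
    """Smooth angular subdomain [theta_lo, theta_hi] x [phi_lo, phi_hi]."""

    theta_lo: float
    theta_hi: float
    phi_lo: float = 0.0
    phi_hi: float = 2.0 * math.pi
    name: str = ""


@dataclasses.dataclass(frozen=True)
class SurfaceShape:
    """Immutable particle surface r = a(theta, phi) (lengths in Angstrom).

    ``radius``, ``dtheta`` and ``dphi`` accept broadcastable arrays of
    (theta, phi) and return a, da/dtheta, da/dphi.  ``axisymmetric`` marks
    phi-independence (da/dphi identically zero).
    """

    radius: Callable[[np.ndarray, np.ndarray], np.ndarray]
    dtheta: Callable[[np.ndarray, np.ndarray], np.ndarray]
    dphi: Callable[[np.ndarray, np.ndarray], np.ndarray]
    patches: Tuple[Patch, ...]
    a_min: float
    a_max: float
    axisymmetric: bool
    name: str = "custom"

    def __post_init__(self):
        if self.a_min <= 0:
            raise ValueError("surface radial function must be strictly positive")
        lo = min(p.theta_lo for p in self.patches)
        hi = max(p.theta_hi for p in self.patches)
        if lo > 1e-12 or hi < math.pi - 1e-12:
            raise ValueError("patches must cover 0 <= theta <= pi")

    # -- geometry helpers ---------------------------------------------------

    def normal_coeffs(self, theta, phi):
        """Coefficients (c_r, c_t, c_p) of the (unnormalized) outward normal
        derivative n.grad f = c_r df/dr + c_t df/dtheta + c_p df/dphi taken
        on the surface, built from grad(r - a): c_r = 1,
        c_t = -a_theta/a^2, c_p = -a_phi/(a sin(theta))^2.

        For a sphere this reduces to the plain radial derivative d/dr.
        """
        theta = np.asarray(theta, dtype=float)
        phi = np.asarray(phi, dtype=float)
        a = self.radius(theta, phi)
        c_t = -self.dtheta(theta, phi) / a**2
        s = np.sin(theta)
        with np.errstate(divide="ignore", invalid="ignore"):
            c_p = np.where(s > 1e-14, -self.dphi(theta, phi) / (a * np.where(s > 1e-14, s, 1.0)) ** 2, 0.0)
        return np.ones_like(a), c_t, c_p

    def contains(self, points: np.ndarray, margin: float = 0.0) -> np.ndarray:
        """True for Cartesian points (in the particle frame) strictly inside
        the surface (r < a(theta, phi) - margin)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        r = np.linalg.norm(pts, axis=-1)
        theta = np.arccos(np.clip(np.divide(pts[..., 2], np.where(r > 0, r, 1.0)), -1, 1))
        phi = np.mod(np.arctan2(pts[..., 1], pts[..., 0]), 2 * math.pi)
        a = self.radius(theta, phi)
        return (r < a - margin) | (r == 0)


def _scan_extrema(radius, axisymmetric: bool) -> Tuple[float, float]:
    th = np.linspace(0.0, math.pi, 4001)
    if axisymmetric:
        a = radius(th, np.zeros_like(th))
    else:
        ph = np.linspace(0.0, 2 * math.pi, 181)
        T, P = np.meshgrid(th, ph, indexing="ij")
        a = radius(T, P)
    return float(np.min(a)), float(np.max(a))


# ---------------------------------------------------------------------------
# built-in families
# ---------------------------------------------------------------------------

def make_sphere(radius: float) -> SurfaceShape:
    """Sphere of the given radius (Angstrom)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    r = float(radius)

    def a(theta, phi):
        return np.full(np.broadcast(np.asarray(theta), np.asarray(phi)).shape, r)

    def zero(theta, phi):
        return np.zeros(np.broadcast(np.asarray(theta), np.asarray(phi)).shape)

    return SurfaceShape(a, zero, zero, (Patch(0.0, math.pi, name="sphere"),),
                        r, r, True, name="sphere")


def make_cone(z0: float) -> SurfaceShape:
    """Cone with opening angle pi/2 and height 2*z0, centered mid-height.

    Apex on the +z axis at height z0; the 45-degree lateral surface
    a = z0/(cos t + sin t) runs to the rim, where the flat cutting plane
    z = -z0 (a = -z0/cos t) closes the solid.  The patch boundary sits at
    t* = pi - arctan(2).  The mirrored partner (apex toward -z) is obtained
    with :func:`mirror`.
    """
    if z0 <= 0:
        raise ValueError("z0 must be positive")
    z0 = float(z0)
    t_star = math.pi - math.atan(2.0)

    def a(theta, phi):
        theta = np.asarray(theta, dtype=float)
        lateral = z0 / (np.cos(theta) + np.sin(theta))
        base = -z0 / np.cos(theta)
        return np.where(theta <= t_star, lateral, base)

    def da(theta, phi):
        theta = np.asarray(theta, dtype=float)
        lateral = z0 * (np.sin(theta) - np.cos(theta)) / (np.cos(theta) + np.sin(theta)) ** 2
        base = -z0 * np.sin(theta) / np.cos(theta) ** 2
        return np.where(theta <= t_star, lateral, base)

    def zero(theta, phi):
        return np.zeros(np.broadcast(np.asarray(theta), np.asarray(phi)).shape)

    patches = (Patch(0.0, t_star, name="lateral"), Patch(t_star, math.pi, name="base"))
    return SurfaceShape(a, da, zero, patches, z0 / math.sqrt(2.0),
                        z0 * math.sqrt(5.0), True, name="cone")


def make_cylinder(z0: float, h: float) -> SurfaceShape:
    """Thick cylinder (disk) of height 2*z0 and radius h, centered mid-height.

    Patches: top face (a = z0/cos t), side wall (a = h/sin t), bottom face
    (a = -z0/cos t), with transitions at t* = arctan(h/z0) and pi - t*.
    """
    if z0 <= 0 or h <= 0:
        raise ValueError("cylinder dimensions must be positive")
    z0, h = float(z0), float(h)
    t_star = math.atan2(h, z0)

    def a(theta, phi):
        theta = np.asarray(theta, dtype=float)
        top = z0 / np.abs(np.cos(theta))
        with np.errstate(divide="ignore"):
            wall = h / np.where(np.sin(theta) > 1e-300, np.sin(theta), 1e-300)
        return np.where((theta >= t_star) & (theta <= math.pi - t_star), wall, top)

    def da(theta, phi):
        theta = np.asarray(theta, dtype=float)
        face = z0 * np.sin(theta) / np.cos(theta) ** 2 * np.sign(np.cos(theta))
        with np.errstate(divide="ignore"):
            s = np.where(np.sin(theta) > 1e-300, np.sin(theta), 1e-300)
        wall = -h * np.cos(theta) / s**2
        return np.where((theta >= t_star) & (theta <= math.pi - t_star), wall, face)

    def zero(theta, phi):
        return np.zeros(np.broadcast(np.asarray(theta), np.asarray(phi)).shape)

    patches = (
        Patch(0.0, t_star, name="top"),
        Patch(t_star, math.pi - t_star, name="wall"),
        Patch(math.pi - t_star, math.pi, name="bottom"),
    )
    return SurfaceShape(a, da, zero, patches, min(z0, h),
                        math.hypot(z0, h), True, name="cylinder")


def make_perturbed_sphere(
    a0: float,
    perturbations: Sequence[Tuple[int, int, str, Optional[float]]],
    seed: Optional[int] = None,
) -> SurfaceShape:
    """Sphere of radius a0 modulated by real surface harmonics:
    a = a0 (1 + sum c_nm B_nm(theta, phi)).

    Each perturbation is (n, m, parity, amplitude); a None amplitude is drawn
    uniformly from [-0.05, 0.05] using ``seed`` (deterministic).  Shapes
    whose radial function is not strictly positive are rejected.
    """
    if a0 <= 0:
        raise ValueError("a0 must be positive")
    rng = np.random.default_rng(seed)
    terms = []
    for (n, m, parity, amp) in perturbations:
        if parity not in ("cos", "sin") or not 0 <= m <= n or (parity == "sin" and m == 0):
            raise ValueError(f"invalid perturbation index ({n},{m},{parity})")
        if amp is None:
            amp = float(rng.uniform(-0.05, 0.05))
        terms.append((int(n), int(m), parity, float(amp)))

    def fields(theta, phi, want_derivs):
        theta = np.asarray(theta, dtype=float)
        phi = np.asarray(phi, dtype=float)
        mu = np.cos(theta)
        st = np.sin(theta)
        val = np.ones(np.broadcast(theta, phi).shape)
        dth = np.zeros_like(val)
        dph = np.zeros_like(val)
        for (n, m, parity, c) in terms:
            P, dP = legendre_table(n, m, mu, derivative=True)
            trig = np.cos(m * phi) if parity == "cos" else np.sin(m * phi)
            val = val + c * P[n - m] * trig
            if want_derivs:
                dth = dth + c * dP[n - m] * (-st) * trig
                dtrig = -m * np.sin(m * phi) if parity == "cos" else m * np.cos(m * phi)
                dph = dph + c * P[n - m] * dtrig
        return val, dth, dph

    def a(theta, phi):
        return a0 * fields(theta, phi, False)[0]

    def da_t(theta, phi):
        return a0 * fields(theta, phi, True)[1]

    def da_p(theta, phi):
        return a0 * fields(theta, phi, True)[2]

    axisym = all(m == 0 for (_, m, _, _) in terms)
    a_min, a_max = _scan_extrema(a, axisym)
    if a_min <= 0:
        raise ValueError("perturbation drives the radial function non-positive")
    return SurfaceShape(a, da_t, da_p, (Patch(0.0, math.pi, name="perturbed"),),
                        a_min, a_max, axisym, name="perturbed_sphere")


def make_custom(radius, dtheta, dphi, patches, axisymmetric=False, name="custom") -> SurfaceShape:
    """User-supplied shape from radial function, angular derivatives and an
    explicit smooth-patch list."""
    a_min, a_max = _scan_extrema(radius, axisymmetric)
    return SurfaceShape(radius, dtheta, dphi, tuple(patches), a_min, a_max,
                        axisymmetric, name=name)


def mirror(shape: SurfaceShape) -> SurfaceShape:
    """Reflection theta -> pi - theta (the second particle of a mirrored pair)."""

    def a(theta, phi):
        return shape.radius(math.pi - np.asarray(theta, dtype=float), phi)

    def da_t(theta, phi):
        return -shape.dtheta(math.pi - np.asarray(theta, dtype=float), phi)

    def da_p(theta, phi):
        return shape.dphi(math.pi - np.asarray(theta, dtype=float), phi)

    patches = tuple(
        Patch(math.pi - p.theta_hi, math.pi - p.theta_lo, p.phi_lo, p.phi_hi, p.name)
        for p in reversed(shape.patches)
    )
    return SurfaceShape(a, da_t, da_p, patches, shape.a_min, shape.a_max,
                        shape.axisymmetric, name=shape.name + "_mirrored")


def _double_fact(n: int) -> int:
    r = 1
    while n > 1:
        r *= n
        n -= 2
    return r
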