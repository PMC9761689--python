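import numpy as np
import pytest

import debyepair as dp


@pytest.fixture(scope="session")
def solvent():
    """Physiological saline: eps_sol 80, Debye length 8.071 A, 25 C."""
    return dp.SolventModel(eps_sol=80.0, debye_length=8.071)


@pytest.fixture(scope="session")
def cone_pair(solvent):
    """The benchmark pair: two facing cones (height 20 A, opening angle
    pi/2) with central +10 e charges, eps_in = 2, 50 A apart."""
    cone = dp.make_cone(10.0)
    p1 = dp.ParticleModel(cone, 2.0, dp.ChargeSet([[0, 0, 0]], [10.0]))
    p2 = dp.ParticleModel(dp.mirror(cone), 2.0, dp.ChargeSet([[0, 0, 0]], [10.0]))
    return dp.Scene((p1, p2), solvent, R=50.0)


@pytest.fixture(scope="session")
def sphere_pair(solvent):
    """Two equal dielectric spheres (a = 10 A) with central +10 e charges."""
    p = dp.ParticleModel(dp.make_sphere(10.0), 2.0, dp.ChargeSet([[0, 0, 0]], [10.0]))
    return dp.Scene((p, p), solvent, R=50.0)


def dh_sphere_closed_forms(solvent, a, q, eps_in):
    """Textbook Debye-Huckel sphere: (Born energy, exterior prefactor).

    phi_out(r) = pref * exp(-kappa r)/r with
    pref = C q e^{kappa a} / (eps_sol (1 + kappa a));
    W_Born = q^2 C/(2a) [1/(eps_sol(1+kappa a)) - 1/eps_in].
    """
    C = solvent.coulomb
    ka = a / solvent.debye_length
    born = q * q * C / (2 * a) * (1.0 / (solvent.eps_sol * (1 + ka)) - 1.0 / eps_in)
    pref = C * q * np.exp(ka) / (solvent.eps_sol * (1 + ka))
    return born, pref


def dlvo_energy(solvent, a1, a2, q1, q2, R):
    """Screened DLVO pair energy for two spheres with central charges."""
    C = solvent.coulomb
    k = solvent.kappa
    return (C * q1 * q2 * np.exp(k * (a1 + a2)) * np.exp(-k * R)
            / (solvent.eps_sol * R * (1 + k * a1) * (1 + k * a2)))
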