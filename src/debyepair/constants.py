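"""Unit system and solvent model.

The package works in (e, Angstrom, kBT) units: lengths in Angstrom, charges
in units of the elementary charge, energies in kBT at the configured
temperature, potentials dimensionless in kBT/e.  The Coulomb conversion
constant is computed from CODATA physical constants at run time.
"""

from __future__ import annotations

import dataclasses
import math

from scipy import constants as _const

DEFAULT_TEMPERATURE = 298.15  # K, room temperature


def coulomb_constant(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Coulomb constant C such that the potential of a unit charge at 1 A in
    vacuum is C in kBT/e units: C = e^2 / (4 pi eps0 * 1 A * kB T)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    e = _const.elementary_charge
    kT = _const.Boltzmann * temperature
    return e * e / (4.0 * math.pi * _const.epsilon_0 * 1e-10 * kT)


def debye_length_from_ionic_strength(
    ionic_strength_molar: float,
    eps_sol: float,
    temperature: float = DEFAULT_TEMPERATURE,
) -> float:
    """Debye length in Angstrom for a 1:1 electrolyte of the given ionic
    strength (mol/L) in a solvent of relative permittivity eps_sol."""
    if ionic_strength_molar <= 0:
        raise ValueError("ionic strength must be positive")
    n = 2.0 * _const.Avogadro * ionic_strength_molar * 1e3  # ions / m^3
    kT = _const.Boltzmann * temperature
    lam2 = eps_sol * _const.epsilon_0 * kT / (n * _const.elementary_charge**2)
    return math.sqrt(lam2) * 1e10


@dataclasses.dataclass(frozen=True)
class SolventModel:
    """Electrolytic solvent: dielectric constant, Debye screening, temperature.

    Parameters
    ----------
    eps_sol : relative permittivity of the solvent.
    debye_length : kappa^-1 in Angstrom.
    temperature : absolute temperature in K (sets the kBT energy unit).
    """

    eps_sol: float
    debye_length: float
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if self.eps_sol <= 0:
            raise ValueError("eps_sol must be positive")
        if self.debye_length <= 0:
            raise ValueError("debye_length must be positive")

    @classmethod
    def from_ionic_strength(
        cls,
        eps_sol: float,
        ionic_strength_molar: float,
        temperature: float = DEFAULT_TEMPERATURE,
    ) -> "SolventModel":
        lam = debye_length_from_ionic_strength(ionic_strength_molar, eps_sol, temperature)
        return cls(eps_sol=eps_sol, debye_length=lam, temperature=temperature)

    @property
    def kappa(self) -> float:
        """Inverse Debye length in 1/Angstrom."""
        return 1.0 / self.debye_length

    @property
    def coulomb(self) -> float:
        """Coulomb constant in kBT*A/e^2 at this temperature."""
        return coulomb_constant(self.temperature)

    def kbt_to_kcal_per_mol(self, energy_kbt: float) -> float:
        kT = _const.Boltzmann * self.temperature
        return energy_kbt * kT * _const.Avogadro / 4184.0
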