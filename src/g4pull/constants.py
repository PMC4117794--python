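"""Physical constants and unit conversions.

Internal units throughout the package: force in pN, length in nm, energy in
pN·nm (= 1e-21 J) or thermal units kBT, time in s.
"""
from __future__ import annotations

from dataclasses import dataclass

#: Boltzmann constant in pN·nm/K.
KB_PN_NM_PER_K = 0.0138065

#: 1 kcal/mol expressed in pN·nm (4184 J/mol / N_A).
PN_NM_PER_KCAL_MOL = 6.9477


@dataclass(frozen=True)
class PhysicalConstants:
    """Thermodynamic state of the experiment.

    Parameters
    ----------
    temperature : float
        Absolute temperature in K. Default 295 K (room temperature,
        midpoint of 21-23 °C).
    """

    temperature: float = 295.0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")

    @property
    def kbt(self) -> float:
        """Thermal energy kB*T in pN·nm (≈4.07 at 295 K)."""
        return KB_PN_NM_PER_K * self.temperature

    @property
    def kbt_kcal_mol(self) -> float:
        """Thermal energy in kcal/mol (≈0.586 at 295 K)."""
        return self.kbt / PN_NM_PER_KCAL_MOL

    def to_kcal_mol(self, energy_kbt: float) -> float:
        """Convert an energy from kBT units to kcal/mol."""
        return energy_kbt * self.kbt_kcal_mol

    def from_kcal_mol(self, energy_kcal_mol: float) -> float:
        """Convert an energy from kcal/mol to kBT units."""
        return energy_kcal_mol / self.kbt_kcal_mol


DEFAULT_CONSTANTS = PhysicalConstants()
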