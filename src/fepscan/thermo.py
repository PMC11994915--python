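"""Thermodynamic state: temperature, Boltzmann constant, inverse temperature.

All energies in this package are kcal/mol and all distances are Å; the
Boltzmann constant is therefore expressed in kcal/(mol·K).
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Boltzmann constant in kcal/(mol·K).
KB_KCAL_PER_MOL_K: float = 0.0019872

#: Room temperature in kelvin used throughout unless overridden.
DEFAULT_TEMPERATURE: float = 300.0


@dataclass(frozen=True)
class ThermoState:
    """Temperature and derived inverse temperature β = 1/(kB·T).

    Parameters
    ----------
    temperature : float
        Absolute temperature in kelvin; must be positive.
    boltzmann_constant : float
        kB in kcal/(mol·K). Defaults to 0.0019872.

    Attributes
    ----------
    beta : float
        1/(kB·T) in mol/kcal, derived at construction.
    """

    temperature: float = DEFAULT_TEMPERATURE
    boltzmann_constant: float = KB_KCAL_PER_MOL_K
    beta: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        if not self.boltzmann_constant > 0:
            raise ValueError(
                f"boltzmann_constant must be positive, got {self.boltzmann_constant}"
            )
        object.__setattr__(
            self, "beta", 1.0 / (self.boltzmann_constant * self.temperature)
        )

    @property
    def kt(self) -> float:
        """Thermal energy kB·T in kcal/mol."""
        return self.boltzmann_constant * self.temperature
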