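"""Thermodynamic state and standard-state constants.

Every exponential formula in the package (Zwanzig averaging, K_D
conversion, uncertainty bands) pulls RT from a single :class:`ThermoState`
so temperature and the gas constant are never duplicated.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Gas constant in kcal/(mol K).
GAS_CONSTANT_KCAL = 1.9872e-3

#: Avogadro constant (1/mol), 2019 SI exact value.
AVOGADRO = 6.02214076e23


def standard_state_volume_A3() -> float:
    """Volume per molecule at the 1 mol/L standard state, in cubic angstroms.

    1 L / N_A = 10^27 A^3 / N_A ~ 1660.5 A^3. This is the reference volume
    for the entropic standard-state correction of a binding free energy.
    """
    return 1.0e27 / AVOGADRO


@dataclass(frozen=True)
class ThermoState:
    """Temperature and gas constant; owns RT.

    Parameters
    ----------
    T : float
        Absolute temperature in kelvin. Default 300 K, the simulation
        thermostat value used throughout the toy studies.
    R : float
        Gas constant in kcal/(mol K).
    """

    T: float = 300.0
    R: float = GAS_CONSTANT_KCAL

    def __post_init__(self) -> None:
        if not (self.T > 0):
            raise ValueError(f"temperature must be positive, got {self.T}")
        if not (self.R > 0):
            raise ValueError(f"gas constant must be positive, got {self.R}")

    @property
    def RT(self) -> float:
        """Thermal energy in kcal/mol."""
        return self.R * self.T
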