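"""Step A — gas-liquid phase partition of the analyte (Henry's law).

At equilibrium the dissolved concentration of a gaseous analyte is
``c = k_H · p`` where ``p`` is its partial pressure and ``k_H`` the
Henry constant in M/atm.  For a hydrogel layer with high water content
the aqueous Henry constant is applied unchanged; an optional
multiplicative gel-partition factor (default 1.0) is exposed for users
who want to correct for the gel matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .quantities import (
    DomainError,
    Quantity,
    magnitude,
    ppm_to_partial_pressure,
)

__all__ = ["AnalyteSpec", "GasSample", "equilibrium_liquid_concentration"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalyteSpec:
    """Physico-chemical constants of a gaseous analyte.

    Parameters
    ----------
    name
        Human-readable analyte name (e.g. ``"methanethiol"``).
    henry_constant
        Henry solubility ``k_H`` in M/atm at the measurement temperature.
    pKa
        Base-10 acid dissociation exponent of the proton-dissociation
        reaction (e.g. 10.3 for methanethiol ⇌ methanethiolate + H⁺).
    diffusion_coefficient
        Aqueous diffusion coefficient ``D`` in m²/s.
    notes
        Free-text provenance, e.g. "D approximated by methanol".
    """

    name: str
    henry_constant: Quantity
    pKa: float
    diffusion_coefficient: Quantity
    notes: str = ""

    def __post_init__(self) -> None:
        if magnitude(self.henry_constant, "M/atm", "henry_constant") <= 0:
            raise DomainError(f"henry_constant must be > 0, got {self.henry_constant}")
        if magnitude(self.diffusion_coefficient, "m^2/s", "diffusion_coefficient") <= 0:
            raise DomainError(
                f"diffusion_coefficient must be > 0, got {self.diffusion_coefficient}"
            )
        if not 0 < self.pKa < 20:
            raise DomainError(f"pKa must lie in (0, 20), got {self.pKa}")


@dataclass(frozen=True)
class GasSample:
    """Composition and state of the gas phase contacting the sensor.

    ``mixing_ratio_ppm`` is the analyte mole fraction × 10⁻⁶.
    Temperature is carried as metadata only: all constants are taken at
    the temperature the user supplied them for, with no van 't Hoff
    correction.
    """

    mixing_ratio_ppm: float
    total_pressure: Quantity = field(default_factory=lambda: Quantity(1.0, "atm"))
    temperature_c: float = 25.0

    def __post_init__(self) -> None:
        if self.mixing_ratio_ppm < 0:
            raise DomainError(
                f"mixing_ratio_ppm must be >= 0, got {self.mixing_ratio_ppm}"
            )
        if magnitude(self.total_pressure, "atm", "total_pressure") <= 0:
            raise DomainError(f"total_pressure must be > 0, got {self.total_pressure}")

    @property
    def partial_pressure(self) -> Quantity:
        return ppm_to_partial_pressure(self.mixing_ratio_ppm, self.total_pressure)


def equilibrium_liquid_concentration(
    gas: GasSample,
    analyte: AnalyteSpec,
    gel_partition_factor: float = 1.0,
) -> Quantity:
    """Equilibrium dissolved analyte concentration, ``c = k_H · p``.

    For 100 ppm methanethiol at 1 atm with k_H = 0.39 M/atm this gives
    3.9 × 10⁻⁵ M (≈ 40 μM).  The result is linear in both the mixing
    ratio and the Henry constant.

    Parameters
    ----------
    gel_partition_factor
        Multiplicative correction for partitioning into the gel matrix
        rather than pure water; 1.0 (default) treats the hydrogel as
        bulk water.
    """
    if gel_partition_factor <= 0:
        raise DomainError(
            f"gel_partition_factor must be > 0, got {gel_partition_factor}"
        )
    p = gas.partial_pressure.m_as("atm")
    k_h = analyte.henry_constant.m_as("M/atm")
    c = Quantity(k_h * p * gel_partition_factor, "M")
    logger.info(
        "Step A (partition): %s ppm at %s -> p = %.4g atm, c = %s",
        gas.mixing_ratio_ppm, gas.total_pressure, p, c,
    )
    return c
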