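"""Step B — intermediate acid-base speciation at buffered pH.

Thiol redox chemistry is carried by the deprotonated thiolate anion
(R-S⁻), not the neutral thiol, so the active analyte concentration is
set by the dissociation equilibrium ``K_a = [H⁺][A⁻]/[HA]``.  The pH is
fixed by the buffer ([H⁺] = 10⁻ᵖᴴ; no proton balance is solved), and
the thiolate pool is treated as quasi-equilibrated during reaction.

Two fractions are offered:

``paper_approx``
    ``[A⁻]/c_total ≈ K_a/[H⁺] = 10^(pH − pKa)`` — valid when pH ≪ pKa
    so that [HA] ≈ c_total.  At pH 7 with pKa 10.3 the anion is ~2000×
    depleted relative to the total thiol.
``exact``
    Henderson–Hasselbalch mass balance ``K_a/(K_a + [H⁺])``, which stays
    in (0, 1) at any pH.

The two agree to better than 0.1 % whenever pH ≤ pKa − 3; the
approximation exceeds 1 (unphysical) once pH ≥ pKa, which triggers an
:class:`ApproximationWarning`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

from .partition import AnalyteSpec
from .quantities import DomainError, Quantity, magnitude

__all__ = [
    "MediumSpec",
    "SpeciationResult",
    "ApproximationWarning",
    "anion_fraction",
    "speciate",
]

logger = logging.getLogger(__name__)

SPECIATION_METHODS = ("paper_approx", "exact")


class ApproximationWarning(UserWarning):
    """The dilute-acid approximation is outside its validity regime."""


@dataclass(frozen=True)
class MediumSpec:
    """The buffered aqueous medium: a fixed pH plus a description."""

    pH: float
    description: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.pH < 14:
            raise DomainError(f"pH must lie in (0, 14), got {self.pH}")


@dataclass(frozen=True)
class SpeciationResult:
    """Outcome of the dissociation equilibrium at fixed pH.

    ``depletion_factor`` = total/anion — how much less abundant the
    active anion is than the dissolved parent compound.
    """

    total_concentration: Quantity
    anion_concentration: Quantity
    anion_fraction: float
    depletion_factor: float


def anion_fraction(pKa: float, pH: float, method: str = "paper_approx") -> float:
    """Fraction of the total acid present as the deprotonated anion.

    See the module docstring for the two methods.  ``paper_approx``
    returns ``10^(pH − pKa)`` (can exceed 1; warns when pH ≥ pKa),
    ``exact`` returns ``K_a/(K_a + [H⁺])``.
    """
    if method not in SPECIATION_METHODS:
        raise ValueError(f"method must be one of {SPECIATION_METHODS}, got {method!r}")
    if not 0 < pH < 14:
        raise DomainError(f"pH must lie in (0, 14), got {pH}")
    if not 0 < pKa < 20:
        raise DomainError(f"pKa must lie in (0, 20), got {pKa}")
    if method == "paper_approx":
        frac = 10.0 ** (pH - pKa)
        if pH >= pKa:
            warnings.warn(
                f"dilute-acid approximation invalid: pH ({pH}) >= pKa ({pKa}) "
                f"gives anion fraction {frac:g} > 1; use method='exact'",
                ApproximationWarning,
                stacklevel=2,
            )
        return frac
    ka = 10.0**-pKa
    h = 10.0**-pH
    return ka / (ka + h)


def speciate(
    total: Quantity,
    analyte: AnalyteSpec,
    medium: MediumSpec,
    method: str = "paper_approx",
) -> SpeciationResult:
    """Split a total dissolved concentration into its active anion part.

    ``anion = total × anion_fraction(pKa, pH)``; linear in ``total``.
    For 40 μM methanethiol (pKa 10.3) at pH 7 the anion is ≈ 20 nM and
    the depletion factor ≈ 2000.
    """
    c_tot = magnitude(total, "M", "total")
    if c_tot < 0:
        raise DomainError(f"total concentration must be >= 0, got {total}")
    frac = anion_fraction(analyte.pKa, medium.pH, method=method)
    result = SpeciationResult(
        total_concentration=total.to("M"),
        anion_concentration=Quantity(c_tot * frac, "M"),
        anion_fraction=frac,
        depletion_factor=1.0 / frac,
    )
    logger.info(
        "Step B (speciation, %s): total %s at pH %.2f (pKa %.2f) -> anion %s "
        "(depletion %.3g x)",
        method, total, medium.pH, analyte.pKa,
        result.anion_concentration, result.depletion_factor,
    )
    return result
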