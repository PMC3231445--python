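"""Unit-safe scalar quantities for biosensor response modelling.

The gas-biosensing literature mixes units freely within a single
calculation chain (ppm in the gas phase, M/atm for Henry constants, nM
for thiolate anions, μm layer thicknesses, mM⁻¹cm⁻¹ absorption
coefficients, AU/min signals).  Silent unit mistakes are the dominant
failure mode of such chains, so every public operation in this package
accepts :class:`Quantity` objects and rejects dimensionally wrong input
with an explicit :class:`UnitError`.

This is deliberately *not* a general unit-algebra system: the vocabulary
is a closed list of the units the domain actually uses, conversions are
exact rational rescalings within one dimension, and compound-unit
arithmetic happens in plain floats inside each formula after magnitudes
have been extracted in known units.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

__all__ = [
    "Quantity",
    "UnitError",
    "DomainError",
    "convert",
    "ppm_to_partial_pressure",
    "parse_quantity",
    "dimension_of",
    "magnitude",
    "round_sig",
    "UNIT_TABLE",
]


class UnitError(ValueError):
    """A quantity carried the wrong unit/dimension for an operation."""


class DomainError(ValueError):
    """A numeric argument lies outside the physically meaningful domain."""


# unit -> (dimension, exact factor to the dimension's canonical unit)
# Canonical units: M, atm, (mole fraction), m, s, m^2/s, M/atm,
# uM^-1 s^-1, mM^-1 cm^-1, AU, AU/min, uM/s, mol, L.
UNIT_TABLE: dict[str, tuple[str, float]] = {
    "M": ("concentration", 1.0),
    "mM": ("concentration", 1e-3),
    "uM": ("concentration", 1e-6),
    "nM": ("concentration", 1e-9),
    "atm": ("pressure", 1.0),
    "ppm": ("mole_fraction", 1e-6),
    "m": ("length", 1.0),
    "cm": ("length", 1e-2),
    "um": ("length", 1e-6),
    "nm": ("length", 1e-9),
    "s": ("time", 1.0),
    "ms": ("time", 1e-3),
    "min": ("time", 60.0),
    "m^2/s": ("diffusivity", 1.0),
    "M/atm": ("henry_constant", 1.0),
    "uM^-1 s^-1": ("rate_constant", 1.0),
    "mM^-1 cm^-1": ("molar_absorptivity", 1.0),
    "M^-1 cm^-1": ("molar_absorptivity", 1e-3),
    "AU": ("absorbance", 1.0),
    "AU/min": ("absorbance_rate", 1.0),
    "AU/s": ("absorbance_rate", 60.0),
    "uM/s": ("concentration_rate", 1.0),
    "mol": ("amount", 1.0),
    "L": ("volume", 1.0),
    "mL": ("volume", 1e-3),
    "uL": ("volume", 1e-6),
}

# Unicode / alternative spellings accepted on input; normalised on storage.
_ALIASES: dict[str, str] = {
    "μM": "uM",
    "µM": "uM",
    "μm": "um",
    "µm": "um",
    "μL": "uL",
    "µL": "uL",
    "μM/s": "uM/s",
    "µM/s": "uM/s",
    "m2/s": "m^2/s",
    "m²/s": "m^2/s",
    "μM^-1 s^-1": "uM^-1 s^-1",
    "uM-1 s-1": "uM^-1 s^-1",
    "μM⁻¹s⁻¹": "uM^-1 s^-1",
    "μM⁻¹·s⁻¹": "uM^-1 s^-1",
    "1/(uM s)": "uM^-1 s^-1",
    "mM-1 cm-1": "mM^-1 cm^-1",
    "mM⁻¹cm⁻¹": "mM^-1 cm^-1",
    "mM⁻¹·cm⁻¹": "mM^-1 cm^-1",
    "M-1 cm-1": "M^-1 cm^-1",
    "M⁻¹cm⁻¹": "M^-1 cm^-1",
}


def normalize_unit(unit: str) -> str:
    """Return the canonical spelling of ``unit``; raise for unknown units."""
    unit = unit.strip()
    unit = _ALIASES.get(unit, unit)
    if unit not in UNIT_TABLE:
        raise UnitError(f"unknown unit {unit!r}; known units: {sorted(UNIT_TABLE)}")
    return unit


def dimension_of(unit: str) -> str:
    """Dimension name of a unit (e.g. ``'concentration'`` for ``'nM'``)."""
    return UNIT_TABLE[normalize_unit(unit)][0]


@dataclass(frozen=True)
class Quantity:
    """A scalar physical quantity: a finite value tagged with a unit.

    Parameters
    ----------
    value
        Finite real magnitude in ``unit``.
    unit
        One of the closed unit vocabulary (unicode spellings such as
        ``"μM"`` are accepted and normalised).

    Examples
    --------
    >>> Quantity(40, "uM").to("M")
    Quantity(value=4e-05, unit='M')
    """

    value: float
    unit: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "unit", normalize_unit(self.unit))
        object.__setattr__(self, "value", float(self.value))
        if not math.isfinite(self.value):
            raise DomainError(f"quantity value must be finite, got {self.value!r}")

    @property
    def dimension(self) -> str:
        return UNIT_TABLE[self.unit][0]

    def to(self, target_unit: str) -> "Quantity":
        """Convert to a dimensionally compatible unit (exact rescaling)."""
        target_unit = normalize_unit(target_unit)
        dim_s, fac_s = UNIT_TABLE[self.unit]
        dim_t, fac_t = UNIT_TABLE[target_unit]
        if dim_s != dim_t:
            raise UnitError(
                f"cannot convert {self.unit!r} ({dim_s}) to {target_unit!r} ({dim_t})"
            )
        return Quantity(self.value * fac_s / fac_t, target_unit)

    def m_as(self, unit: str) -> float:
        """Magnitude expressed in ``unit`` (shorthand for ``.to(unit).value``)."""
        return self.to(unit).value

    def __str__(self) -> str:
        return f"{self.value:g} {self.unit}"

    def __format__(self, spec: str) -> str:
        return f"{format(self.value, spec)} {self.unit}"


def convert(q: Quantity, target_unit: str) -> Quantity:
    """Functional form of :meth:`Quantity.to`."""
    return q.to(target_unit)


def magnitude(q: Quantity, unit: str, name: str = "quantity") -> float:
    """Extract ``q`` in ``unit``, raising a :class:`UnitError` that names
    the offending argument — used by every module for argument checking."""
    if not isinstance(q, Quantity):
        raise UnitError(f"{name} must be a Quantity in {unit}, got {type(q).__name__}")
    try:
        return q.m_as(unit)
    except UnitError as exc:
        raise UnitError(f"{name}: {exc}") from None


def ppm_to_partial_pressure(mixing_ratio_ppm: float, total_pressure: Quantity) -> Quantity:
    """Partial pressure of a trace gas given its mixing ratio.

    ppm is interpreted as mole fraction × 10⁻⁶, so for an ideal gas the
    partial pressure is ``p = ppm × 1e-6 × p_total`` (Dalton's law).
    100 ppm at 1 atm total pressure gives 1.0 × 10⁻⁴ atm.
    """
    if mixing_ratio_ppm < 0:
        raise DomainError(f"mixing ratio must be >= 0 ppm, got {mixing_ratio_ppm}")
    p_tot = magnitude(total_pressure, "atm", "total_pressure")
    if p_tot <= 0:
        raise DomainError(f"total pressure must be > 0, got {total_pressure}")
    return Quantity(mixing_ratio_ppm * 1e-6 * p_tot, "atm")


_QTY_RE = re.compile(r"^\s*([+-]?[0-9.]+(?:[eE][+-]?[0-9]+)?)\s*(.+?)\s*$")


def parse_quantity(text: str | Quantity) -> Quantity:
    """Parse a string like ``"0.39 M/atm"`` or ``"2.5 um"`` into a Quantity.

    Already-constructed quantities pass through unchanged; this is the
    entry point for the unit-tagged strings used in scenario config files.
    """
    if isinstance(text, Quantity):
        return text
    if not isinstance(text, str):
        raise UnitError(
            f"expected a unit-tagged string like '0.39 M/atm', got {text!r}"
        )
    m = _QTY_RE.match(text)
    if not m:
        raise UnitError(f"cannot parse quantity from {text!r}")
    return Quantity(float(m.group(1)), m.group(2))


def round_sig(x: float, n_digits: int) -> float:
    """Round ``x`` to ``n_digits`` significant figures (0 stays 0)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + n_digits - 1)
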