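"""Minimal unit tagging for histone bookkeeping.

Quantities that are easy to confuse (molecules per embryo vs genomes worth,
per-embryo vs per-cell) carry an explicit unit string. Addition and
subtraction require matching units; crossing unit systems must go through an
explicit conversion (see :mod:`histocomp.genome`).
"""

from __future__ import annotations

from dataclasses import dataclass

#: Avogadro's number, molecules per mole.
AVOGADRO = 6.02214076e23

#: Litres per cubic micrometre.
L_PER_UM3 = 1e-15


class UnitError(TypeError):
    """Raised when quantities with incompatible units are combined."""


@dataclass(frozen=True)
class UnitValue:
    """A scalar with a unit tag.

    Supports +/- between equal units and scaling by plain numbers. Anything
    else must be converted explicitly.
    """

    value: float
    unit: str

    def _check(self, other: "UnitValue") -> None:
        if not isinstance(other, UnitValue):
            raise UnitError(
                f"cannot combine {self.unit!r} with untagged {type(other).__name__}"
            )
        if other.unit != self.unit:
            raise UnitError(f"unit mismatch: {self.unit!r} vs {other.unit!r}")

    def __add__(self, other: "UnitValue") -> "UnitValue":
        self._check(other)
        return UnitValue(self.value + other.value, self.unit)

    def __sub__(self, other: "UnitValue") -> "UnitValue":
        self._check(other)
        return UnitValue(self.value - other.value, self.unit)

    def __mul__(self, factor: float) -> "UnitValue":
        if isinstance(factor, UnitValue):
            raise UnitError("multiplying two tagged quantities is not supported")
        return UnitValue(self.value * factor, self.unit)

    __rmul__ = __mul__

    def __truediv__(self, divisor: float) -> "UnitValue":
        if isinstance(divisor, UnitValue):
            if divisor.unit != self.unit:
                raise UnitError(f"unit mismatch: {self.unit!r} vs {divisor.unit!r}")
            return self.value / divisor.value  # dimensionless
        return UnitValue(self.value / divisor, self.unit)

    def __float__(self) -> float:
        return float(self.value)


def molecules_per_um3_to_nanomolar(conc: float) -> float:
    """Convert a number density (molecules/µm³) to nanomolar.

    1 molecule/µm³ = 1/(N_A × 1e-15 L) mol/L ≈ 1.66 nM.
    """
    return conc / (AVOGADRO * L_PER_UM3) * 1e9
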