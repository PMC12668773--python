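"""Multiplicative unit algebra for kinetic models.

Units are vectors of rational exponents over five base dimensions:
amount-concentration, time, volume, mass and a dimensionless scalar.
Products and quotients of units add and subtract exponent vectors, so
units form an abelian group; two units are equal iff their exponent
vectors are equal, regardless of how they were written down.  Affine
units (degree Celsius and friends) are deliberately unsupported —
kinetic rate laws only ever need multiplicative units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Union

BASE_DIMENSIONS = ("concentration", "time", "volume", "mass")

Rational = Union[int, Fraction]


@dataclass(frozen=True)
class Unit:
    """A unit as rational exponents over the base dimensions.

    Parameters
    ----------
    exponents:
        Mapping base-dimension -> rational exponent.  Dimensions missing
        from the mapping have exponent zero; a fully empty mapping is the
        dimensionless scalar.
    display:
        Optional human-readable string ("mM/s").  Ignored for equality.
    """

    exponents: Mapping[str, Fraction] = field(default_factory=dict)
    display: str = ""

    def __post_init__(self) -> None:
        clean = {}
        for dim, exp in dict(self.exponents).items():
            if dim not in BASE_DIMENSIONS:
                raise ValueError(f"unknown base dimension {dim!r}")
            frac = Fraction(exp)
            if frac != 0:
                clean[dim] = frac
        object.__setattr__(self, "exponents", clean)

    # -- group operations -------------------------------------------------
    def __mul__(self, other: "Unit") -> "Unit":
        exps = dict(self.exponents)
        for dim, exp in other.exponents.items():
            exps[dim] = exps.get(dim, Fraction(0)) + exp
        return Unit(exps, display=_join(self.display, other.display, "*"))

    def __truediv__(self, other: "Unit") -> "Unit":
        exps = dict(self.exponents)
        for dim, exp in other.exponents.items():
            exps[dim] = exps.get(dim, Fraction(0)) - exp
        return Unit(exps, display=_join(self.display, other.display, "/"))

    def __pow__(self, power: Rational) -> "Unit":
        p = Fraction(power)
        return Unit({d: e * p for d, e in self.exponents.items()})

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Unit):
            return NotImplemented
        return dict(self.exponents) == dict(other.exponents)

    def __hash__(self) -> int:
        return hash(frozenset(self.exponents.items()))

    @property
    def is_dimensionless(self) -> bool:
        return not self.exponents

    def __str__(self) -> str:
        if self.display:
            return self.display
        if self.is_dimensionless:
            return "1"
        parts = []
        for dim in BASE_DIMENSIONS:
            if dim in self.exponents:
                exp = self.exponents[dim]
                parts.append(dim if exp == 1 else f"{dim}^{exp}")
        return "*".join(parts)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "exponents": {d: [e.numerator, e.denominator] for d, e in self.exponents.items()},
            "display": self.display,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "Unit":
        exps = {d: Fraction(n, m) for d, (n, m) in data.get("exponents", {}).items()}
        return cls(exps, display=data.get("display", ""))


def _join(a: str, b: str, op: str) -> str:
    if a and b:
        return f"({a}){op}({b})"
    return ""


# Common units for convenience.  Display strings are cosmetic only.
dimensionless = Unit({}, display="1")
mM = Unit({"concentration": 1}, display="mM")
second = Unit({"time": 1}, display="s")
minute = Unit({"time": 1}, display="min")  # same dimension as second; scale not tracked
per_second = Unit({"time": -1}, display="1/s")
mM_per_second = Unit({"concentration": 1, "time": -1}, display="mM/s")
litre = Unit({"volume": 1}, display="L")
gram = Unit({"mass": 1}, display="g")
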