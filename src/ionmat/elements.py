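"""Elemental reference data.

The twelve elements occurring in the built-in tissue compositions, each with
atomic number, relative atomic mass and a Bragg-additivity mean excitation
energy (ICRU-37 style values: gas values for H/C/N/O constituents of
compounds, solid/elemental values for the heavier elements).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Element:
    """One chemical element as used in stopping-power bookkeeping."""

    symbol: str
    z: int
    a_r: float
    i_ev: float

    def __post_init__(self) -> None:
        if self.z < 1:
            raise ValueError(f"{self.symbol}: atomic number must be >= 1")
        if self.a_r <= 0:
            raise ValueError(f"{self.symbol}: relative atomic mass must be > 0")
        if self.i_ev <= 0:
            raise ValueError(f"{self.symbol}: mean excitation energy must be > 0")

    @property
    def z_over_a(self) -> float:
        return self.z / self.a_r


_ELEMENT_LIST = [
    Element("H", 1, 1.008, 19.2),
    Element("C", 6, 12.011, 81.0),
    Element("N", 7, 14.007, 82.0),
    Element("O", 8, 15.999, 106.0),
    Element("Na", 11, 22.990, 149.0),
    Element("Mg", 12, 24.305, 156.0),
    Element("P", 15, 30.974, 173.0),
    Element("S", 16, 32.06, 180.0),
    Element("Cl", 17, 35.45, 174.0),
    Element("Ar", 18, 39.948, 188.0),
    Element("K", 19, 39.098, 190.0),
    Element("Ca", 20, 40.078, 191.0),
]

#: Built-in element table keyed by symbol.
ELEMENTS: dict[str, Element] = {e.symbol: e for e in _ELEMENT_LIST}


def get_element(symbol: str) -> Element:
    """Look up an element by symbol, raising ``KeyError`` with context."""
    try:
        return ELEMENTS[symbol]
    except KeyError:
        raise KeyError(
            f"unknown element symbol {symbol!r}; known: {sorted(ELEMENTS)}"
        ) from None
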