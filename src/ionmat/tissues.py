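"""Tissue composition library.

Holds the built-in reference-tissue elemental mass fractions (nine materials
from air to tooth) plus water, and computes the composition-level quantities
needed for stopping-power work: the electron-density factor ``sum(w_i Z_i/A_i)``
and the Bragg-rule mean excitation energy.

Water is deliberately *not* part of :func:`builtin_tissues`; it is a special
composition whose mean excitation energy is always taken from the configured
water value (default 78 eV) rather than derived by Bragg additivity — see
:mod:`ionmat.humap`.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Union

from .elements import ELEMENTS, get_element

#: Allowed deviation of the mass-fraction sum from unity.
FRACTION_SUM_TOL = 0.002

#: Reserved name of the special water composition.
WATER_NAME = "water"

FractionsLike = Union[Mapping[str, float], Iterable[tuple[str, float]]]


@dataclass(frozen=True)
class TissueComposition:
    """A named material defined by per-element mass fractions.

    ``items`` is an ordered tuple of ``(symbol, mass_fraction)`` pairs.
    Repeated symbols are permitted (their fractions simply add), which keeps
    Bragg-rule quantities manifestly additive.
    """

    name: str
    items: tuple[tuple[str, float], ...]

    def __init__(self, name: str, fractions: FractionsLike) -> None:
        pairs = tuple(fractions.items()) if isinstance(fractions, Mapping) else tuple(fractions)
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "items", tuple((s, float(w)) for s, w in pairs))
        self._validate()

    def _validate(self) -> None:
        if not self.items:
            raise ValueError(f"composition {self.name!r} is empty")
        for symbol, w in self.items:
            if symbol not in ELEMENTS:
                raise KeyError(f"composition {self.name!r}: unknown element {symbol!r}")
            if w < 0:
                raise ValueError(f"composition {self.name!r}: negative fraction for {symbol}")
        total = sum(w for _, w in self.items)
        if abs(total - 1.0) > FRACTION_SUM_TOL:
            raise ValueError(
                f"composition {self.name!r}: mass fractions sum to {total:.4f}, "
                f"expected 1 +/- {FRACTION_SUM_TOL}"
            )

    @property
    def fractions(self) -> dict[str, float]:
        """Mass fractions merged by element symbol."""
        out: dict[str, float] = {}
        for symbol, w in self.items:
            out[symbol] = out.get(symbol, 0.0) + w
        return out

    def fraction(self, symbol: str) -> float:
        return self.fractions.get(symbol, 0.0)


def z_over_a(comp: TissueComposition) -> float:
    """Return ``sum_i w_i Z_i / A_i`` for the composition."""
    return sum(w * get_element(s).z_over_a for s, w in comp.items)


def mean_excitation_energy(comp: TissueComposition, i_values: Mapping[str, float] | None = None) -> float:
    """Bragg-rule mean excitation energy in eV.

    ``ln I = sum(w Z/A ln I_i) / sum(w Z/A)`` over the composition's elements.
    ``i_values`` overrides the built-in per-element values by symbol.
    """
    num = 0.0
    den = 0.0
    for symbol, w in comp.items:
        el = get_element(symbol)
        i_ev = i_values[symbol] if i_values and symbol in i_values else el.i_ev
        if i_ev <= 0:
            raise ValueError(f"non-positive I override for {symbol}")
        num += w * el.z_over_a * math.log(i_ev)
        den += w * el.z_over_a
    if den <= 0:
        raise ValueError(f"composition {comp.name!r} has zero electron-density weight")
    return math.exp(num / den)


def water() -> TissueComposition:
    """The special water composition (H 11.19%, O 88.81% by mass)."""
    return TissueComposition(WATER_NAME, {"H": 0.1119, "O": 0.8881})


def _packaged_rows() -> list[dict[str, str]]:
    with resources.files("ionmat.data").joinpath("tissues.csv").open("r", encoding="utf-8") as fh:
        return list(csv.DictReader(fh))


def _rows_to_compositions(rows: Iterable[Mapping[str, str]]) -> list[TissueComposition]:
    comps = []
    for row in rows:
        name = row["material"]
        fractions = {
            sym: float(val)
            for sym, val in row.items()
            if sym != "material" and val not in ("", None) and float(val) != 0.0
        }
        comps.append(TissueComposition(name, fractions))
    return comps


def builtin_tissues() -> list[TissueComposition]:
    """The nine built-in reference tissues, in CT-number order (air ... tooth)."""
    return _rows_to_compositions(_packaged_rows())


def load_library(path: str | Path | None = None, include_water: bool = True) -> dict[str, TissueComposition]:
    """Load a composition library keyed by material name.

    With no ``path`` the packaged table is used. ``include_water`` adds the
    special water composition under its reserved name.
    """
    if path is None:
        comps = builtin_tissues()
    else:
        with open(path, "r", encoding="utf-8", newline="") as fh:
            comps = _rows_to_compositions(list(csv.DictReader(fh)))
    library: dict[str, TissueComposition] = {}
    for comp in comps:
        if comp.name in library:
            raise ValueError(f"duplicate material name {comp.name!r} in library")
        library[comp.name] = comp
    if include_water:
        library.setdefault(WATER_NAME, water())
    return library


def write_library(comps: Iterable[TissueComposition], path: str | Path) -> None:
    """Write compositions as CSV: one row per material, one column per element."""
    symbols = list(ELEMENTS)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["material", *symbols])
        for comp in comps:
            fr = comp.fractions
            writer.writerow([comp.name, *[repr(fr.get(s, 0.0)) for s in symbols]])
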