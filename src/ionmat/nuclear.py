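"""Material-to-water nuclear-interaction probability ratio.

Geometric nucleus-nucleus collision cross-sections (Sihver parameterisation
with an overlap parameter) combined into the ratio rho_N of a material's
nuclear-interaction probability per unit path length to that of water.
rho_N is linear in mass density but, unlike the stopping-power ratio, is
*not* reproduced by water at scaled density — that nonlinearity is the whole
reason realistic compositions matter for fragment production.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .humap import MaterialTable
from .tissues import WATER_NAME, TissueComposition

#: Representative mass number per element (single isotope; no abundance averaging).
MASS_NUMBERS: dict[str, int] = {
    "H": 1, "C": 12, "N": 14, "O": 16, "Na": 23, "Mg": 24,
    "P": 31, "S": 32, "Cl": 35, "Ar": 40, "K": 39, "Ca": 40,
}


@dataclass(frozen=True)
class NuclearConstants:
    r0_fm: float = 1.36          # effective nucleon radius
    m_rw: float = 18.015         # molecular weight of water

    def __post_init__(self) -> None:
        if self.r0_fm <= 0 or self.m_rw <= 0:
            raise ValueError("nuclear constants must be positive")


DEFAULT_NUCLEAR = NuclearConstants()


@dataclass(frozen=True)
class Projectile:
    kind: str   # "proton" | "ion"
    a: int

    def __post_init__(self) -> None:
        if self.kind not in ("proton", "ion"):
            raise ValueError(f"projectile kind must be 'proton' or 'ion', got {self.kind!r}")
        if self.a < 1:
            raise ValueError("mass number must be >= 1")
        if self.kind == "proton" and self.a != 1:
            raise ValueError("a proton projectile has A = 1")

    @classmethod
    def proton(cls) -> "Projectile":
        return cls("proton", 1)

    @classmethod
    def ion(cls, a: int) -> "Projectile":
        return cls("ion", a)

    @classmethod
    def carbon(cls) -> "Projectile":
        return cls.ion(12)

    @classmethod
    def parse(cls, spec: str) -> "Projectile":
        """Parse e.g. 'p', 'proton', 'C12', 'He4' into a projectile."""
        s = spec.strip()
        if s.lower() in ("p", "proton", "h1"):
            return cls.proton()
        digits = "".join(ch for ch in s if ch.isdigit())
        if not digits:
            raise ValueError(f"cannot parse projectile {spec!r}; expected e.g. 'C12' or 'proton'")
        return cls.ion(int(digits))


def overlap_parameter(proj: Projectile, a_target: float) -> float:
    """Overlap parameter b0 of the geometric cross-section."""
    if a_target < 1:
        raise ValueError("target mass number must be >= 1")
    if proj.kind == "proton":
        return 2.247 - 0.915 * (1.0 + a_target ** (-1.0 / 3.0))
    return 1.581 - 0.876 * (proj.a ** (-1.0 / 3.0) + a_target ** (-1.0 / 3.0))


def sigma_n(proj: Projectile, a_target: float, k: NuclearConstants = DEFAULT_NUCLEAR) -> float:
    """Geometric nucleus-nucleus collision cross-section in fm^2."""
    b0 = overlap_parameter(proj, a_target)
    bracket = (proj.a ** (1.0 / 3.0) + a_target ** (1.0 / 3.0)
               - b0 * (proj.a ** (-1.0 / 3.0) + a_target ** (-1.0 / 3.0)))
    if bracket <= 0:
        raise ValueError(
            f"non-physical geometry: bracket {bracket:.4f} <= 0 for A={proj.a}, A_t={a_target}"
        )
    return math.pi * k.r0_fm ** 2 * bracket ** 2


def water_sigma_over_a(proj: Projectile, k: NuclearConstants = DEFAULT_NUCLEAR) -> float:
    """Water's per-mass cross-section (2 sigma_H + sigma_O) / M_rw, in fm^2."""
    return (2.0 * sigma_n(proj, MASS_NUMBERS["H"], k) + sigma_n(proj, MASS_NUMBERS["O"], k)) / k.m_rw


def rho_n(
    comp: TissueComposition,
    density: float,
    proj: Projectile,
    k: NuclearConstants = DEFAULT_NUCLEAR,
) -> float:
    """Nuclear-interaction probability ratio of the material to water.

    ``rho * sum_i w_i sigma_Ni / A_ri`` divided by water's molecular form.
    The water composition itself uses the molecular denominator for its own
    numerator, so rho_n(water, rho) == rho exactly.
    """
    if density <= 0:
        raise ValueError("density must be > 0")
    denom = water_sigma_over_a(proj, k)
    if comp.name == WATER_NAME:
        return density
    num = 0.0
    for symbol, w in comp.items:
        try:
            a_t = MASS_NUMBERS[symbol]
        except KeyError:
            raise KeyError(f"no mass number known for element {symbol!r}") from None
        num += w * sigma_n(proj, a_t, k) / a_t
    return density * num / denom


def rho_n_by_hu(
    table: MaterialTable,
    proj: Projectile,
    k: NuclearConstants = DEFAULT_NUCLEAR,
) -> list[dict[str, float]]:
    """Per-bin rho_N for both assignment methods.

    For each card of the (realistic-composition) table: the realistic value at
    the solved density, and the varying-density-water value at density = SPR.
    Returns rows of {hu, spr, rho_n_our, rho_n_water}.
    """
    if table.method != "our":
        raise ValueError("rho_n_by_hu needs a realistic-composition ('our') table")
    rows = []
    for card in table.cards:
        comp = table.library[card.tissue]
        our = rho_n(comp, card.density, proj, k)
        rows.append({
            "hu": card.representative_hu,
            "spr": card.spr,
            "rho_n_our": our,
            "rho_n_water": card.spr,  # water method: density = SPR, ratio = density
        })
    return rows
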