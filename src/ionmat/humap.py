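"""CT-number to material-card mapping.

The central idea: instead of fitting mass density against CT number from a
scanner calibration, take the HU-to-stopping-power-ratio (SPR) curve already
registered in the treatment planning system, assign a reference-tissue
composition per HU interval, and *solve* each bin's mass density so that the
material reproduces the curve's SPR exactly under a fixed-velocity
Bethe-Bloch ratio:

    SPR = [rho_m * sum(w Z/A) * (ln(mec2/I_m) - 1/3)]
          / [rho_w * (Z/A)_w * (ln(mec2/I_w) - 1/3)]

The density solve is the closed-form inverse of that ratio.  The
"varying-density-water" alternative keeps the water composition everywhere
and sets density = SPR, which preserves range but not nuclear interactions.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Union

import numpy as np

from .tissues import (
    WATER_NAME,
    TissueComposition,
    load_library,
    mean_excitation_energy,
    water,
    z_over_a,
)

HU_MIN = -1000.0
HU_MAX = 2000.0


@dataclass(frozen=True)
class PhysicsConstants:
    """Constants of the stopping-power ratio model.

    ``velocity_factor`` is the constant subtracted from the logarithm; the
    default 1/3 corresponds to a fixed incident-carbon velocity of 0.557c.
    """

    mec2_ev: float = 510_998.95
    i_water_ev: float = 78.0
    velocity_factor: float = 1.0 / 3.0
    rho_water: float = 1.0

    def __post_init__(self) -> None:
        if min(self.mec2_ev, self.i_water_ev, self.rho_water) <= 0:
            raise ValueError("physics constants must be strictly positive")
        if self.velocity_factor >= math.log(self.mec2_ev / self.i_water_ev):
            raise ValueError("velocity factor exceeds the stopping logarithm for water")


DEFAULT_CONSTANTS = PhysicsConstants()


def _stopping_number(i_ev: float, k: PhysicsConstants) -> float:
    if i_ev >= k.mec2_ev:
        raise ValueError(f"mean excitation energy {i_ev} eV >= electron rest energy")
    val = math.log(k.mec2_ev / i_ev) - k.velocity_factor
    if val <= 0:
        raise ValueError(f"non-positive stopping number for I = {i_ev} eV")
    return val


def material_i_ev(
    comp: TissueComposition,
    k: PhysicsConstants = DEFAULT_CONSTANTS,
    i_values: Mapping[str, float] | None = None,
) -> float:
    """Mean excitation energy used in the SPR model.

    Water is special-cased: its I is always the configured water value,
    never Bragg-rule derived.
    """
    if comp.name == WATER_NAME:
        return k.i_water_ev
    return mean_excitation_energy(comp, i_values)


def spr_from_material(
    comp: TissueComposition,
    density: float,
    k: PhysicsConstants = DEFAULT_CONSTANTS,
    i_values: Mapping[str, float] | None = None,
) -> float:
    """Stopping-power ratio to water of ``comp`` at mass density ``density``."""
    if density <= 0:
        raise ValueError("density must be > 0")
    i_m = material_i_ev(comp, k, i_values)
    num = density * z_over_a(comp) * _stopping_number(i_m, k)
    den = k.rho_water * z_over_a(water()) * _stopping_number(k.i_water_ev, k)
    return num / den


def density_from_spr(
    comp: TissueComposition,
    spr: float,
    k: PhysicsConstants = DEFAULT_CONSTANTS,
    i_values: Mapping[str, float] | None = None,
) -> float:
    """Mass density (g/cm^3) at which ``comp`` has the given SPR.

    Exact algebraic inverse of :func:`spr_from_material` (the ratio is linear
    in density), so the round trip is exact to machine precision.
    """
    if spr <= 0:
        raise ValueError("spr must be > 0")
    return spr / spr_from_material(comp, 1.0, k, i_values)


def water_density_from_spr(spr: float, k: PhysicsConstants = DEFAULT_CONSTANTS) -> float:
    """Density assigned by the varying-density-water method: SPR * rho_water."""
    if spr <= 0:
        raise ValueError("spr must be > 0")
    return spr * k.rho_water


class HuSprCurve:
    """Piecewise-linear HU -> SPR calibration curve.

    Evaluation clamps to the end values outside the breakpoint range.
    """

    def __init__(self, breakpoints: Iterable[tuple[float, float]]) -> None:
        pts = sorted((float(h), float(s)) for h, s in breakpoints)
        if not pts:
            raise ValueError("curve needs at least one breakpoint")
        hu = np.array([p[0] for p in pts])
        spr = np.array([p[1] for p in pts])
        if np.any(np.diff(hu) <= 0):
            raise ValueError("curve HU breakpoints must be strictly increasing")
        if np.any(spr <= 0):
            raise ValueError("curve SPR values must be > 0")
        self.hu = hu
        self.spr = spr

    def __call__(self, hu: float | np.ndarray) -> float | np.ndarray:
        out = np.interp(hu, self.hu, self.spr)
        return float(out) if np.isscalar(hu) or np.ndim(hu) == 0 else out

    @property
    def breakpoints(self) -> list[tuple[float, float]]:
        return list(zip(self.hu.tolist(), self.spr.tolist()))

    @classmethod
    def from_csv(cls, path: str | Path) -> "HuSprCurve":
        with open(path, "r", encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {"hu", "spr"} <= set(reader.fieldnames):
                raise ValueError(f"{path}: expected CSV header with columns 'hu,spr'")
            return cls((float(r["hu"]), float(r["spr"])) for r in reader)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["hu", "spr"])
            for h, s in self.breakpoints:
                writer.writerow([repr(h), repr(s)])


#: The eight printed (HU, SPR) anchor points of the reference TPS calibration.
TPS_ANCHORS: tuple[tuple[float, float], ...] = (
    (-325.0, 0.70),
    (-105.0, 0.95),
    (-5.0, 1.01),
    (45.0, 1.04),
    (175.0, 1.10),
    (265.0, 1.13),
    (715.0, 1.31),
    (1585.0, 1.66),
)


def fixture_curve() -> HuSprCurve:
    """Stand-in TPS calibration curve.

    Piecewise linear through the eight printed anchors, extended to
    (-1000, 0.001) below and to (2000, 1.827) above (linear continuation of
    the last printed segment), so clamping is never exercised on the default
    HU domain.
    """
    return HuSprCurve([(-1000.0, 0.001), *TPS_ANCHORS, (2000.0, 1.827)])


class HuAllocationScheme:
    """Ordered half-open HU intervals, each mapped to a tissue name.

    The intervals must exactly partition [-1000, 2000]; the topmost interval
    is closed at 2000.
    """

    def __init__(self, intervals: Iterable[tuple[float, float, str]]) -> None:
        ivs = sorted((float(lo), float(hi), str(t)) for lo, hi, t in intervals)
        if not ivs:
            raise ValueError("allocation scheme is empty")
        if ivs[0][0] != HU_MIN or ivs[-1][1] != HU_MAX:
            raise ValueError(f"scheme must span [{HU_MIN}, {HU_MAX}]")
        for (lo, hi, _), (lo2, _, _) in zip(ivs, ivs[1:]):
            if hi != lo2:
                raise ValueError(f"scheme has a gap/overlap at HU {hi} vs {lo2}")
        for lo, hi, _ in ivs:
            if hi <= lo:
                raise ValueError(f"empty interval [{lo}, {hi})")
        self.intervals = ivs

    def assign(self, hu: float) -> str:
        if not (HU_MIN <= hu <= HU_MAX):
            raise ValueError(f"HU {hu} outside [{HU_MIN}, {HU_MAX}]")
        if hu == HU_MAX:
            return self.intervals[-1][2]
        for lo, hi, tissue in self.intervals:
            if lo <= hu < hi:
                return tissue
        raise AssertionError("unreachable: scheme partitions the domain")

    def tissue_names(self) -> list[str]:
        return [t for _, _, t in self.intervals]

    @classmethod
    def from_records(cls, records: Iterable[Mapping[str, object]]) -> "HuAllocationScheme":
        return cls((float(r["lo"]), float(r["hi"]), str(r["tissue"])) for r in records)

    def to_records(self) -> list[dict[str, object]]:
        return [{"lo": lo, "hi": hi, "tissue": t} for lo, hi, t in self.intervals]


def default_scheme() -> HuAllocationScheme:
    """Default HU-interval to tissue allocation.

    Boundaries chosen so each tissue's representative HU (the TPS anchor)
    falls inside its own interval and fat+adipose together cover [-150, 10).
    """
    return HuAllocationScheme([
        (-1000.0, -950.0, "air"),
        (-950.0, -150.0, "lung"),
        (-150.0, -50.0, "fat"),
        (-50.0, 10.0, "adipose"),
        (10.0, 120.0, "soft tissue"),
        (120.0, 220.0, "muscle"),
        (220.0, 450.0, "bone-scapula"),
        (450.0, 1100.0, "bone-mineral"),
        (1100.0, 2000.0, "tooth"),
    ])


def assign_tissue(hu: float, scheme: HuAllocationScheme | None = None) -> str:
    """Tissue name for a CT number under the (default) allocation scheme."""
    return (scheme or default_scheme()).assign(hu)


@dataclass(frozen=True)
class MaterialCard:
    """One HU bin of the material table."""

    lo: float
    hi: float
    representative_hu: float
    tissue: str
    spr: float
    density: float

    def __post_init__(self) -> None:
        if self.spr <= 0 or self.density <= 0:
            raise ValueError("material card needs positive SPR and density")


@dataclass
class MaterialTable:
    """Uniform-step binned material cards covering the HU domain."""

    cards: list[MaterialCard]
    method: str = "our"
    library: dict[str, TissueComposition] = field(default_factory=load_library, repr=False)

    @property
    def lo(self) -> float:
        return self.cards[0].lo

    @property
    def hi(self) -> float:
        return self.cards[-1].hi

    @property
    def step(self) -> float:
        return self.cards[0].hi - self.cards[0].lo

    def card_for_hu(self, hu: float) -> MaterialCard:
        if not (self.lo <= hu <= self.hi):
            raise ValueError(f"HU {hu} outside table domain [{self.lo}, {self.hi}]")
        idx = min(int((hu - self.lo) // self.step), len(self.cards) - 1)
        return self.cards[idx]

    def composition_for(self, card: MaterialCard) -> TissueComposition:
        if self.method == "water":
            return water()
        return self.library[card.tissue]

    def __len__(self) -> int:
        return len(self.cards)

    def __iter__(self):
        return iter(self.cards)


def build_material_table(
    curve: HuSprCurve,
    scheme: HuAllocationScheme | None = None,
    library: dict[str, TissueComposition] | None = None,
    step: float = 10.0,
    lo: float = HU_MIN,
    hi: float = HU_MAX,
    method: str = "our",
    constants: PhysicsConstants = DEFAULT_CONSTANTS,
) -> MaterialTable:
    """Build the binned material table over [lo, hi] in uniform HU steps.

    Each bin's representative HU is its center; the tissue comes from the
    allocation scheme, the SPR from the calibration curve, and the density
    from the closed-form solve (or density = SPR for ``method="water"``).
    """
    if method in ("varying-density-water", "varying_density_water"):
        method = "water"
    if method not in ("our", "water"):
        raise ValueError(f"unknown method {method!r}")
    scheme = scheme or default_scheme()
    library = library or load_library()
    n_bins = (hi - lo) / step
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError(f"(hi - lo) = {hi - lo} not divisible by step {step}")
    n_bins = int(round(n_bins))
    missing = [t for t in scheme.tissue_names() if t not in library]
    if missing:
        raise KeyError(f"scheme tissues missing from library: {missing}")

    cards = []
    for i in range(n_bins):
        b_lo = lo + i * step
        b_hi = b_lo + step
        center = 0.5 * (b_lo + b_hi)
        spr = float(curve(center))
        tissue = scheme.assign(center)
        if method == "water":
            density = water_density_from_spr(spr, constants)
        else:
            density = density_from_spr(library[tissue], spr, constants)
        cards.append(MaterialCard(b_lo, b_hi, center, tissue, spr, density))
    return MaterialTable(cards, method=method, library=library)


_CSV_COLUMNS = ["lo", "hi", "representative_hu", "tissue", "spr", "density"]


def write_material_table(table: MaterialTable, path: str | Path, format: str = "csv") -> None:
    """Serialize a material table as CSV or as PHITS-style material cards."""
    if format == "csv":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(_CSV_COLUMNS + ["method"])
            for c in table.cards:
                writer.writerow([repr(c.lo), repr(c.hi), repr(c.representative_hu),
                                 c.tissue, repr(c.spr), repr(c.density), table.method])
    elif format in ("phits-card", "phits"):
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("[ Material ]\n")
            for i, c in enumerate(table.cards, start=1):
                comp = table.composition_for(c)
                fh.write(f"$ bin {i}: HU [{c.lo:g}, {c.hi:g})  {comp.name}"
                         f"  SPR {c.spr:.6f}  rho {c.density:.6f} g/cm3\n")
                fh.write(f"MAT[{i}]\n")
                for symbol, w in sorted(comp.fractions.items()):
                    if w > 0:
                        fh.write(f"    {symbol:<2s} {-w:.6f}\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_material_table(path: str | Path) -> MaterialTable:
    """Read a CSV material table written by :func:`write_material_table`."""
    cards = []
    method = "our"
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            method = row.get("method", method)
            cards.append(MaterialCard(
                float(row["lo"]), float(row["hi"]), float(row["representative_hu"]),
                row["tissue"], float(row["spr"]), float(row["density"]),
            ))
    if not cards:
        raise ValueError(f"{path}: empty material table")
    return MaterialTable(cards, method=method)
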