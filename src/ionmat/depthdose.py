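"""Depth-dose validation harness.

1-D layered phantoms, a synthetic spread-out-Bragg-peak (SOBP) reference
curve, water-equivalent-path-length (WEPL) range scaling of the reference
through a phantom, range metrics (peak position, distal 50% depth), a 1-D
gamma analysis, and the per-event dose-to-medium to dose-to-water conversion.

No particle transport is performed here: depth-dose curves are produced by
stretching/compressing the water reference along WEPL, the same mechanism a
pencil-beam engine uses, which is sufficient to exercise range metrics,
density-binning error and gamma comparisons.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence, Union

import numpy as np

from .humap import DEFAULT_CONSTANTS, MaterialTable, PhysicsConstants, material_i_ev
from .tissues import TissueComposition, water, z_over_a

#: Nucleon rest energy used to derive beta from kinetic energy per nucleon.
AMU_MEV = 931.494


class DepthDoseCurve:
    """Dose versus depth on a uniform grid (depth in mm, dose dimensionless)."""

    def __init__(self, depth_mm: np.ndarray, dose: np.ndarray) -> None:
        depth_mm = np.asarray(depth_mm, dtype=float)
        dose = np.asarray(dose, dtype=float)
        if depth_mm.ndim != 1 or depth_mm.size < 2 or depth_mm.shape != dose.shape:
            raise ValueError("curve needs matching 1-D depth and dose arrays (>= 2 points)")
        steps = np.diff(depth_mm)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ValueError("depth grid must be uniform and increasing")
        if np.any(dose < 0):
            raise ValueError("doses must be >= 0")
        self.depth_mm = depth_mm
        self.dose = dose

    @property
    def step_mm(self) -> float:
        return float(self.depth_mm[1] - self.depth_mm[0])

    def normalized(self) -> "DepthDoseCurve":
        """Entrance-normalized copy (first grid point's dose becomes 1)."""
        if self.dose[0] <= 0:
            raise ValueError("cannot normalize: zero entrance dose")
        return DepthDoseCurve(self.depth_mm, self.dose / self.dose[0])

    def __len__(self) -> int:
        return self.depth_mm.size

    @classmethod
    def from_csv(cls, path: str | Path) -> "DepthDoseCurve":
        with open(path, "r", encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {"depth_mm", "dose"} <= set(reader.fieldnames):
                raise ValueError(f"{path}: expected CSV header with columns 'depth_mm,dose'")
            rows = [(float(r["depth_mm"]), float(r["dose"])) for r in reader]
        return cls(np.array([r[0] for r in rows]), np.array([r[1] for r in rows]))

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["depth_mm", "dose"])
            for z, d in zip(self.depth_mm, self.dose):
                writer.writerow([repr(float(z)), repr(float(d))])


@dataclass(frozen=True)
class Slab:
    thickness_cm: float
    hu: float

    def __post_init__(self) -> None:
        if self.thickness_cm <= 0:
            raise ValueError("slab thickness must be > 0")


class Phantom1D:
    """Ordered slabs of (thickness, HU) along the beam axis."""

    def __init__(self, slabs: Iterable[Slab | tuple[float, float]], length_cm: float | None = None) -> None:
        self.slabs = [s if isinstance(s, Slab) else Slab(*s) for s in slabs]
        if not self.slabs:
            raise ValueError("phantom needs at least one slab")
        total = sum(s.thickness_cm for s in self.slabs)
        if length_cm is not None and abs(total - length_cm) > 1e-9:
            raise ValueError(f"slabs sum to {total} cm, declared length is {length_cm} cm")
        self.length_cm = total

    def boundaries_mm(self) -> np.ndarray:
        """Cumulative slab boundary depths in mm, starting at 0."""
        t = np.array([s.thickness_cm for s in self.slabs]) * 10.0
        return np.concatenate([[0.0], np.cumsum(t)])


def build_phantom(spec: str | Sequence[tuple[float, float]], hu: float | None = None,
                  length_cm: float = 40.0) -> Phantom1D:
    """Build a phantom from a preset name or an explicit slab list.

    Presets: ``"homogeneous"`` (one ``length_cm`` slab at ``hu``) and
    ``"heterogeneous"`` (water with a 2 cm HU-715 slab at 5 cm and
    a 15 cm HU=-325 slab at 10 cm depth, 40 cm total).
    """
    if isinstance(spec, str):
        if spec == "homogeneous":
            if hu is None:
                raise ValueError("homogeneous preset needs an HU value")
            return Phantom1D([Slab(length_cm, hu)], length_cm)
        if spec in ("heterogeneous", "fig3"):
            return Phantom1D(
                [Slab(5.0, 0.0), Slab(2.0, 715.0), Slab(3.0, 0.0),
                 Slab(15.0, -325.0), Slab(15.0, 0.0)],
                40.0,
            )
        raise ValueError(f"unknown phantom preset {spec!r}")
    return Phantom1D([Slab(t, h) for t, h in spec], length_cm)


def generate_sobp_reference(
    range_cm: float = 27.0,
    sobp_width_cm: float = 8.0,
    step_mm: float = 0.1,
    depth_cm: float = 40.0,
    plateau_level: float = 3.0,
    falloff_mm: float | None = None,
    tail_level: float = 0.15,
) -> DepthDoseCurve:
    """Deterministic synthetic SOBP depth-dose curve in water.

    Entrance dose 1, cubic ramp up to a flat plateau of ``plateau_level``
    spanning [range - width, range], a linear distal falloff starting at
    ``range_cm`` and reaching the fragment tail within ``falloff_mm``
    (default: one grid step, which pins the distal 50% depth within one grid
    step of the nominal range), then a slowly decaying tail.
    """
    if not (0 < sobp_width_cm < range_cm):
        raise ValueError("need 0 < sobp width < range")
    if step_mm <= 0 or depth_cm * 10.0 <= range_cm * 10.0:
        raise ValueError("invalid grid geometry")
    r = range_cm * 10.0
    w = sobp_width_cm * 10.0
    p = plateau_level
    t = tail_level
    fw = step_mm if falloff_mm is None else falloff_mm
    z = np.arange(0.0, depth_cm * 10.0 + 0.5 * step_mm, step_mm)

    dose = np.empty_like(z)
    ramp_end = r - w
    # proximal ramp: 1 at the surface rising to the plateau level
    sel = z < ramp_end
    dose[sel] = 1.0 + (p - 1.0) * (z[sel] / ramp_end) ** 3
    # flat plateau up to and including the nominal range
    sel = (z >= ramp_end) & (z <= r)
    dose[sel] = p
    # steep linear falloff from (r, p) to (r + fw, t)
    sel = (z > r) & (z < r + fw)
    dose[sel] = p + (t - p) * (z[sel] - r) / fw
    # fragment tail decaying over ~10 cm
    sel = z >= r + fw
    dose[sel] = t * np.exp(-(z[sel] - (r + fw)) / 100.0)
    return DepthDoseCurve(z, dose).normalized()


SprLookup = Union[MaterialTable, Callable[[float], float]]


def _spr_of(table: SprLookup) -> Callable[[float], float]:
    if callable(table):
        return table
    return lambda hu: table.card_for_hu(hu).spr


def wepl_map(phantom: Phantom1D, table: SprLookup, reference: DepthDoseCurve) -> DepthDoseCurve:
    """Map the water reference curve through a phantom by WEPL range scaling.

    dose(z) = reference(WEPL(z)) with WEPL(z) the cumulative SPR-weighted
    depth.  Beyond the reference's last depth the dose is held constant,
    mirroring the registered-profile behaviour of a planning system.
    ``table`` may be a material table (binned SPR lookup per slab HU) or any
    callable HU -> SPR.
    """
    spr_of = _spr_of(table)
    bounds = phantom.boundaries_mm()
    sprs = np.array([float(spr_of(s.hu)) for s in phantom.slabs])
    wepl_nodes = np.concatenate([[0.0], np.cumsum(np.diff(bounds) * sprs)])
    z = np.arange(0.0, phantom.length_cm * 10.0 + 0.5 * reference.step_mm, reference.step_mm)
    wepl = np.interp(z, bounds, wepl_nodes)
    dose = np.interp(wepl, reference.depth_mm, reference.dose,
                     left=reference.dose[0], right=reference.dose[-1])
    return DepthDoseCurve(z, dose)


def peak_position(curve: DepthDoseCurve) -> float:
    """Depth of the global dose maximum; ties break to the shallowest depth."""
    if np.all(curve.dose == 0):
        raise ValueError("all-zero curve has no peak")
    return float(curve.depth_mm[int(np.argmax(curve.dose))])


def d50_position(curve: DepthDoseCurve) -> float:
    """Distal depth at which the dose falls to 50% of the curve maximum.

    The crossing is linearly interpolated between grid points; the *last*
    downward crossing is used (the distal falloff edge).
    """
    dmax = float(np.max(curve.dose))
    if dmax <= 0:
        raise ValueError("all-zero curve has no d50")
    thr = 0.5 * dmax
    above = curve.dose >= thr
    crossings = np.nonzero(above[:-1] & ~above[1:])[0]
    if crossings.size == 0:
        raise ValueError("curve has no distal 50% crossing")
    i = int(crossings[-1])
    z0, z1 = curve.depth_mm[i], curve.depth_mm[i + 1]
    d0, d1 = curve.dose[i], curve.dose[i + 1]
    return float(z0 + (thr - d0) / (d1 - d0) * (z1 - z0))


def delta_metrics(eval_curve: DepthDoseCurve, ref_curve: DepthDoseCurve) -> tuple[float, float]:
    """Signed (delta_peak, delta_d50) in mm, evaluated curve minus reference."""
    return (
        peak_position(eval_curve) - peak_position(ref_curve),
        d50_position(eval_curve) - d50_position(ref_curve),
    )


def gamma_index_1d(
    eval_curve: DepthDoseCurve,
    ref_curve: DepthDoseCurve,
    dta_mm: float = 1.0,
    dose_pct: float = 3.0,
    low_dose_cutoff_pct: float = 10.0,
    window_factor: float = 3.0,
) -> tuple[np.ndarray, float]:
    """1-D gamma index with global dose normalization.

    For each evaluated point, gamma is the minimum over reference samples of
    sqrt((dz/DTA)^2 + (dD/tol)^2) with tol = ``dose_pct`` percent of the
    reference curve's global maximum.  The candidate search starts in a
    window of ``window_factor * DTA`` around the point and expands until the
    window provably contains the global minimum, so results are identical to
    an exhaustive scan.  Points where the reference dose (interpolated at the
    evaluated depth) is below the cutoff are excluded from the passing-rate
    denominator.  Returns (gamma array, passing rate in percent).
    """
    if dta_mm <= 0 or dose_pct <= 0:
        raise ValueError("tolerances must be positive")
    ref_z, ref_d = ref_curve.depth_mm, ref_curve.dose
    ev_z, ev_d = eval_curve.depth_mm, eval_curve.dose
    dose_tol = dose_pct / 100.0 * float(np.max(ref_d))
    if dose_tol <= 0:
        raise ValueError("reference curve has no positive dose")

    gamma = np.empty(ev_z.size)
    span = float(ref_z[-1] - ref_z[0])
    for j, (z, d) in enumerate(zip(ev_z, ev_d)):
        radius = window_factor * dta_mm
        while True:
            lo = np.searchsorted(ref_z, z - radius, side="left")
            hi = np.searchsorted(ref_z, z + radius, side="right")
            sel_z = ref_z[lo:hi]
            sel_d = ref_d[lo:hi]
            if sel_z.size:
                g2 = ((sel_z - z) / dta_mm) ** 2 + ((sel_d - d) / dose_tol) ** 2
                best = math.sqrt(float(np.min(g2)))
            else:
                best = math.inf
            # candidates outside the window have gamma >= radius/dta
            if best <= radius / dta_mm or radius >= span + abs(z - ref_z[0]) + abs(ref_z[-1] - z):
                break
            radius *= 2.0
        gamma[j] = best

    ref_at_eval = np.interp(ev_z, ref_z, ref_d, left=ref_d[0], right=ref_d[-1])
    considered = ref_at_eval >= low_dose_cutoff_pct / 100.0 * float(np.max(ref_d))
    if not np.any(considered):
        raise ValueError("no evaluated points above the low-dose cutoff")
    passing = float(np.count_nonzero(gamma[considered] <= 1.0)) / np.count_nonzero(considered)
    return gamma, 100.0 * passing


@dataclass(frozen=True)
class DepositionEvent:
    """One energy-deposition event of a charged particle in a tally bin."""

    z: int
    a: int
    energy_mev_per_u: float
    edep_mev: float
    bin_index: int = 0

    def __post_init__(self) -> None:
        if self.energy_mev_per_u <= 0 or self.edep_mev <= 0:
            raise ValueError("event energies must be > 0")


@dataclass(frozen=True)
class DoseTally:
    """One scoring bin: volume, medium composition and density."""

    volume_cm3: float
    composition: TissueComposition
    density: float

    def __post_init__(self) -> None:
        if self.volume_cm3 <= 0 or self.density <= 0:
            raise ValueError("tally volume and density must be > 0")


def _beta_squared(energy_mev_per_u: float) -> float:
    gamma_rel = 1.0 + energy_mev_per_u / AMU_MEV
    return 1.0 - 1.0 / gamma_rel ** 2


def stopping_ratio_w_over_m(
    comp: TissueComposition,
    density: float,
    energy_mev_per_u: float,
    k: PhysicsConstants = DEFAULT_CONSTANTS,
) -> float:
    """Ratio of linear stopping powers water/medium at the event's velocity.

    Bethe form without corrections: linear stopping power proportional to
    rho * sum(w Z/A) * [ln(2 me c^2 beta^2 gamma^2 / I) - beta^2], with the
    medium's I from Bragg's rule (water forced to the configured value).
    """
    b2 = _beta_squared(energy_mev_per_u)
    if b2 >= 1.0:
        raise ValueError("beta >= 1")
    g2 = 1.0 / (1.0 - b2)
    arg = 2.0 * k.mec2_ev * b2 * g2

    def ell(i_ev: float) -> float:
        val = math.log(arg / i_ev) - b2
        if val <= 0:
            raise ValueError(f"non-positive stopping number at E={energy_mev_per_u} MeV/u, I={i_ev} eV")
        return val

    i_m = material_i_ev(comp, k)
    wat = water()
    num = k.rho_water * z_over_a(wat) * ell(k.i_water_ev)
    den = density * z_over_a(comp) * ell(i_m)
    return num / den


def dose_to_medium(events: Iterable[DepositionEvent], tally: DoseTally) -> float:
    """Plain dose to medium: total deposited energy over tally mass (MeV/g)."""
    total = sum(e.edep_mev for e in events)
    return total / (tally.volume_cm3 * tally.density)


def dose_to_water(
    events: Iterable[DepositionEvent],
    tally: DoseTally,
    k: PhysicsConstants = DEFAULT_CONSTANTS,
) -> float:
    """Convert event-wise dose to medium into dose to water (MeV/g).

    D_w = 1/(V rho_m) * sum_i (rho_m/rho_w) eps_i (dE/dx)_w/(dE/dx)_m, with
    the linear-stopping-power ratio evaluated per event at the event's
    particle energy.  Identity whenever the medium's composition is water,
    at any density.
    """
    rho_m = tally.density
    total = 0.0
    for e in events:
        ratio = stopping_ratio_w_over_m(tally.composition, rho_m, e.energy_mev_per_u, k)
        total += (rho_m / k.rho_water) * e.edep_mev * ratio
    return total / (tally.volume_cm3 * rho_m)


def read_events_csv(path: str | Path) -> list[DepositionEvent]:
    """Read an event list CSV with columns Z, A, E_MeV_per_u, edep_MeV, bin."""
    events = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            events.append(DepositionEvent(
                int(row["Z"]), int(row["A"]), float(row["E_MeV_per_u"]),
                float(row["edep_MeV"]), int(row.get("bin", 0)),
            ))
    return events
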