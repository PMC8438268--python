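# ionmat

CT-number → material assignment for ion-beam Monte Carlo dose reconstruction.

Instead of fitting mass density against CT number from a scanner calibration,
`ionmat` takes the HU→stopping-power-ratio (SPR) curve already registered in a
treatment planning system, assigns a reference-tissue elemental composition
per HU interval, and **solves each 10-HU bin's mass density in closed form**
so that the material reproduces the curve's SPR under a fixed-velocity
Bethe–Bloch ratio with Bragg-rule mean excitation energies. The resulting
material cards (composition + density per HU bin) are what a Monte Carlo
transport engine needs, while the incident-ion range stays consistent with
the planning system by construction.

The package also provides the companion computations used to validate such a
material map:

- **`ionmat.tissues`** — built-in reference-tissue compositions (air, lung,
  fat, adipose, soft tissue, muscle, bone-scapula, bone-mineral, tooth),
  `sum(w·Z/A)` and Bragg-rule mean excitation energies.
- **`ionmat.humap`** — HU–SPR curve handling, HU-interval tissue allocation,
  the density solve and its varying-density-water alternative
  (water composition everywhere, density = SPR), binned material-table
  generation and CSV / PHITS-style card export.
- **`ionmat.nuclear`** — geometric nucleus–nucleus cross-sections (overlap
  parameter form) and the material-to-water nuclear-interaction probability
  ratio ρ_N, which is *not* preserved by the varying-density-water method.
- **`ionmat.depthdose`** — 1-D layered phantoms, a synthetic spread-out
  Bragg peak reference, WEPL range scaling through a phantom, peak/distal-50%
  range metrics, a 1-D gamma analysis (1 mm / 3 % by default) and the
  per-event dose-to-medium → dose-to-water conversion.

## CLI

```sh
ionmat fixtures --out fixtures/            # write default curve/tissues/scheme/phantom/SOBP
ionmat build-table --out table.csv         # 300-bin material table (10 HU steps)
ionmat build-table --method water --out w.csv
ionmat build-table --format phits-card --out cards.txt
ionmat assign --hu 715                     # -> bone-mineral
ionmat density --tissue tooth --spr 1.66   # closed-form density solve
ionmat rhon --out rhon.csv                 # rho_N vs HU for both methods
ionmat sobp --range 27 --width 8 --out ref.csv
ionmat depthdose --preset heterogeneous --reference ref.csv --out mapped.csv
ionmat metrics --ref ref.csv --eval mapped.csv
ionmat gamma --ref ref.csv --eval mapped.csv --dta 1 --dd 3
ionmat validate --preset heterogeneous --out report/
```

All commands are deterministic; `--config FILE` supplies YAML overrides for
the physics constants (electron rest energy, water I-value, velocity factor,
water density).

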