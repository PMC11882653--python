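# lichenphys

Analysis pipeline for hydration-resolved lichen CO₂ gas-exchange
measurements. Given a drying run — an ordered series of light-response
curves measured while a thallus dries, with the thallus weighed between
curves — the package extracts the per-sample core parameters that
describe a species' water relations, light economics and carbon
acquisition, and links them to an ordinal rank of habitat association:

* **Water relations** — MinWC, MaxWC (lowest/highest water content at
  which net photosynthesis stays above 90% of its maximum) and their
  width OptWC, in both % of dry mass and mm precipitation equivalent
  (1 mm ≡ 100 mg H₂O cm⁻²).
* **Light economics** — light compensation point (LCP, PPFD where net
  photosynthesis crosses zero) and light saturation point (LSP, lowest
  PPFD reaching 90% of the curve maximum), both by linear interpolation
  between measured steps.
* **Carbon acquisition** — MaxNP, maximum dark respiration, carbon gain
  efficiency (CGE = MaxNP / |DR|), and optional chlorophyll content from
  DMSO-extract absorbances.
* **Morphometrics** — specific thallus mass (STM, mg cm⁻²) and water
  holding capacity (WHC, mm).

A calibrated simulator (`lichenphys.synthetic`) reproduces the
measurement protocol — the 0…1500 µmol m⁻² s⁻¹ PPFD staircase repeated
along a drying trajectory, with Gaussian measurement noise — so every
stage of the pipeline is testable against known ground truth without
any external data. The statistics module provides the study-design
inference: Shapiro–Wilk normality screening with transform fallback,
one-way ANOVA, Tukey post-hoc tests with a compact letter display, and
a maximum-likelihood proportional-odds ordinal regression. A small
realized-niche module cleans occurrence records, joins gridded climate
values and summarizes per-species precipitation breadth.

Note on units: the source material prints net photosynthesis as
"nmol g⁻²DM s⁻¹"; a squared mass unit is dimensionally anomalous and is
read throughout this package as per gram dry mass (nmol g⁻¹DM s⁻¹).
Likewise chlorophyll content is treated as µg per mg dry mass.

## Command line

```bash
# simulate the calibrated 7-species × 3-replicate panel
lichenphys simulate --seed 1 --out-gas gas.csv --out-samples samples.csv --out-ranks ranks.csv

# extract per-sample core parameters (threshold, smoothing and mass
# convention are flags; defaults: 0.9, no smoothing, midpoint masses)
lichenphys extract --gas gas.csv --samples samples.csv --out core.tsv

# species ANOVA + Tukey letters and the ordinal habitat-association scan
lichenphys stats --core core.tsv --ranks ranks.csv --out stats.json

# occurrence cleaning, climate join and niche-breadth summaries
lichenphys niche --occurrences occ.csv --climate cells.csv --ranks ranks.csv --out breadth.tsv

# or end-to-end from a YAML config
lichenphys run --config config.yaml --outdir out/
```

Input formats are plain CSV/TSV (UTF-8, "." decimal): a long gas-exchange
table with one row per (sample, curve, PPFD step) and columns
`sample_id, curve_index, ppfd, assim, mass_before_mg, mass_after_mg`; a
sample table with `sample_id, species_code, site, dry_mass_mg, area_cm2,
full_wet_mass_mg`; a rank table with `species_code, rank`. Masses are mg,
areas cm², PPFD µmol photons m⁻² s⁻¹, assimilation nmol g⁻¹DM s⁻¹
(positive = net photosynthesis); no unit autodetection is performed.

## Layout

```
src/lichenphys/
  datamodel.py       domain types + validation
  io.py              CSV/TSV readers and writers
  synthetic.py       protocol simulator, ground truth, species calibration
  curve_features.py  core-parameter extraction (the central computation)
  pigments.py        chlorophyll from DMSO-extract absorbances
  stats.py           ANOVA, Tukey CLD, Pearson, proportional odds
  niche.py           occurrence cleaning, climate join, niche breadth
  cli.py             click-based pipeline commands
tests/               pytest suite; test_acceptance.py holds the binding criteria
scripts/acceptance.py
```
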