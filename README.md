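# isopixel

Dual stable-isotope (¹³C/¹⁵N) NanoSIMS image analysis for pulse-chase
labelling studies of plant–fungus nutrient exchange, with a synthetic
ion-count scene simulator that makes every stage testable against known
ground truth.

NanoSIMS raster-scans a Cs⁺ beam across a resin-embedded tissue section and
counts sputtered secondary ions per species per pixel. In a dual-labelling
experiment — the plant canopy exposed to ¹³CO₂ while its ectomycorrhizal
fungi access a ¹⁵N-labelled nitrogen source — the per-pixel isotope
fractions map where recent photoassimilates and fungus-delivered nitrogen
end up, tissue by tissue and cell by cell. `isopixel` implements the full
evaluation chain for such data:

* **Isotope-fraction maps.** The carbon fraction comes from the diatomic
  C₂⁻ species by the pairing formula
  `at%¹³C = 100 · ¹³C¹²C⁻ / (2·¹²C¹²C⁻ + ¹³C¹²C⁻)` (¹³C¹³C⁻ is not
  detected), the nitrogen fraction from
  `at%¹⁵N = 100 · ¹²C¹⁵N⁻ / (¹²C¹⁵N⁻ + ¹²C¹⁴N⁻)`, each with delta-method
  Poisson standard errors and low-count masking. The structural CN⁻ image
  is corrected for the dual labelling:
  `(¹²C¹⁴N⁻ + ¹²C¹⁵N⁻)·(1 + R)` with `R = ¹³C¹²C⁻/(2·¹²C¹²C⁻)`.
* **APE calibration.** Atom percent excess = sample at% minus the at% of an
  unlabelled control reference (global or per tissue × compartment).
* **Mosaic assembly + adsorption QC.** Tiles stitch by the
  nearest-tile-centre rule (overlapping rasters of an altered surface are
  not independent replicates); a rank-sum screen flags tiles whose
  re-measured overlap strip shows the at%¹⁵N depression caused by adsorbed
  natural-abundance N₂, unless the tile was pre-sputtered.
* **ROI statistics.** Per-ROI compositions by the ratio-of-sums estimator
  (species intensities averaged over the ROI first, formulas applied to the
  averages), grouped into tissue × compartment summaries (n, mean, RSD,
  min, max) for the six root-tip tissue classes (HE, HM, HN, PC, E, VT) ×
  (cell wall, lumen).
* **C–N coupling statistics.** Continuous two-segment ("breakpoint")
  regression `y = b₀ + a_low·x + (a_high − a_low)·max(0, x − BP)` fitted by
  an exhaustive RSS profile over interior x-quantiles with iterative
  linearization refinement, a Davies-type breakpoint-existence test,
  bootstrap SE(BP); AIC/BIC model selection across
  linear/log-x/log-y/log-log/segmented candidates (with the log-Jacobian
  correction for transformed responses); Spearman rank correlation with
  exact small-n permutation p-values; line-scan profiles at 3 pixels per
  data point; split-root per-side mass-weighted means and OLS fits.
* **Synthetic scenes.** Ground-truth root-tip cross-sections (concentric
  tissue rings, external hyphae with two radial enrichment patterns,
  biphasically coupled per-cell enrichments, hyphal hot-spots), simulated
  down to Poisson ion counts per acquisition tile, plus bulk root-segment /
  root-tip APE tables for the root-system scale.

## Worked example

Simulate a labelled root-tip scene, stitch it, and quantify it:

```python
from isopixel import *
from isopixel.mosaic import MosaicLayout

cfg = SceneConfig(shape=(184, 184), cell_size_px=12, n_hyphae=25, seed=7)
truth = generate_root_tip_scene(cfg)
grid = TileGrid(rows=2, cols=2, tile_px=96, overlap_px=8)
tiles = simulate_counts(truth, grid, seed=11)
canvas, contrib = assemble_mosaic(tiles, MosaicLayout.from_grid(grid, cfg.pixel_size_um))
control = ControlReference(at13c_pct=1.07, at15n_pct=0.37)
table = roi_composition(canvas, truth_to_roiset(truth), control=control)
print(tissue_summary(table).round(2).head(4).to_string(index=False))
```

```
tissue compartment  n  at13c_mean  at13c_rsd  at13c_min  at13c_max  at15n_mean  at15n_rsd  at15n_min  at15n_max
     E          CW 14        1.32       0.19       0.93       1.79        4.38       0.51       1.09       8.58
     E           L  8        1.29       0.18       1.06       1.68        4.69       0.60       0.79       8.91
    HE          CW 24        1.25       0.23       1.00       2.15        2.76       0.99       0.34      11.95
    HE           L 23        1.18       0.20       0.90       1.93        2.91       0.88       0.33      10.36
```

Each row is one tissue × compartment group of ROIs: endodermis cell walls
average 1.32 at%¹³C (0.25 at% above the 1.07 at% control) and 4.38 at%¹⁵N
(4.0 at% excess over 0.37), while external hyphae span up to ~12 at%¹⁵N —
the strongly labelled hot-spot hyphae.

Breakpoint regression on ROI-level coupling data (here drawn from the
built-in fungal cell-wall reference model, n = 1118, noise calibrated to
R² = 0.65):

```python
x, y = simulate_roi_coupling(fungal_cw_coupling(), n=1118, r2=0.65, seed=1)
fit = fit_segmented(x, y, n_boot=199, seed=1)
print(f"BP = {fit.breakpoint:.2f} +/- {fit.se_breakpoint:.2f} at%13C excess")
print(f"slopes: low {fit.slope_low:.2f}, high {fit.slope_high:.2f}; R2 = {fit.r2:.2f}")
print("selected model:", select_model(x, y).selected)
```

```
BP = 1.86 +/- 0.06 at%13C excess
slopes: low 7.70, high -1.49; R2 = 0.63
selected model: segmented
```

The fitted kink sits near the generating breakpoint of 1.93 at%¹³C excess:
below it ¹⁵N rises steeply with ¹³C (slope ≈ 7.7), above it the coupling is
flat to slightly negative — the biphasic pattern the breakpoint model
exists to quantify. Bulk-scale arithmetic lives in `isopixel.roi`:

```python
>>> mixing_fraction(20.0, 99.0, 0.37)     # hyphae at 20 at%15N, 99 at% source
0.199                                     # one fifth of their N replaced
>>> solution_molarity(54.5, formula="NH4Cl", label_at_pct=98.0)
1.001                                     # mM N, isotope-weighted molar mass
```

A YAML-configured end-to-end run (`isopixel run --config run.yaml`) chains
simulate → mosaic → ratios → roi-stats → segfit → rootstats, writes a
manifest with per-stage seeds and output checksums, and is byte-identical
when repeated; see `isopixel --help` for the individual subcommands.

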