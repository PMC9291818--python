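# Methods

## Counting model and isotope-fraction estimators

A NanoSIMS acquisition is modelled per pixel as independent Poisson counts
per secondary-ion species. The diatomic carbon species arise from binomial
atom pairing of the local ¹³C atom fraction `p_C`: with C₂ emission mean
`M`, `E[¹²C¹²C⁻] = M(1−p_C)²` and `E[¹³C¹²C⁻] = 2Mp_C(1−p_C)`; ¹³C¹³C⁻ is
not in the detected species set. The estimator

    at%¹³C = 100 · ¹³C¹²C⁻ / (2·¹²C¹²C⁻ + ¹³C¹²C⁻)

is exact under independent pairing (an algebraic identity:
`2p(1−p) / (2(1−p)² + 2p(1−p)) = p`) and is the field-standard formula for
this detector configuration; if pairing were non-independent it would be a
slight underestimate, and we deliberately implement the standard estimator
rather than an "improved" one. The CN⁻ species split the CN emission mean
by the ¹⁵N fraction, giving `at%¹⁵N = 100·¹²C¹⁵N⁻/(¹²C¹⁵N⁻+¹²C¹⁴N⁻)`.

Per-pixel standard errors use first-order (delta-method) propagation of the
independent Poisson counts. Pixels whose ratio denominator falls below a
count threshold (default 10) are masked invalid rather than imputed — at
low counts the ratio estimator blows up, and no value is more honest than a
wild one. APE is stored signed (sample at% − control at%); summaries may
floor displayed minima at zero, stored values are never clamped.

The structural CN⁻ image uses the dual-label correction
`(¹²C¹⁴N⁻+¹²C¹⁵N⁻)(1+R)` with `R = ¹³C¹²C⁻/(2·¹²C¹²C⁻)`, so strongly
¹³C-labelled structures keep their apparent material density.

The control reference (defaults 1.07 at%¹³C, 0.37 at%¹⁵N) is a measured
quantity, slightly below terrestrial natural abundance for carbon; we treat
it as the measured-control calibration and model no further instrumental
mass fractionation, dead-time or quasi-simultaneous-arrival correction.

## ROI quantification

ROI compositions use the ratio-of-sums estimator: species intensities are
averaged over the ROI's pixels first, then the at% formulas are applied to
the averages. This matches the convention of extracting average signal
intensities per region before computing compositions, weighs pixels by
their ion yield, and is exactly additive under ROI merges. The
mean-of-per-pixel-ratios alternative is exposed only as a cross-check
(`roi_composition_mean_of_ratios`); the two differ on heterogeneous ROIs.
RSD for single-ROI groups is defined as 0. ROIs are ingested as label
images + annotation tables; in the original workflow they are drawn by
hand, here ground-truth scenes convert to ROI sets automatically
(`truth_to_roiset`), one ROI per cell unit × compartment.

## Mosaic assembly and adsorption QC

Overlap pixels take counts from the tile whose centre is nearest (ties to
the earlier acquisition) — overlapping rasters of the same area are not
independent Poisson replicates once sputtering has altered the surface, so
averaging or summing would be wrong. Overlap in pixels is round-half-up
from micrometres; canvas spans follow the stitching arithmetic (tiles minus
overlaps) and are recorded in the layout metadata. Nominal field-of-view
figures quoted for such mosaics are sometimes rounded (a 4×4 grid of 70 µm
tiles with 20 µm overlap spans ≈220 µm, not 200 µm); the layout never
silently reconciles to a nominal span.

The N₂-adsorption artifact — previously rastered areas adsorb atmospheric
N₂ at natural abundance, depressing measured at%¹⁵N on re-measurement — is
screened per tile: the canvas pixels a tile contributed inside overlap with
any earlier tile (its re-measured strip) are compared against a matched
interior band of equal width by a one-sided Mann–Whitney test, α = 0.01
by default. Pre-sputtered tiles (the instrumental remedy) are skipped. The
test's null assumes local homogeneity across the strip boundary; on
strongly structured tissue the screen also responds to genuine anatomical
gradients, so its calibrated operating characteristics (≥90% detection of
a 30% CN-rate depression, ≤5% false flags) are established on homogeneous
enriched scenes, and on real mosaics a flag means "depressed strip" —
inspect before blaming adsorption.

## Segmented regression and model selection

The two-segment model `y = b₀ + a_low·x + (a_high−a_low)·max(0, x−BP)` is
continuous at the breakpoint by construction. Fitting profiles the RSS over
200 breakpoint candidates on the interior 5–95% x-quantile range (boundary
candidates make the hinge column collinear), then refines the best
candidate by iterative linearization — refit with the hinge and its
derivative column, update `BP ← BP + γ̂/d̂` — to 1e-8 on BP, falling back
to a bounded scalar RSS search if the iteration leaves the grid bracket.
On noiseless kinks the refined fit matches exhaustive search to tolerance
(tested).

Breakpoint existence is a Davies-type maximum-score test: the largest |t|
of the hinge coefficient over 50 interior candidates, with the Davies upper
bound for the maximum of a correlated process. Non-significant (α = 0.05)
fits fall back to the plain line with the breakpoint reported undefined.
SE(BP) is a seeded nonparametric pairs bootstrap (default 999 resamples; a
coarser grid per resample keeps it tractable). Per-segment R² and p-values
come from sub-fits on the points below/above the fitted breakpoint; the
total R² is that of the full segmented fit — definitions recorded here
because several conventions circulate.

Model selection compares linear, log-x, log-y, log-log and segmented
candidates by AIC or BIC. Log-transformed-response candidates add the
log-Jacobian (Σ log y) so likelihoods are comparable on the original
response scale; both corrected and uncorrected criteria are reported and
selection defaults to corrected. Parameter counts include the residual
variance (3 for the line-like models, 5 for segmented); ties break toward
fewer parameters; candidates requiring logs of non-positive data are
excluded and recorded.

Spearman correlation uses mid-ranks for ties; the permutation p-value is
exact for n ≤ 10 on untied data (all n! pairings, vectorized) and
asymptotic otherwise. Line scans aggregate 3 pixels per data point by
default, with distances at bin centres.

Split-root per-side means weight segments by dry mass — mass weighting is
our choice of weight variable for "weighted mean of measured segments" —
and per-side OLS of APE¹⁵N on APE¹³C uses ordinary least squares.

## Synthetic scenes: what they emulate, and what they do not

The scene generator is stylized anatomy, not morphogenesis: concentric
rings (vascular core, endodermis, cortex, Hartig net, mantle) with a
jittered rectangular cell lattice providing the cell-wall/lumen pattern,
and external hyphae as discs with an annular wall. Geometry defaults put
ring radii at fixed fractions of the canvas; realized per-class areas track
the closed-form annulus areas (tested to ±20%, the slack covering
discretization and hypha overwrites).

Enrichment is drawn per cell-scale unit: the true APE¹³C is lognormal per
tissue (the strong right skew of observed enrichment distributions — most
units barely labelled, a few strongly — has no published parametric form;
lognormal is the natural minimal choice), and APE¹⁵N follows the
continuous two-segment coupling model plus Gaussian noise. Default
per-tissue parameters place breakpoints at interior quantiles of the
lognormal draw (roughly 10–35% of units above the kink) so the biphasic
structure is visible at ordinary scene sizes. A configurable fraction of
external hyphae are hot-spots (boosted lognormal draw), and each hypha
carries one of two radial patterns: "wall-co-located" (both isotopes
peaking in the outer ring) or "centre-¹⁵N" (¹⁵N peaking centrally with
almost no ¹³C), mixed 50:50 by default.

Acquisition defaults follow standard practice for this instrument class:
512×512 px tiles, 70/512 µm pixel size, 13.5 ms dwell per pixel; tile
field sizes are configurable since published tile sizes for comparable
mosaics vary (50–70 µm). Emission rates (CN⁻ 30 counts/px/ms in lumen, 45
in walls; C₂⁻ at 0.4× CN) give per-pixel CN counts of a few hundred at the
default dwell — enough that ROI-level ratios are precise while per-pixel
ratios remain visibly noisy, as in real data. The adsorption artifact adds
CN⁻ counts at natural ¹⁵N abundance on previously covered pixels of
non-pre-sputtered tiles, at a configurable fraction of the local CN rate
(default 0.3); the qualitative mechanism is known, the depth is not, hence
a parameter.

The bulk root-system generator draws per-side segment APE¹³C from a
lognormal (means ≈0.8–0.84, SDs ≈0.24–0.27 APE chosen so the generating
linear models reproduce the reported per-side APE¹⁵N means and SDs), and
APE¹⁵N from the per-side linear model (amended 0.25·x − 0.06, unamended
0.029·x − 0.013) with Gaussian noise calibrated so the population R² on
the realized draw equals the target (amended 0.1416, unamended 0.39):
`sd² = Var(model)·(1−R²)/R²`. Root tips are lognormal with median and mean
matched to the reported heavy-tailed summaries (amended: median 0.003,
mean 0.28).

What the generator does not emulate — and hence what passing tests do not
establish about real data: realistic fungal morphology and septation,
sputtering physics and depth effects, detector dead time and QSA, drift
and charging, spatial autocorrelation of enrichment beyond the cell-unit
scale, and anatomical gradients confounding the adsorption screen.

## Numerical and design choices

* Per-stage seeds derive from the global seed via
  `numpy.random.SeedSequence(seed).spawn`, so stages rerun in isolation;
  every output records its seed, and identical configs are byte-identical.
* Test and acceptance problem sizes are scaled-down scenes (160–184 px
  canvases, 2×2 tile grids) — our choice of desk-scale defaults; the
  estimators are size-agnostic and the statistical benchmarks use the full
  published sample sizes (n = 1118 ROIs; 35/32 segments).
* Stitching never interpolates: counts are copied verbatim, preserving
  their Poisson character for downstream ratio statistics.
* `excess_15n_mass` supports both an atom-based convention (N pool in
  moles, excess atoms weighted at the ¹⁵N mass) and a mass-based one; the
  two differ by 15.000/14.007 and the convention is recorded in the
  output, since bulk-budget numbers in the literature rarely state theirs.
* The exact-permutation Spearman p is limited to n ≤ 10 (10! ≈ 3.6M
  pairings, vectorized as one matrix product); beyond that the
  t-approximation is accurate and standard.

## Known limitations

Vendor raw formats (.im) are out of scope; stacks enter as multi-page TIFF
with a JSON sidecar under a documented contract. Tissue classes come from
annotations or ground truth — no automated segmentation. The breakpoint
SE is bootstrap-based; a delta-method variant would require the hinge
curvature assumptions the bootstrap avoids. The Davies bound is
conservative for coarse candidate grids. GLM-with-post-hoc comparisons and
other routine off-the-shelf testing are deliberately not re-implemented.
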