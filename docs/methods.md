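# Methods

## The model

The niche model is a regularized maximum-entropy presence-background
distribution. Over a background sample of landscape cells (default 10 000
random valid cells, presences added to the background before the partition
function is computed), the model is the Gibbs density

    P(x) = exp(λ·f(x)) / Z,   Z = Σ_background exp(λ·f(x)),

and the coefficients maximize

    (1/m) Σ_presences λ·f(xᵢ) − log Z − Σⱼ βⱼ|λⱼ|.

Per-feature penalties are βⱼ = rm · λ_class(m) · sqrt(varⱼ/m), with varⱼ the
feature variance over presence sites and λ_class(m) the published per-class
defaults of the reference presence-background tool, interpolated
log-linearly in the presence count m (linear/quadratic/product: 1.0 at
m=10, 0.2 at m=30, 0.05 at m≥100; hinge: 0.5; threshold: 2.0 at m=10, 1.0
at m≥100). `rm` is the user-facing regularization multiplier.

Features are built on variables min-max scaled to [0, 1] from the pooled
presence+background values (projection clamps to that range): linear z,
quadratic z², pairwise products, hinge pairs max(0,(z−k)/(1−k)) and
max(0,(k−z)/k), and threshold indicators z>k, with knots at 50 equally
spaced background quantiles per variable (duplicated quantiles collapse).
Constant variables are excluded with a warning.

Output transforms: raw (sums to 1 over the training background — asserted
after every fit), cloglog 1−exp(−e^H·raw) (the default, matching modern
tool behavior), and logistic τr/((1−τ)+τr) with τ=0.5, r=e^H·raw, where H
is the entropy of the fitted background distribution. Both bounded
transforms are strictly increasing in raw, so cell rankings agree.

### Optimizer

Cyclic coordinate descent with soft-thresholding. Each coordinate update
uses the current model expectation and variance of that feature over the
background (maintained incrementally through the unnormalized log-weights),
takes the Newton step, applies the L1 soft-threshold, and clips steps to
±4 for stability. Convergence is declared when the relative objective
change over a full sweep drops below `tol` (default 1e-5, `max_iter`
default 500 sweeps); non-convergence returns the model with a warning.
Per-update objective gains are recorded and attributed to the updated
feature's source variable (product features split evenly) to give percent
contribution; a gainless model reports all zeros.

On one- and two-feature problems the coordinate-descent solution matches an
independent brute-force maximization of the same penalized objective (dense
grid plus derivative-free polish) to 1e-4 in coefficient space; this is a
standing test.

## Selection and evaluation

AUC is the rank (Mann–Whitney) statistic with ties counted one half; TSS is
maximized over all observed thresholds with "score ≥ threshold" predicting
presence; OR10 uses the 10th percentile of training presence scores and
strictly-below counting. AICc = 2k − 2lnL + 2k(k+1)/(n−k−1) with k the
count of coefficients over 1e-8 in magnitude and lnL the presence
log-likelihood of raw normalized over *all* valid cells of the projection
grid (the common selection convention; the training-background alternative
is a documented toggle). The tuning grid crosses multipliers
{0.5,…,4 step 0.5} with feature sets {L, LQ, H, LQH, LQHP, LQHPT, QHP,
QHPT, HPT}; the cell with delta-AICc = 0 is selected, ties broken by lower
OR10, then lower train-test AUC gap, then fewer nonzero coefficients. A
failed cell records its error and the grid continues.

## Spatial stages

**Grids.** Geographic WGS84, north-up, square cells; cell centers at
(x_min+(j+0.5)·cell, y_max−(i+0.5)·cell); point-in-cell tests are half-open
from the south/west edges, so a point on the exact north/east boundary is
off-grid. Cell areas use the spherical form R²·Δλ·(sinφ_top−sinφ_bottom)
with R = 6371.0 km; the working resolution defaults to 2.5 arcmin but
nothing assumes a fixed extent. ESRI ASCII is written at 6 significant
digits by default with a full-precision flag for round-trip work; GeoTIFF
I/O (via tifffile with standard geo-tags) stores float64. Bilinear
resampling interpolates between source cell centers, never overshoots the
source range, and any nodata corner poisons the output cell; stack
alignment applies the union of nodata masks.

**Thinning.** Exact duplicates are removed, the order is shuffled by seed,
and each point is kept iff ≥ min_km (haversine) from all points kept so
far; the result is maximal (no discarded point can be re-added). A
best-of-N-seeds variant mirrors the repeated-trials idea of the usual
thinning packages.

**Collinearity screen.** Pearson r over jointly valid cells (or at
occurrence points — both modes exist because published workflows are often
silent on this). "Ecological significance" is not computable, so the screen
takes an explicit priority list and resolves conflicts greedily in priority
order; constant variables have undefined r, are flagged, and are treated as
r=0 so they are never dropped for collinearity. The filter asserts post-hoc
that no retained pair reaches the threshold, and the retained set grows
monotonically with the threshold.

**MESS / MoD.** Per variable, with f the percentage of reference values
strictly below the query value: f=0 → 100(p−min)/(max−min); 0<f≤50 → 2f;
50<f<100 → 2(100−f); f=100 → 100(max−p)/(max−min). The last branch is the
continuous limit of the piecewise form (a source transcription of it
contains an evident typo). Strictly-below counting means the similarity
peak of 100 is attained when the query splits the reference sample exactly
in half (even n). The surface takes the minimum over variables; MoD is the
argmin (first index on ties). The default reference is the environmental
values at occurrence cells; all suitable-area cells are a configurable
alternative.

**Habitat classes and centroids.** The published class labels leave gaps
(0.1–0.2 and 0.5–0.6 unassigned); classification here uses contiguous edges
(0.1, 0.25, 0.5] — unsuitable, secondary, suitable, optimal — so area
accounting partitions the valid surface exactly. Jenks breaks are the exact
dynamic-programming optimum (verified against exhaustive partition search
for n ≤ 12); quality classification subsamples above 5 000 cells for
tractability. Centroids are suitability·area-weighted means of cell centers
over cells ≥ 0.25 by default (a uniform-weight class mode exists; the
choice is stated because published tools leave it internal). Longitude
averaging is arithmetic — valid away from the antimeridian, guarded by a
bounds check. Migration vectors report haversine distance and initial
great-circle bearing, labelled on an 8-sector compass rose.

## Assay and quality models

The calibration line is OLS of absorbance on glucose concentration; the
packaged reference protocol is 15.07 mg glucose in 25 mL (stock
602.8 µg/mL) with aliquots 0.5–1.8 mL. The printed standard concentrations
(3.0140–10.8505 µg/mL) imply a 100 mL final volume although the protocol
text says 25 mL bottles; the printed concentrations are followed.
Polysaccharide content is (c·d·f/w)·100% with f = 2.38; the dilution factor
d deliberately carries all volume/unit bookkeeping (e.g. a 100 mL extract
from 0.1 g gives d = 1e-4 in µg→g units) because published protocols leave
that reconciliation implicit. Concentrations below the calibration
intercept clamp to zero with a warning.

The 44-site content table ships as a CSV fixture (percent mass fraction,
mean ± SD of three replicates); sites with heterophyllin B below the
quantification limit carry an ND flag and NaN means and are excluded from
regression by default (left-censoring at half the minimum detected value is
an option; the original handling is unstated). Stepwise regression is
forward entry by smallest partial-F p-value below alpha_enter (0.05),
backward removal above alpha_remove (0.10), iterated to a fixpoint with a
cycle guard, skipping candidates that make the design singular; with both
alphas at 1 it reduces to full OLS (tested against a normal-equations
solve). The published content equations are frozen constants
(polysaccharide: intercept −79.109 over bio6, bio1, bio2, bio3, bio4,
bio12, bio14, bio16; heterophyllin B: intercept 0.013 over bio6, bio2,
bio3, bio4, bio12, bio16) and are applied cellwise to raster stacks;
quality maps use three-class natural breaks over the current-period surface
by default, and those break values should be frozen and reused across
future scenarios so class areas stay comparable.

## Synthetic scenes

The generator emulates the structure, not the geography, of the real study
system: 19 bioclim-style Gaussian random fields (white noise smoothed with
a Gaussian kernel of 6 cells, standardized, then mixed by the Cholesky
factor of a block correlation matrix — AR(1)-within-block with base 0.93
for the temperature block bio1–bio11 and 0.90 for the precipitation block
bio12–bio19, zero across blocks) on an 80×80, 0.2° grid over a
subtropical-China-like window, with loosely realistic means and SDs. The
niche truth is a product-Gaussian response, by default a restricted-range
specialist: bio12 optimum 1450 mm (≈1.2 landscape SD above the mean) with
breadth 60 mm, plus a secondary bio1 axis (16.5 °C, breadth 1.3 °C,
weight 0.6). That restrictiveness was chosen to match the reported
discrimination regime of the real system (a specialist herb; the true
surface's own AUC ceiling is in the mid-0.9s); with a broad generalist
niche no model, however good, could reach such AUCs. Presences are drawn
without replacement proportional to truth and jittered within the cell;
site compound tables add Gaussian noise (default 10% of the response SD) to
a content equation, with an optional ND threshold. A scenario knob applies
additive warming and multiplicative precipitation change, giving
centroid-shift and similarity experiments a known expected direction.

What passing synthetic tests do **not** show: real bioclim layers have
terrain-driven anisotropy, skewed precipitation distributions and
cross-block correlations that the generator omits; real occurrence data
carry spatial sampling bias that proportional-to-suitability sampling does
not emulate. Recovery rates here certify the machinery, not field
performance.

## Problem sizes and numerical choices

Default test and acceptance runs use the 80×80 scene (6 400 cells,
200 presences, full-landscape background) and 10 seeds for the recovery
rates — sizes chosen so the whole suite exercises every stage in a few
minutes. Fit tolerance 1e-5 (1e-12 in oracle tests), coordinate steps
clipped at ±4, nonzero-coefficient threshold 1e-8, hinge/threshold knots
clipped to (1e-6, 1−1e-6). Degenerate inputs fail loudly: constant
reference variables in MESS, zero-mass centroids, fewer distinct values
than classes in Jenks, n ≤ k+1 in AICc.

## Known limitations

No projected coordinate systems, no tiling for out-of-memory rasters, no
categorical features or clamping diagnostics beyond MESS, no bit-parity
with any particular desktop implementation, and the eight non-maximum-
entropy ensemble algorithms are out of scope (the surface-range envelope
stands in as a baseline). The CLI is a thin wrapper; orchestration beyond
single stages belongs in user scripts.
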