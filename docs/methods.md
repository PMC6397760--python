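# Methods

This note documents the models and procedures `crownpipe` implements, the
parameters that matter, the synthetic data the tests rely on, and the
design choices made where the design was genuinely open. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Coordinate and raster conventions

All positions are projected metric easting/northing. The alignment cost
normalizes residuals by metre-valued RMS errors, so geographic (degree)
coordinates must be projected before entering the pipeline. Rasters put
row 0 at the northern edge; the grid origin is the upper-left *outer*
corner; pixel (r, c) covers a half-open square of side `pixel_size` and
its centre sits half a pixel in. Nodata is NaN internally; NaN pixels are
excluded from masks, features and band means. The red and near-infrared
NDVI bands are selected by nearest centre wavelength to 628.1 nm and
728.3 nm, which transfers across sensors with different band numbering
(ties go to the lower band index).

## Segmentation

The vegetation mask keeps pixels with NDVI ≥ `ndvi_min` (default 0.5) and
canopy height ≥ `crown_min_height_m` (default 3 m), both bounds
inclusive, both values finite. The NDVI cut removes soil and ground cover
while retaining canopy; it is a config knob because the appropriate value
is scene-dependent.

Treetops are local maxima of the masked CHM under a variable window:
a pixel of height *h* ≥ `top_min_height_m` (default 5 m) is an apex iff no
masked pixel within Euclidean centre-to-centre distance
`window_slope * h + window_intercept` (defaults 0.25 and 1.2, radius in
metres and inclusive of the boundary) is strictly higher. The linear
radius rule encodes the allometric fact that taller trees carry wider
crowns, so a taller apex must dominate a wider neighbourhood. Two
resolved ambiguities: window membership is measured in metres (the rule's
inputs and outputs are metres, not pixels), and plateau ties are broken
by row-major order — a pixel loses to an equal-height masked pixel
earlier in row-major order inside its window, guaranteeing exactly one
apex per flat plateau. Apex detection (≥ 5 m) is deliberately stricter
than crown membership (≥ 3 m): crown edges may run below the apex
threshold but not to the ground.

Crowns are grown by a marker-controlled watershed on the inverted CHM
restricted to retained pixels: flooding proceeds by descending height
with 4-connectivity, and on equal heights earlier-discovered pixels flood
first, so ridge ties go to the marker flooded first (markers are seeded
in descending apex height). The flood is implemented directly (a
heap-based priority flood) rather than through a library call because
these tie rules are part of the contract: the test suite holds the output
to exact equality with an independently written linear-scan priority
flood, and cross-checks against `skimage.segmentation.watershed` on
tie-free inputs, where all correct floods agree.

Each labelled pixel set is polygonized as the union of its pixel squares
with collinear vertices removed; the polygon area is defined as pixel
count × pixel area. Crowns enclosing holes are rejected rather than
silently filled (they do not arise from this flood in practice).

## Alignment

Stems are first assigned to plots by nearest crown (ties to the smaller
crown id), then each plot's stems are translated so their centroid
coincides with the crown centroid, removing the systematic positioning
bias between ground and airborne surveys. The offset correction is
applied *before* the RMS normalizers are measured on training pairs, so
the normalizers describe residual (random) error only.

Crown diameter is derived from area under a circular-crown assumption,
D = 2√(A/π). The allometric predictor is an ordinary least-squares
regression of crown diameter on stem diameter (cm); a stem-height
predictor is also available in `fit_allometry` but is not used in the
cost, because stem diameter is the stronger predictor of crown size in
mixed pine–oak systems of this kind. The pair cost is the sum of squared
diameter and coordinate residuals, each scaled by its training RMS to be
dimensionless. A `position_only` switch drops the diameter term,
reproducing a position-only benchmark matcher for comparison.

The minimum-total-cost one-to-one matching is found with an exact linear
assignment solver (`scipy.optimize.linear_sum_assignment`) rather than
explicit enumeration of all pairings — the optimum is identical (verified
against enumeration for n ≤ 6) and the solver scales to real plots. With
unequal counts the smaller side is fully matched and the surplus is
reported unmatched. Degenerate training data with a zero RMS raise an
error instructing the user to set an explicit floor, rather than
silently dividing by an arbitrary epsilon.

## Classification

Per-crown pixels are aggregated to mean/min/max height, √pixel-count
(a diameter proxy at 1 m pixels), and per-band mean reflectance. Two PCA
routines — one on the 4 structural features, one on the spectral means —
retain 3 and 10 components respectively (13 features total). Inputs are
centred but, by default, not variance-standardized: the band means share
units, and standardization would up-weight noisy low-variance bands. A
`standardize` switch (correlation PCA) is available for scenes where the
structural features' differing units matter more.

Each species is a multivariate normal in the reduced space. Likelihoods
are computed and compared in log space via a Cholesky factorization: the
raw 13-dimensional density underflows double precision, and the argmax is
unchanged. Covariances get a ridge of 1e-6 × mean diagonal; species with
fewer training trees than the feature dimension + 1 (< 14 by default) use
the pooled within-class covariance, because per-class covariances
estimated from so few trees are singular or nearly so — the classic
failure mode of Gaussian maximum likelihood with unevenly sampled
classes. Posteriors are the softmax of the log-likelihoods under a
uniform class prior; likelihood ties resolve to the lexicographically
smaller species name.

## Evaluation

Segmentation: per-crown Jaccard (intersection over union of pixel sets)
under a greedy matching — reference crowns in descending size order each
claim the unclaimed predicted crown with the largest intersection;
unmatched references score 0 and enter the mean. The published
competition aggregate behind scores of this kind uses an unpublished
matching rule, so numbers produced here are internally consistent but not
comparable to leaderboard values. Classification: rank-1 accuracy,
cross-entropy in nats with posteriors floored at 1e-12 (keeping a
certain-and-wrong prediction finite), and per-species precision / recall
/ F1 with the conventions precision = 0 for a never-predicted species and
F1 = 0 when either component is 0. Micro-averaged recall equals rank-1 by
construction, which the tests assert.

## Synthetic scenes

The generator emulates the survey geometry the pipeline targets: square
plots (default 80 × 80 m) gridded at 1 m, a 426-band cube spanning
350–2500 nm, stems jittered by σ = 1 m with a plot-wide systematic offset
of a few metres (default (3.2, −1.7) m, typical hand-held GPS bias).
Trees are placed by rejection sampling with a minimum apex spacing,
apexes snapped to pixel centres; each tree is a cone
h(d) = H·max(0, 1 − d/R) and the CHM is the pixelwise maximum (ties to
the earlier tree). Crown radius follows R = 0.2·H + 1.0 + N(0, 0.25) m,
and stem diameters are generated by inverting a linear
crown-diameter-on-stem-diameter relation (slope 0.114 m/cm, intercept
0.882 m) with 0.5 m residual noise, so the regression the alignment
stage fits is well-posed with realistic scatter. Default species
signatures share a green-vegetation curve (red edge at ~710 nm, NIR
plateau, SWIR water-absorption dips) and differ by NIR/SWIR bumps placed
away from the NDVI bands, so every species passes the vegetation mask
while staying separable; the ground signature is spectrally flat
(NDVI ≈ 0). One global seed spawns per-purpose substreams (placement,
spectra, jitter, allometry), making scenes bit-reproducible and the
subsystems independently variable. A `degrade_scene` harness adds stem
jitter and blends species signatures toward their mean (mixing 1 =
species indistinguishable) without disturbing the noise already drawn.

What the generator does *not* emulate: irregular and overlapping crown
shapes (hemispheres are the only alternative shape), understory and
sapling layers, within-crown spectral gradients and illumination/BRDF
effects, sensor artefacts, and incomplete stem–crown correspondence.
Passing tests on these scenes therefore demonstrate correctness of the
algorithms under their stated assumptions — not field-level skill on real
imagery, where crown overlap and spectral mixing dominate the error
budget.

## Problem sizes and numerical choices

The test suite and acceptance script use problem sizes chosen to exercise
every code path at desk scale: oracle equivalences on 50 × 50 (treetops)
and 20 × 20 (watershed) grids, assignment enumeration at n ≤ 6 over 100
instances, alignment recovery over 20 ten-stem plots, classification
recovery over 10 seeds of 3 × 30 + 3 × 30 crowns, and an 18-tree
160 × 160 m scene for end-to-end runs. Scenes used for alignment-only
properties carry 4-band cubes, since those tests never touch the spectral
stage. Tolerances: closed-form cases to 1e-9; oracle equivalences exact;
round-trip I/O to 1e-6; PCA orthonormality to 1e-8. Pipeline reports
exclude timings so identical configurations and seeds yield byte-identical
JSON.

## Known limitations

- The greedy Jaccard matching is order-dependent by design and documented
  rather than optimal (a maximum-weight matching would differ on
  contrived overlaps).
- Alignment assumes complete one-to-one stem/crown data within a plot;
  surplus records are reported unmatched but no partial-credit matching
  is attempted.
- Classification requires every test-time species to have been seen in
  training; unseen species raise an error rather than being rejected as
  outliers.
- The watershed assigns every retained pixel connected to a marker; it
  does not model unclaimed canopy (e.g. crowns whose apex fell below the
  5 m threshold are absorbed by neighbours or left unlabelled wholesale).
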