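# Methods

This document records the modelling choices implemented in `stacksdm`,
their parameters, and the rationale for the places where the package
deviates from the most common textbook recipe.

## Study design

The package implements stacked species distribution modelling (SSDM) for
assemblage-level diversity mapping:

1. occurrence records are cleaned, thinned to one record per species per
   grid cell, and species with too few records are dropped;
2. each remaining species is modelled individually against a stack of
   environmental raster layers, with several algorithms per species;
3. the per-algorithm suitability maps are combined into one weighted
   ensemble per species and binarised at a TSS-optimal threshold;
4. the binary maps are stacked (cellwise summed) into a species-richness
   surface, with companion uncertainty and weighted-endemism surfaces;
5. the richness surface is analysed with gradient regressions, regional
   ANOVA and Moran's I, and species are clustered by their environmental
   importance profiles.

Because assemblage-scale compilations are presence-only, every stage is
validated against synthetic data with known truth: virtual species with
Gaussian niches on simulated autocorrelated landscapes (see
"Synthetic-data generator" below).

## Grids and raster I/O

Analysis grids are north-up, square-cell grids (`GridSpec`): row 0 is
the northernmost row and the origin is the north-west corner. A cell
owns its west and north edges (half-open intervals); points on the east
and south boundary of the full extent are closed into the last cell so
the extent has no unowned border. Layers are stored as ESRI ASCII grids
(`.asc`, plain text, NODATA −9999) plus a YAML manifest carrying layer
names, units and the priority order used by the collinearity screen. On
reading a stack, the shared validity mask is the intersection of the
per-layer masks. Bilinear resampling interpolates between the four
surrounding cell centers, propagates nodata from any contributing
corner, and clamps target points inside the extent but outside the hull
of source centers to the nearest center.

## Occurrence preprocessing

Cleaning applies, in order: local synonym standardisation, exact
deduplication, removal of records with missing or out-of-range
coordinates, removal of records off the grid or on nodata cells, and
removal of names not resolvable to species level. Each drop reason is
counted and logged. Thinning keeps the first record per species-cell
after a stable sort on source identifier, so results do not depend on
input row order. Species with fewer than 4 thinned records are excluded
(too few for cross-validated fitting).

Collinear layers are screened greedily on the pairwise Pearson
correlation over jointly valid cells: while any pair exceeds |r| = 0.85,
the lower-priority member of the worst pair is dropped.

## Pseudo-absences

Pseudo-absences are drawn without replacement from valid cells,
allocated proportionally across a 5 x 5 spatial stratification of the
grid (floor allocation, remainders to the blocks with the largest
eligibility) so the background follows the geography of available
habitat. Counts follow the per-algorithm-family convention:
presence-matched for classification-style algorithms (CTA, RF, SVM,
GBM, ANN), a fixed background of 1000 for regression-style ones (GLM),
both capped at eligibility.

At the pipeline level, cells within a Chebyshev (chessboard) distance of
3 of any presence cell are excluded from the background. Rationale:
with presence-only data, cells adjacent to presences are
disproportionately occupied-but-unsampled habitat; background points
drawn there act as false absences and bias the TSS threshold upward,
shrinking predicted ranges. On the synthetic benchmark this defect was
visible directly — ranked suitability tracked truth almost perfectly
while thresholded ranges under-covered it — and the buffer corrected it
(end-to-end richness correlation with truth across four seeds rose from
about 0.78 to 0.80–0.86). The low-level
`occurrences.generate_pseudo_absences` keeps buffer 0 as its default;
the pipeline default is 3.

## Algorithms

Algorithm adapters share one contract: `fit(X, y, seed)` then
`predict(X)` returning suitabilities in [0, 1], deterministic under the
seed. Built-ins: CTA (classification tree, balanced class weights), RF
(500 trees, balanced), GBM (1000 trees, learning rate 0.01, depth 3),
SVM (RBF kernel on standardised inputs; the decision margin is mapped
through a logistic link, a monotone map that leaves AUC and TSS
threshold scans unchanged), GLM (logistic regression with quadratic
terms), ANN (one hidden layer of 16 units). The default ensemble is
CTA + RF + SVM; `ensemble.search_combinations` evaluates alternatives.

## Evaluation

Threshold-dependent metrics come from the 2 x 2 confusion table:
sensitivity, specificity, TSS (= sensitivity + specificity − 1), Cohen's
kappa (chance agreement from marginal products), proportion correct,
omission rate and Jaccard similarity. AUC is the rank (Mann–Whitney)
statistic. Cross-validation is stratified k-fold (default k = 20,
10 replicates), with per-fold metrics computed at the fold-specific
TSS-optimal threshold and averaged.

`select_threshold` scans the sorted unique prediction values and
returns the smallest value maximising sensitivity + specificity, with
the scan scored in exact integer arithmetic over the common denominator
so that mathematically tied candidates compare equal (float TSS can
differ between tied candidates by one ulp).

### Threshold selection on out-of-fold predictions

The final binarisation threshold of a fitted model is *not* selected on
in-sample predictions of the refitted model. Flexible learners
reproduce their training labels almost perfectly, so resubstitution
thresholds are biased high and shrink predicted ranges. Instead, each
cross-validation replicate's pooled out-of-fold predictions yield one
TSS-optimal threshold, and the replicate thresholds are averaged.
Ensembles likewise threshold on the weighted combination of member
out-of-fold predictions.

### Variable importance

Permutation importance: the raw score of a variable is the mean over
repeats of 1 − r, where r is the Pearson correlation between
predictions on the intact design matrix and on a copy with that
variable's column permuted. Negative raw scores are clipped to zero and
the vector is normalised to percentages summing to 100.

## Stacking and community evaluation

Richness is the cellwise sum of thresholded binary maps, so total
richness over the grid equals the sum of per-species range sizes by
construction. Uncertainty is the mean over species of the
between-algorithm standard deviation of member suitabilities. Weighted
endemism (WEI) sums, per cell, each present species' inverse range
size. Community evaluation scores the predicted assemblage against the
observed species set at each occupied cell over the full modelled
roster (prediction success = percent correct; absence of unrecorded
roster species is assumed, the unavoidable convention with
presence-only data).

## Spatial statistics

Regional comparisons use one-way ANOVA with Tukey HSD (alpha 0.05);
richness gradients are OLS fits of cell richness on the cell-center
coordinate along one axis. Moran's I uses binary rook-contiguity
weights (not row-standardised) with the normality approximation for the
z-score; E[I] = −1/(n − 1). When subsampling large grids for Moran's I,
a random rectangular window is cropped rather than scattering points,
because a scattered subset loses contiguity and hence all weights.

## Importance clustering

Species are clustered on their ensemble importance profiles with the
HCPC idiom: PCA under the correlation-matrix convention (columns
standardised with one delta degree of freedom; deterministic component
signs), retaining the smallest number of components explaining at least
80% of variance (capped at 5), then Ward hierarchical clustering on the
retained scores. The automatic cluster count is the candidate in
[2, 10] with the largest relative drop in within-cluster inertia
between consecutive cuts. Each cluster is characterised by the
variables with the largest standardised contrast against the grand mean
and a representative species nearest the centroid.

## Synthetic-data generator

The generator emulates what a basin-scale compilation provides, on a
shallow subtropical shelf sea:

- **Landscape**: a 100 x 100 grid (cell 0.02 degrees) with a diagonal
  land margin covering about 12% of cells in the south-west corner.
- **Layers**: 15 named layers with realistic value ranges (bathymetry,
  temperature statistics, salinity, chlorophyll-a, dissolved oxygen,
  nutrients, pH, calcite, light attenuation). Each layer mixes a
  deterministic ramp (alternating N–S and E–W, weight 0.4) with
  Gaussian-smoothed white noise (kernel radius 8 cells), rescaled to
  the layer's range. Fields are strongly spatially autocorrelated
  (Moran's I well above 0.5), as real environmental surfaces are.
- **Species**: suitability is the product of per-layer Gaussian
  responses (optimum and breadth drawn within each layer's range;
  about half the species are single-layer specialists), normalised to
  a maximum of 1. Occupancy thresholds suitability at the quantile
  matching a prevalence target in [0.08, 0.25].
- **Sampling**: presence-only draws proportional to suitability within
  the occupied range, deduplicated to cells, with cell-center
  coordinates; detection is perfect, so every record lies inside the
  true range.

Known limits: niches are unimodal and axis-aligned (no interactions),
detection bias is limited to suitability weighting, and layers are
mutually independent apart from chance correlation.

## Problem sizes and determinism

Library defaults are k = 20 folds and 10 replicates. The bundled
end-to-end recovery study (20 species, 15 layers, 100 x 100 grid,
CTA-RF-SVM) uses k = 5 with 1 replicate and 1 permutation repeat — a
package choice that keeps a from-scratch refit within a few minutes
while leaving the headline results stable. All randomness flows from
one root seed through named substreams (a stable string hash below
2^31), so identical configurations reproduce identical outputs;
remaining nondeterminism is limited to last-ulp differences in linear
algebra, which the tests tolerate.

## Reference census

`datasets.synthetic_gulf_census` expands published order, genus and
wall-type tallies of an Arabian Gulf benthic foraminifera compilation
(492 species) into a synthetic species-level census table: species
names are placeholders, but group counts match the published tallies,
so composition summaries reproduce the published percentage shares.
The published order-level and wall-type tallies are not mutually
consistent; wall types are assigned to match the published wall tallies
(hyaline 288, porcelaneous 142, agglutinated 62), independent of order
where needed.
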