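# Methods

This note records the modelling assumptions, numerical choices and
defaults behind `nichedyn`, and what the synthetic validation does and
does not establish about real data.

## Grids and coordinates

Rasters are abstract planar grids: 0-based row/col, x increasing with
column, y decreasing with row, square cells of configurable side (km;
default 5 km in synthetic scenarios, matching the resolution at which
hornet-scale records are usually pixelated). Cell membership is half-open
(`x0 + j·s <= x < x0 + (j+1)·s`), fixed so that rarefaction and
point-to-cell lookups are reproducible. No geographic CRS or reprojection:
the analysis is CRS-agnostic, and layers are expected on one common grid
per range. Raster I/O is ESRI ASCII grid only — a plain-text, single-band
format with NODATA; the stack's validity mask is the conjunction of the
per-layer masks.

## Preprocessing

**Rarefaction** keeps at most one record per grid cell. Among co-celled
records it retains the one whose per-layer-standardized environmental
vector lies farthest (Euclidean) from the centroid of the records already
kept — an environmentally-weighted thinning rule; the first kept cell and
all ties fall back to input order, making the operation deterministic and
idempotent. No published rule exists for which co-celled point to keep;
this choice maximizes retained environmental information.

**Collinearity filter.** Pearson correlations are computed on the pooled
background cells of both ranges (a per-range mode would apply the union of
removals); for every pair with |r| ≥ 0.70 (default) the lower-priority
variable is removed, priority being an explicit ordered list (a proxy for
acknowledged biological importance) or table order. Constant variables
have undefined r and are kept with a warning. The surviving set never
contains a pair at or above the threshold (asserted by recomputation).

## The environmental ordination (PCA-env)

The two comparison axes come from a PCA of the standardized union of *all*
background cells of both ranges, maximizing the ecological variance the
space can express. Only two axes are used. Loadings are
sign-fixed (largest-magnitude entry of each column positive) so repeated
fits agree. Entities are compared on one shared R×R grid; R = 100 by
default (the conventional resolution for this framework), with axis
bounds taken over the pooled scores of both ranges and padded by 5% of
each axis range so kernels are not truncated at the data extremes.

## Occupancy surfaces

For each entity, occurrence density `o` and availability density `e` are
separable Gaussian product-kernel KDEs evaluated at cell centres.
Bandwidths follow Silverman's rule per axis (`h = sd · n^(-1/6)`),
computed independently on the occurrence scores (for `o`) and the
background scores (for `e`); a fixed bandwidth can be supplied instead.
Two numerical floors keep the surfaces well behaved:

* bandwidths are floored at one grid-cell width, since a sub-cell kernel
  can underflow at every cell centre of a coarse grid (tiny or nearly
  collinear samples);
* density below 1e-12 of a surface's maximum is treated as absent, giving
  `o` and `e` finite support, preventing `z = o/e` blow-ups at the
  envelope fringe, and making the binarized niches (below) meaningful.

Corrected occupancy `z = o/e` (zero where `e` is absent) is rescaled to a
maximum of 1. The corrected surface is what all metrics operate on; the
uncorrected `o` is retained for plotting. Occupancy-density choices beyond
Gaussian kernels are out of scope.

## Niche metrics

Schoener's D normalizes each `z` to unit mass over the analogue mask and
returns `1 − ½Σ|p₁ − p₂|`; it is symmetric and invariant to positive
rescaling of either surface. The analogue mask at quantile 0 is the joint
availability support; at q > 0 each range additionally drops cells below
its own q-th availability quantile (computed over positive cells only).

For expansion / maximum niche stability / unfilling the niches are
binarized at `z > 0` by default. A configurable occupancy-mass threshold
(e.g. 0.05 drops the weakest cells jointly holding 5% of occupancy mass)
is offered because KDE tails otherwise inflate niche extent; the default
stays 0 and is logged. Edge conventions: an empty analogue mask is an
error; a native niche wholly outside analogue space is an error; an
invasive niche wholly outside analogue space yields expansion = 1,
stability = 0 with a warning (the pattern a fresh introduction into
non-native-like conditions produces). Expansion + stability = 1 exactly
whenever invasive occupancy intersects the mask.

## Permutation tests

Equivalency: pooled occurrence scores are reallocated between the two
entities (sizes preserved), both occupancy surfaces rebuilt (availability
surfaces held fixed), and D recomputed; the default one-tailed direction
rejects when the observed overlap is *lower* than the null. An exhaustive
mode enumerates all distinct splits for tiny samples. Similarity: entity
2's occupancy surface is translated so its mass centroid lands on a
uniformly random cell of its own available space, truncated mass is
zeroed, and the one-tailed p is small when the observed overlap is
*higher* than chance placement; a "both directions" analysis is two calls
with the roles swapped. p-values use `(1 + b)/(n_perm + 1)` so they are
never zero; n_perm defaults to 99 (configurable). Because the equivalency
null is exchangeable, the test is exact: its type-I error at α = 0.05 is
verified against the binomial interval over 200 null simulations.

## Temporal dynamics and marginality sweep

Yearly series compare the cumulative dated invasive records up to each
year against the fixed native surface, reusing one PCA, one availability
surface and one bandwidth (taken from the full dated set) so that
year-to-year changes reflect accumulating occurrences only. Undated
records are excluded from this analysis only. An alternative
year-vs-previous-cumulative overlap is available via the series' columns.
The marginality sweep recomputes the indices at intersect quantiles
0 / 0.1 / 0.2 by default; a quantile with an empty mask yields a flagged
all-NaN row rather than fabricated numbers.

## Ensemble distribution models

Per dataset: pseudo-absences are drawn uniformly without replacement from
valid cells holding no presence, at 5× the presence count, and redrawn for
every repetition (resampling honestly dominates the ensemble variance);
splits are 75/25 stratified to preserve the class ratio. Learners:
gradient-boosted trees and random forests (scikit-learn defaults,
seeded), and a declared MaxEnt surrogate — an L1-regularized
presence-vs-background logistic model over linear + quadratic features —
behind a pluggable scorer interface. AUC is the rank-based Mann–Whitney
statistic on the held-out quarter (ties ½). Each run is binarized at its
own max-sensitivity+specificity threshold chosen among midpoints of its
training scores (ties resolve to the lowest threshold, favouring
sensitivity). Consensus requires strictly more than half of the runs; a
15/30 tie is absence. Projection applies every run's scorer and threshold
to the other range (identical layer names/order required). The risk
overlay partitions valid cells into both / native-only / invasive-only /
neither, with high risk the union of the first three. Variable-importance
analysis and spatial-block cross-validation are out of scope.

## Synthetic scenarios and what they show

Layers are planar gradients (direction rotating per layer), each
normalized to [0, 1] before weighting, plus seeded white noise smoothed by
two passes of a 3×3 mean filter (simple, reproducible spatial
autocorrelation). Because the k layers are functions of a 2-d landscape,
an arbitrary k-vector need not be a realizable environment; scenario
niches can therefore be anchored to the gradient values of chosen grid
cells (`native_centre_cell` / `invaded_centre_cell`), guaranteeing the
true niche exists on the map and making the implied shift exactly known.
True suitability is a product of per-layer Gaussians; records are drawn
with probability proportional to suitability (cell centres, possibly
several per cell before rarefaction), and invaded-range records can be
restricted to a radially growing disc around an introduction cell with
per-year counts growing linearly — a stylized citizen-science record
stream.

Standard study conditions used by the tests and the acceptance script,
chosen once as representative:

* conserved-niche scenario: 32×32 grid, 4 layers, noise 0.1, breadth 0.25,
  300 native / 400 invaded records;
* radial-spread scenario: as above with 600 invaded records, introduction
  at the grid centre, 2 cells/year over 8 years;
* fully shifted scenario: breadth 0.08 with centres anchored to opposite
  grid corners, so the occupied envelopes are disjoint while availability
  is shared;
* sharp well-sampled scenario for the reciprocal models: 56×56 grid,
  breadth 0.08, noise 0.02, 400 records per range.

These sizes keep a full validation run within minutes on one CPU while
leaving every effect far above sampling noise.

What passing tests show: the estimators recover known truth — a zero
shift yields near-zero expansion and high D; a disjoint shift yields the
all-expansion/all-unfilling signature; unfilling declines monotonically
under radial spread; reciprocal ensembles cover a conserved niche's other
range and miss a shifted one. What they do not show: behaviour under real
sampling pathologies (spatially biased effort beyond
suitability-weighting, label noise, non-Gaussian niches, strongly
non-stationary layers) or the numeric values any particular real dataset
would produce — those depend on the actual layers, record sets and
preprocessing choices.

## Known limitations

* Two ordination axes only; variance in higher components is ignored.
* The MaxEnt surrogate is not the reference MaxEnt implementation (no
  hinge/threshold/product features, different regularization path).
* The similarity null translates a surface rigidly; it does not reshape
  it to the local availability structure.
* Occupancy correction divides two KDEs; despite the floors, `z` near the
  support edge is less reliable than in the core, which is why the
  marginality sweep and the optional occupancy-mass threshold exist.
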