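# Methods

This note records the models and procedures the package implements, the
assumptions behind them, and the choices made where the design was
genuinely open.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Scope and data model

The package operates on three inputs: a georeferenced table of wild
populations, a stack of gridded environmental layers in three components
(bioclimatic, edaphic, geophysic; 2.5 arc-min cells by default), and a
table of trait-evaluated accessions with 0–100 disease severity ratings
(DSr).  Coordinates are WGS84 decimal degrees.  Grid cells are addressed
by center and all point extraction is nearest-center — an ELC map is a
per-cell categorical surface, so interpolating between cells would mix
categories.  Missing values are an explicit sentinel (NaN internally,
−9999 in files), never 0: a category of 0 and a missing value both mean
"no data" and such sites are excluded from every selection.  Genebank
holdings are recognized purely by the `GE` identifier prefix.

Raster I/O supports ESRI ASCII grids (a self-describing text format) and
GeoTIFF through `tifffile`, with the grid spec carried in the TIFF
ImageDescription tag; the package does not emit the full GeoTIFF geo-tag
set, which none of its own stages require.

## Aridity indices and rule tables

The De Martonne aridity index is P/(T+10) with P in mm/yr and T in °C;
the monthly form is 12·P<sub>m</sub>/(T<sub>m</sub>+10) with
P<sub>m</sub> the *monthly* precipitation, and the flowering-season index
is the mean of the four monthly indices for March–June (the lentil
flowering window).  Whether the monthly form's numerator is monthly or
annual precipitation is a recurring ambiguity in applied work; the
package reads it as monthly, which makes twelve constant months reproduce
the annual index exactly (an identity the tests verify), and exposes
`monthly_precip_is_annual`-style reinterpretation simply by passing
different columns.  Temperatures at or below −10 °C make the denominator
non-positive; the index is then undefined and the package raises rather
than clamping — no site in the intended domain approaches that value, but
the contract is total.

Three rule tables classify sites.  All interval bins are left-closed and
right-open (`10 ≤ I < 20` style), matching the printed aridity bins;
the same convention is applied to the salinity bins at 2/4/8/16 dS/m,
whose source prints bare ranges ("2–4").  The five-way texture scheme
(Clay; Silty Clay; Sandy Clay; Silty Clay Loam; Other) is evaluated in
fixed row order with first match winning; on the 1 %-step composition
simplex the printed predicates never overlap (verified exhaustively
against a brute-force oracle), but the order is pinned for safety.
Compositions must sum to 100 ± 2 %, absorbing rounding in soil
databases.

## Variable selection

A random forest classifies occurrence cells against randomly drawn
background cells (default 10× the presences) from the stack's valid,
unoccupied cells; excluding occupied cells from the background pool
matters, because identical feature vectors with conflicting labels turn
the importance signal into noise.  Importance is the classical mean
decrease in accuracy: per tree, out-of-bag accuracy before minus after
permuting one variable, averaged over trees.  An alternative multiclass
response on taxon identity is available (`response="taxon"`); the
presence/background form is the default because it matches
"explaining the distribution" semantics and works for single-taxon runs.
Longitude and latitude participate as geophysic candidates.

Pruning takes the top 15 variables per component by MDA and scans them in
decreasing order, retaining a variable only if its Pearson |r| with every
already-retained variable of the same component is ≤ 0.5 or the
correlation is not significant at α = 0.05.  Correlations are computed on
the occurrence-site values, not the whole grid, since selection concerns
the populations' environmental space.  MDA ties break lexicographically
by name so output is order-invariant.  Whether the "top 15" applies per
component or to a pooled edaphic+geophysic set is ambiguous; per-component
is the default, `pooled=True` is available.

## ELC map

Each component's retained layers are z-standardized per layer (mm and °C
must not compete on raw scale) and clustered with k-means (25 restarts,
seeded) for k = 1…6.  The elbow rule picks the smallest k ≥ 2 whose next
decrease in within-cluster sum of squares falls below half the previous
decrease; if never satisfied, k = 6.  The inequality can also be read as
"decrease < 50 % of the current WSS"; that reading is available as
`rule="absolute"`.  Constant (zero-variance) data makes every decrease
zero and the rule vacuous; the package returns k = 1 there instead of the
max-k fallback.  Clustering runs over all valid territory cells (an ELC
map covers the territory); occurrence-only clustering can be had by
masking the stack.

Categories are the realized (bioclimatic, edaphic, geophysic) cluster
triples, densely renumbered 1…n in sorted-triple order so reruns are
comparable; the legend is a recorded bijection.  Any original map's
arbitrary category numbering is not reconstructable and is not claimed.
Cells missing any component get category 0, and populations landing on
category-0 cells are flagged excluded.

## Environmental filtering

Drought: I<sub>ar</sub>DM < 15, then I<sub>ar</sub>DM<sub>f</sub> < 15,
ranked ascending by the flowering index (most arid first), ties broken by
the annual index and then population id.  Salinity: topsoil conductivity
> 4 dS/m; when that tier is empty the fallback tier 2 < ec < 4 fires, and
the output records which tier produced it.  Waterlogging: texture in the
four poorly draining classes, then I<sub>ar</sub>DM > 25, wettest first.
All comparators are strict, as the source phrases them ("below 15",
"> 25"), and the applied criteria are recorded on the selection object.

When more than 30 candidates qualify, per-ELC-category quotas are
proportional to category counts.  The quota rounding minimizes
Σ|alloc − cap·n<sub>c</sub>/n| subject to the quota bounds and, when the
cap permits, at least one member per represented category; because the
objective is separable and convex, greedy marginal allocation is exactly
optimal and coincides with largest-remainder (Hamilton) rounding when the
bounds are slack.  Ties go to the larger category, then the smaller
category id.  The proportionality algorithm is not specified by the
method's sources; Hamilton is the least-surprising choice and is verified
against an exhaustive oracle in the tests.

## Calibration

Resistant means DSr *strictly* below the empirical first-decile threshold
(linear-interpolation, type-7 quantile).  The strict inequality excludes
boundary ties, keeping the resistant class within the decile even when
several accessions share the threshold value; the quantile is a parameter
so alternative cutoffs (17 %, 35 %, 50 %) are one argument away.

The suite runs nine algorithm families.  GLM, GBM, CTA, ANN and RF are
the scikit-learn estimators (logistic regression, gradient boosting,
CART, a single-hidden-layer perceptron, random forest).  GAM is a
per-feature cubic B-spline basis with L2-penalized logistic regression;
MARS is a hinge-basis expansion at quantile knots with logistic
regression; FDA is linear discriminant analysis on the same hinge basis —
the adaptive-spline discriminant family implemented directly, since no
dedicated GAM/MARS package is a dependency.  SRE is the Bioclim-style
surface range envelope: presence iff every variable lies inside the
per-variable 2.5–97.5 % training-presence quantile box, suitability the
fraction of variables inside.  Hyperparameters live in one block
(`make_algorithm`) so they are auditable.

Presences and absences get equal total weight: `class_weight="balanced"`
where supported, balanced sample weights for boosting, equal priors for
the discriminant, and seeded minority oversampling for the perceptron
(which accepts no weights).  Splits are 75/25, stratified by class —
unstratified splits can empty the rare class; `stratify=False` is
available.  The cutoff is the training-set TSS-maximizing threshold
(scores are scanned at midpoints between distinct values), and the
held-out TSS is computed at that cutoff, so test performance reflects an
honestly pre-committed decision rule.  Mean TSS per algorithm is binned
Fail < 0.2 ≤ Poor < 0.4 ≤ Fair < 0.6 ≤ Good < 0.8 ≤ Excellent.

Permutation importance of a fitted run is the mean over shuffles of
1 − corr(intact predictions, shuffled-variable predictions), clipped to
[0, 1] — the convention of the ensemble modeling frameworks this suite
mirrors.  A variable the model never touches scores exactly 0; constant
predictions score 0 everywhere.

Model selection is reported, not automated: the top three algorithms by
mean TSS come with importance tables, and the caller may override the
argmax (`choose=`) when, e.g., a model driven almost entirely by a
positional variable is not biologically meaningful.  If every algorithm's
mean TSS is below 0.2 the trait is declared unmodelable and no projection
is made.  Otherwise the chosen algorithm's highest-TSS run is projected:
suitability is the model score scaled affinely to 0–1000 (rank-preserving,
so top-N membership is identical on raw or scaled outputs), labels are
strict-above-cutoff, and the top 30 resistant-labelled populations form
the screening subset.

## Synthetic data

The generator fabricates what the pipeline consumes, with all ground
truth recorded: per-component zone grids (axis-aligned contiguous bands —
row bands for bioclimatic, column bands for edaphic, fine cycling row
sub-bands for geophysic, so mosaics are spatial, not shuffled pixels),
layer values equal to zone-center coordinates plus white noise, and
cluster centers at scaled unit vectors so all pairwise center distances
are equal — the cleanest geometry for testing cluster-count recovery,
because the elbow rule's successive WSS decreases are then equal until
the true k and collapse after it.  Occurrence cells are drawn without
replacement with probability ∝ exp(β·z(informative layers)); β = 0 gives
uniform occupancy.  DSr = 100·(1 − logistic(η)) + N(0, σ) clipped to
[0, 100], with η a linear function of standardized site environment, so
high linear predictor means the resistant end.  Gaussian-then-clip noise
was chosen over a Beta model for transparent moment control.  One master
seed fans out to named substreams (stack / occurrences / DSr) so stages
regenerate independently.

The "study" flavor maps latent values affinely to physical names and
units (annual temperature and precipitation, topsoil clay/silt/EC,
radiation), derives monthly precipitation and temperature from the annual
layers through a fixed Mediterranean-flavored seasonal profile, and
derives sand as 100 − clay − silt so compositions stay valid.
Z-standardization before clustering makes recovery invariant to these
affine maps.  None of this imitates real European climate gradients or
real *Lens* niche envelopes: passing tests demonstrate that the
algorithms recover known structure under controlled conditions, not that
any particular real landscape would yield the same subset sizes or TSS
values.

## Problem sizes and determinism

Default test and acceptance problem sizes are the package's own scaled
study design: 36×36 grids (1296 cells), 624 populations, 351 evaluated
accessions, 25 suite runs per algorithm, 25-seed recovery replicates.
These sizes keep the full suite and the acceptance script comfortable on
a single CPU while leaving every statistical property testable.  All
stochastic stages consume named substreams of one seed; reruns with the
same seed are byte-identical, and the pipeline writes a manifest (seed,
parameters, per-stage row counts) from which any output can be
regenerated.

## Known limitations

* The GAM/FDA/MARS implementations are deliberately compact basis-expansion
  models, not full backfitting or forward/backward MARS; they represent
  their families' inductive bias without claiming feature parity.
* Real applications depend on continental-scale layer archives (WorldClim,
  harmonized soil databases) and on curated evaluation datasets; the
  package verifies its *procedures* on ground-truthed synthetic data and
  on structurally mirrored fixtures, and makes no claim about the subset
  sizes or TSS values any particular real landscape would yield.
* No spatial cross-validation: split randomness ignores spatial
  autocorrelation, as in the mirrored design.
* No coordinate cleaning or occurrence-database construction; inputs are
  assumed deduplicated and georeferenced upstream.
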