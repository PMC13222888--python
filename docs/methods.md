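# Methods

This note documents the models and procedures implemented in `ldrank`, the
parameters that matter, the numerical conventions, and what the synthetic
test bed does and does not establish.

## Land-cover change model

Two epochs of an integer category raster are compared cell by cell on the
six major categories (cropland, forest, grassland, water bodies, bare
areas, impervious surfaces; codes 1–6 by default, overridable through
`ClassScheme`). Fine classification products are first merged into these
categories through a `ReclassMap` (CSV: `fine_code, major_code`); the merge
fails loudly, naming code and cell count, if a fine code has no entry.

The transition matrix S holds S_ij = cell_area × (number of cells that are
class i in the first epoch and class j in the second). Only cells valid in
**both** epochs enter any area or denominator; a cell that is nodata in
either epoch is excluded everywhere. Two conservation identities follow
directly and are enforced by tests: row i of S sums to the first-epoch area
of class i over jointly valid cells, and the grand total of S equals the
jointly valid area.

Change labels: *degradation* iff source ∈ {grassland, forest, water} and
target ∈ {cropland, bare, impervious}; *restoration* iff source ∈
{cropland, bare} and target ∈ {grassland, forest, water}; *stable* iff
source = target; anything else is *other change*. Label areas equal the
corresponding block sums of S exactly.

**Annual change rate.** rate = 100 × (changed area / jointly valid area) /
period length (years), in % yr⁻¹. This is the simplest rate consistent
with treating the degraded share of the study area as accruing uniformly
over the period. "Net" LD/LR areas are reported as the total degraded
(restored) area over the period; the package does not subtract
re-conversions within a period, and both totals are labelled explicitly so
the distinction stays visible.

**Distance surfaces.** Distance-to-class indicators are exact Euclidean
distances between cell centres (scipy's exact EDT with the cell side
sqrt(cell_area) as sampling), in km, zero on source cells. Grids are
treated as planar; no geodesic correction, which is adequate for
county-scale rasters and exact for the synthetic grids.

## Driver table preprocessing

Indicators carry metadata (name, group ∈ {natural, human, economic,
urbanisation}, unit, orientation ∈ {direct, inverse}). The default
twelve-indicator configuration is 2 natural (mean temperature, total
precipitation), 2 human (population and sheep density), 4 economic (GDP
densities of the primary/secondary/tertiary industries and total), 4
urbanisation (distances to urban land, rural settlements, roads, other
built-up land), with precipitation and the four distances inverse-oriented.

Zonal means average raster cells per county, ignoring NaN/nodata; an empty
zone is an error naming the unit. Station data are gridded by inverse
distance weighting, w_k = d_k^(−p), using **all** samples and default power
p = 2 — the standard choice when no calibration information exists; both
are configurable. IDW output is a convex combination of the samples, hence
bounded by their range, and reproduces a sample exactly when a cell centre
coincides with it.

Normalization is per-column min–max to [0, 1]. A constant column maps to
0.5 everywhere: any constant leaves every pairwise comparison on that
column tied, and 0.5 keeps the column visibly neutral in exports.
Orientation flips inverse columns v ↦ 1 − v after normalization; the
`oriented` flag makes the table's state explicit, and orienting twice is an
error rather than a silent undo (the flip is an involution).

The collinearity screen reports pairwise Pearson r between two groups
(default economic vs urbanisation) with a |r| ≥ 0.7 flag, the conventional
threshold above which collinearity starts to distort multi-indicator
rankings; zero-variance columns yield an undefined r, reported and flagged
rather than dropped silently.

## Partial order and Hasse diagram

Counties are compared componentwise (x ≥ y iff every oriented indicator of
x is ≥ that of y). Ties: counties with identical vectors are collapsed into
equivalence classes *before* ordering — otherwise mutual ≤ between distinct
counties would break antisymmetry — and all members inherit their
representative's level and rank. Equality is exact floating-point equality
by default; an optional tolerance ε merges near-ties but makes the induced
relation only approximately transitive, so it defaults to 0 (on normalized
tables exact ties come from genuinely identical inputs; `Poset.validate()`
checks the order axioms by enumeration if ε is used).

The Hasse diagram is the transitive reduction: (a, b) is a cover iff a < b
with no c strictly between, computed by the definitional middle-element
scan (O(n³), trivial at n ≤ a few hundred; an independent networkx-based
oracle cross-checks it in the tests). Levels are counted **top-down**:
depth(x) is the longest upward cover-path from x to a maximal element,
L = 1 + max depth, level(x) = L − depth(x). This puts every maximal
(undominated) element at the top level L and is the convention under which
"higher level = dominated by fewer counties = stronger influence" reads
correctly. A cycle in the covers (impossible for a valid order, possible
for hand-supplied relations) raises.

Maximal chains are all source-to-sink paths of the cover DAG with ≥ 2
elements. Isolated elements — incomparable with everything — sit at the top
level by the depth formula but are excluded from chains and flagged
separately, since "undominated because extreme/incommensurable" is
management-relevant information distinct from "dominating".

Average ranks use LPOM0, Rav(x) = (S+1)(N+1)/(N+1−U), a standard local
closed form for the mean rank over all linear extensions; it is exact on
chains and antichains (verified against full linear-extension enumeration
up to N = 8) and an approximation elsewhere. Exact linear-extension
counting is deliberately out of scope beyond the N ≤ 8 test oracle.

## Dominance attribution

Each driver group gets its own poset/diagram on its own indicator columns.
A county's height in group g is scored to [0, 1]:

- `level_height` (default): (level − 1)/(L − 1); a one-level diagram scores
  0.5 for everyone, so a structureless group neither wins nor loses.
- `lpom_norm`: (Rav − 1)/(N − 1), the LPOM0 rank rescaled; finer-grained
  because it uses S and U, not just the level; 0.5 when N = 1.

The dominant set of a county is {g : score_g ≥ max score − tie_tol};
tie_tol = 0 gives the argmax set, and co-dominance (several groups tied at
the maximum) is kept rather than broken arbitrarily. Region summaries count
counties per (region, group) with the group in the dominant set, so rows
can sum to more than the number of counties exactly when ties occur.

The attribution rule is a documented operationalization of "higher Hasse
level = stronger influence"; the method and tolerance are configuration
arguments precisely because the mapping from diagram position to a single
dominant label admits alternatives.

## Synthetic scenarios and what they show

The generator emulates the study design, not real geography: counties are
contiguous rectangular blocks on a grid; each county u has a planted
dominant group g*(u) (default: round-robin over the four groups). On a
latent influence scale, indicators of g*(u) sit at base + δ, others at
base, all jittered with iid N(0, σ²); the latent values are then mapped to
plausible raw units per indicator with *decreasing* maps for
inverse-oriented indicators, so normalization and orientation are both
genuinely exercised (normalization is affine-invariant, so these scales are
cosmetic). Defaults: 20 counties on a 50 × 50 grid, δ = 0.5, σ = 0.05,
five regions — a clearly separated but noisy scenario.

Land-cover pairs: epoch 1 draws each cell iid from a stated class mixture
(default grassland-dominated, 40%); epoch 2 flips each cell of class i to
class j independently with probability p_ij (default regime: grassland →
cropland 0.2, forest → cropland 0.05, cropland → grassland 0.1, bare →
grassland 0.1 over a 10-year period, i.e. expected LD rate 0.875 % yr⁻¹
and LR rate 0.35 % yr⁻¹). The truth JSON records the planted dominants,
the region map and the expected LD/LR areas/rates implied by mixture ×
probabilities; measured counts are binomial around them.

One `SeedSequence` per scenario spawns independent substreams per generator
(zones, drivers, land cover), so outputs are reproducible bit-for-bit under
a fixed seed and adding a generator never perturbs existing ones.

What passing tests show: the pipeline recovers planted structure —
noise-free recovery is exact, and at δ = 0.5, σ = 0.05 with 20 counties the
planted group is in the dominant set for ≈ 99% of county-seed combinations
(measured over 200 seeds). What they do not show: robustness to spatially
autocorrelated noise, correlated indicators, non-rectangular counties,
class mixtures drifting between epochs, or indicator sets whose groups
overlap semantically — real data have all of these, and the generator
deliberately omits them (iid noise and iid cells keep the planted truth
analytically checkable).

## Problem sizes and numerical conventions

Test and acceptance runs use desk-scale sizes chosen to keep the whole
suite fast while leaving the statistics meaningful: random posets of ≤ 8
elements (500 for oracle equivalence — small enough for exhaustive path
enumeration and linear-extension counting), 20-county driver tables over
200 seeds for recovery rates, and 50 × 50 grids (2 500 iid cells) for
transition statistics, where the 99% binomial interval around p = 0.2 is
±2 percentage points.

Degenerate inputs are handled by stated convention rather than by error
where a convention is defensible: constant indicator columns → 0.5;
one-level diagrams and singleton posets → score 0.5; single IDW sample →
constant field. Errors are reserved for contract violations (unmapped
codes, shape mismatches, empty zones, orienting twice, cyclic relations,
all-nodata maps).

## Known limitations

- The change model sees only class transitions; within-class degradation
  (productivity decline without a class change) is invisible to it.
- LPOM0 is an approximation between the chain and antichain extremes;
  rankings from Rav and from levels can disagree on intermediate posets,
  which is why the scoring method is explicit configuration.
- A positive comparison tolerance ε trades exactness of the order axioms
  for robustness to measurement noise; the default keeps the axioms exact.
- Grid I/O is limited to the Esri ASCII format (plain text, explicit
  nodata); georeferenced binary formats are out of scope.
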