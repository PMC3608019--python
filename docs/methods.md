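# Methods

`refugia` reconstructs the glacial-refugium history of a group of parapatric
species from two independent lines of evidence: the spatial structure of
mitochondrial genetic variation, and habitat-suitability models projected
onto glacial-maximum climate.  This note documents the models, the
parameters that matter, the synthetic study systems the package tests
itself against, and the numerical choices behind both.

## The genetic landscape

The unit of observation is a one-locus alignment of equal-length
mitochondrial sequences (the reference configuration uses 658 bp, a typical
protein-coding mtDNA fragment), each joined to an individual, a sampled
population with coordinates, and a species label.

**Haplotypes and distances.**  Identical sequences — compared literally,
including `N` and gap characters — collapse to haplotypes.  All distances
are uncorrected: the mismatch count, or the proportion of mismatched sites
(p-distance), with *pairwise deletion* of any site where either sequence is
ambiguous or gapped.  No substitution-model correction is applied; the
divergences involved are shallow and every downstream statistic is defined
on raw mismatches.

**Lineage assignment and introgression.**  Haplotypes are placed on a
neighbor-joining tree (classical Saitou–Nei agglomeration on p-distances)
rooted on a designated outgroup at the midpoint of its pendant edge.  The
implementation is exactly deterministic: ties in the Q criterion are broken
by the lexicographically smallest pair of cluster labels, and negative
branch-length estimates are clamped to zero.  Bootstrap support resamples
alignment columns with replacement, rebuilds the tree per replicate, and
reports the percentage of replicates containing each reference bipartition
(1000 replicates and an 80% significance convention are the defaults).

Each species' mitochondrial clade is delimited as the smallest clade
containing all its *seed* haplotypes.  Seeds are haplotypes carried
exclusively by that species' individuals; a species with no pure haplotype
falls back to majority carriage.  Seeding on pure haplotypes (rather than
majority carriage directly) matters precisely in the situation the tool is
built to detect: a haplotype copied across a species boundary has mixed
carriers, and when many recipients share one donor haplotype a majority
rule can poison the recipient's clade.  A haplotype contained in exactly
one species clade takes that lineage.  A haplotype inside several
overlapping clades, or basal to every crown clade, is flagged *ambiguous*
and assigned the lineage of its nearest (p-distance) unambiguously assigned
haplotype; the monophyly report lists every overlapping clade pair.  An
individual whose haplotype lineage differs from its species label is
*introgressed*; populations are classed `original`, `mixed` or
`introgressed` accordingly.

**Exclusion before spatial statistics.**  Introgressed mitochondria do not
reflect the history of either host or donor, so they are removed before any
spatial statistic.  Two rules are provided: `population` (default) drops
every population containing foreign mtDNA entirely; `individual` drops only
the introgressed individuals.  The default is the stricter reading; the
choice changes the per-species retention counts reported in the run
manifest (kept-for-π ≤ kept-for-Z_i ≤ total, since single-sequence
populations are additionally excluded from π only).

**The two statistics.**
* π — within-population diversity: the mean number of pairwise differences
  over all n(n−1)/2 unordered individual pairs of a population (units:
  nucleotide differences).  Computed in haplotype-frequency-weighted form
  Σ_{i<j} c_i c_j d_ij / C(n,2); a brute-force pair enumeration serves as
  the test oracle.  Populations with a single retained sequence are skipped
  (π would be trivially zero).
* Z_i — among-population divergence: populations of one species are joined
  by a planar Delaunay triangulation of their coordinates, and each edge
  carries the mean proportion of mismatched sites over all cross-population
  sequence pairs, placed at the arithmetic midpoint of the edge.
  Degenerate geometries fall back deterministically (two populations → the
  single edge; collinear sets → the path graph; duplicate coordinates →
  a logged 1e-6-degree jitter).

**Surfaces.**  Both point sets are interpolated on the full grid by inverse
distance weighting (power 2, 12 nearest neighbours by default — the
defaults of the GIS tooling this follows; both configurable), then cropped
to the species' range polygon; interpolation precedes cropping, so midpoint
values outside the range are used while interpolating but not shown.
Distances are planar degrees: adequate at the synthetic extent (~3°);
`buffer` distances for the SDM arm apply a cosine-latitude correction where
kilometres matter.  Composite maps min–max rescale the per-species surfaces
to [0, 1] either on one *global* scale (comparable across species, at the
risk of flattening genetically poor species) or *per species*; an
all-constant surface maps to 0.5 by convention.

## The distribution-modelling arm

**Screening.**  Climate layers are screened for collinearity by a greedy
pass in a priority order (first = most biologically meaningful): a layer is
retained iff its absolute Pearson correlation with every already-retained
layer, over background cells, stays below 0.7.

**Background.**  Pseudo-absences are sampled uniformly from the cells whose
centers lie within a fixed-radius buffer (200 km for real continental data;
50 km in the scaled-down synthetic configuration) of any known locality of
the whole species group — the area plausibly accessible to the genus.

**The model.**  Habitat suitability is a Gibbs distribution over background
cells with a linear predictor η(x) in *hinge features* of each variable:
forward hinges max(0, x−k)/(max−k) and reverse hinges max(0, k−x)/(k−min),
knots at equally spaced quantiles of the background values (30 per
direction by default; 4 in the scaled-down pipeline configuration).
Evaluation clamps inputs into the background envelope, so projections onto
out-of-range (e.g. glacial) climates behave like range-edge values.  Hinge
features only: piecewise-linear responses give smooth, monotone-trend fits
that transfer across time better than wiggly feature classes.

Fitting maximizes the L1-penalized log-likelihood

    Σ_presence η(x) − n_p · log Σ_background exp(η(x)) − Σ_j λ_j |w_j|

with λ_j = β · s_j/√n_p, where s_j is the feature's standard deviation over
presences (floored at 0.05 so the penalty never vanishes and β→∞ genuinely
collapses the model to the uniform background distribution) and β = 1 by
default.  The objective is concave; it is solved by splitting each weight
into positive and negative parts and running box-constrained L-BFGS-B, with
the gradient tolerance scaled by n_p (gradient entries grow linearly with
the presence count).  A dense brute-force weight grid on a 12-cell toy
problem is kept as the optimality oracle in the tests.

Outputs: the *raw* output exp(η−log Z) sums to one over the training
background; the *logistic* output c·raw/(1+c·raw) with c = e^H (H the
entropy of the fitted background distribution) maps suitability into
(0, 1).  Projection onto any scenario stack reuses the training normalizer
and clamps, then crops and composites exactly as the genetic surfaces do.

**Significance.**  Model quality is the training AUC — the exact
Mann–Whitney probability that a presence cell outscores a background cell,
ties counting half; there is deliberately no train/test split.  The
observed AUC is ranked within 99 AUCs of models fitted, with identical
settings and background, to the same number of *random* localities drawn
uniformly from the buffered region; pooled as the 100th value, the model is
significant only if it strictly exceeds the 95th smallest pooled value
(ties count against).  Under the null the observed value is exchangeable
with the replicates, so the type-I error is 5% by construction — the
Monte-Carlo calibration in the acceptance suite checks the implementation,
not the mathematics.  Each species' test uses one fixed background sample;
only the localities are redrawn per replicate.

## The synthetic study systems

The generator produces worlds in which every downstream claim has a ground
truth, emulating the essential features of a continental multi-species
phylogeography:

* **Climate** — per layer, Gaussian-smoothed white noise (correlation
  length 8 cells by default) standardized to mean 0 / sd 1, with a
  requested equicorrelation across layers induced before smoothing
  (achieved within ±0.1) and, optionally, a north→south linear gradient
  blended in.  The glacial counterpart is the same field plus a constant
  per-layer offset — in the reference configuration a −1 sd "cooling" of
  the gradient-bearing first layer.  Grids default to 60×60 cells of 0.05°,
  a deliberately small extent so planar approximations hold.
* **Species** — suitability is a product of Gaussian responses to two or
  more layers (each response peaking at 1); the range mask is suitability
  above a threshold (0.45 default) under current climate, the refugium mask
  additionally under glacial climate (refugium ⊆ range by construction),
  and contact zones are range cells 8-adjacent to another species' range.
  Two species spaced along the first layer's gradient yield the classic
  layout: southern refugia, northward expansion, a parapatric contact band.
* **Sequences** — Jukes–Cantor single-site substitutions, no rate
  heterogeneity, no indels: the pipeline consumes only mismatch counts, so
  a richer model would add nothing testable.  Species ancestors diverge by
  Poisson(40) substitutions (comfortably above the ≥20 sites that make
  flagging unambiguous); each refugium patch gets a founder, refugial
  populations carry a small local radiation around their founder
  (Poisson(mut_rate = 3) substitutions per local lineage, giving refugial
  π of roughly 3–8 differences), and expansion populations carry the
  nearest founder with 0–2 private substitutions shared by the whole
  population — the star-phylogeny footprint of rapid expansion.  With a
  zero mutation rate every species is exactly monomorphic.
* **Introgression** — individuals in contact-zone populations swap their
  whole sequence (maternal inheritance, no recombination) with probability
  0.5 for the haplotype of the donor species' nearest population,
  preferring non-contact donors so the planted sequence provably stays
  present in the donor species.  Every event is logged.
* **Occurrences** — cells sampled without replacement with probability
  proportional to suitability (100 per species by default, proportionate to
  the locality density of real continental datasets at this grid size).

Population placement is stratified (a few populations forced onto contact
cells, about a third onto refugium cells, defaults exposed in the
configuration) so that every regime is represented at n = 18 populations
per species, 5 individuals each.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: no demographically faithful coalescent (no
effective population sizes, migration matrices or selection), no sampling
biases or sequencing error, no spatially anisotropic climate change, no
niche evolution between scenarios, and real mitochondrial data can violate
the clean reciprocal-monophyly-with-recent-introgression structure in ways
the ambiguity flags only partially capture.

## Problem sizes and numerical choices

The test and acceptance runs use scaled-down problem sizes chosen so the
whole battery reruns in minutes: 60×60 grids, two species, 180 sequences,
background samples of 150–400 cells, 4–8 hinge knots per direction, and the
null-model calibration at 200 Monte-Carlo repetitions of the full
99-replicate test (n = 30 localities, two layers).  The reference
configuration's parameters are echoed into every run manifest for
provenance, and all generators are pure functions of (parameters, seed) —
reruns are byte-identical.

Numerical conventions collected in one place: IDW queries within 1e-9
degrees of a sample point return the sample value exactly; NJ tie-breaks
and negative-branch clamping as above; constant layers are dropped from
screening with a warning; background sampling with more cells requested
than available uses all cells with a warning; composite scaling of a
constant surface returns 0.5; the L-BFGS-B stopping criterion is a
projected-gradient norm of 1e-5·n_p with ftol 1e-12.

## Known limitations

* The assignment of haplotypes shared verbatim between species rests on
  clade containment plus the nearest-assigned-neighbour fallback; with very
  high introgression rates or unresolved trees the ambiguity flags should
  be inspected rather than trusted silently.
* Z_i midpoints of long Delaunay edges can fall outside both populations'
  ranges; the crop discards that information by design (interpolate first,
  crop last).
* Training AUC with spatially autocorrelated occurrences is optimistic in
  absolute terms; the null-model rank test is the intended safeguard, and
  no absolute AUC threshold is ever applied.
* Planar-degree distances limit the genetic arm to modest extents; only
  the buffer construction corrects for latitude.
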