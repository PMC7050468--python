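# Methods

`synbiogeo` analyses the biogeography of thermophilic *Synechococcus*
populations sampled as `psaA` amplicons from island-like hot springs. This
note documents the models and procedures implemented, the assumptions behind
them, the defaults and why they were chosen, and what the synthetic test
data can and cannot show.

## High-frequency sequences (HFS)

Raw reads are trimmed to 302 bases from the 5′ end (the amplicon segment
length the design targets); reads that are shorter, or that contain any
character outside ACGT inside the trimmed window, are dropped. Cleaning is
deliberately minimal — no denoising, chimera removal or quality filtering —
because all downstream statistics operate on exact-sequence identity and an
abundance threshold already suppresses singleton sequencing errors.

Identical sequences are collapsed into variants; an HFS-*N* table keeps
variants with at least *N* identical reads summed **across all samples**
(HFS10 for the main analyses, HFS2 for the dispersal analysis, which must
see even rarely shared variants). Thresholding is monotone, so HFS10 ⊆ HFS2
and applying thresholds in sequence equals applying their maximum once.
Variant ids are assigned by descending total count with lexicographic
sequence tie-break, making tables reproducible across platforms.

Lineage assignment (A-like vs B′-like) uses global Hamming identity against
trimmed reference segments. Because variants and references share one fixed
length, alignment-free identity is exact, replacing a local-alignment search
with a dependency-free computation. An exact identity tie between lineages
yields `unassigned` (excluded from lineage-split analyses) with a warning.

## Sharing and distance decay

Sharing between two samples is `100 · 2|Sa ∩ Sb| / (|Sa| + |Sb|)` over the
sets of variants present in each sample. The companion statistic counts the
reads belonging to shared variants in the pair member with the smaller
library (ties broken by lexicographic sample id). Geographic separation is
the haversine great-circle distance on a sphere of radius 6,371,000 m;
replicate samples of one spring are assigned 1 m so they can appear on a
log-distance axis. Samples flagged in the exclusion list (a config input,
never hard-coded) are removed before pairing; with the bundled survey's 21
retained samples this yields C(21,2) = 210 comparisons.

The distance-decay trend is an ordinary least-squares fit of percent shared
against log10(distance in m) — a decision, since a decay curve's functional
form is not fixed by the data — with a two-sided permutation p-value
(sharing values shuffled over pairs, add-one estimator, seedable).

## Endemism classification

Endemism is measured on **reads**, not distinct variants: presence/absence
hides how concentrated a population is in its home basin. After aggregating
variant counts by putative ecotype (PE):

- **endemic**: 100% of reads in one basin;
- **near-endemic**: ≥ 90% (configurable) in one basin;
- **multi-basin**: otherwise;
- **predominant** (orthogonal flag): > 1% of reads of at least one sample;
- **cosmopolitan** (orthogonal flag): > 10 reads per sample in samples of
  at least two basins.

Occasional stray detections (1–2 reads outside the main basin) are governed
by the near-endemic threshold; a `min_pe_reads` noise floor is available in
the pipeline config. Read weighting is the default because it is the point
of the classification, but `pe_abundance(..., weight="variants")` provides
the presence-based alternative (distinct variants per basin) for
comparison, and the PE-by-sample table is written so any other summary can
be computed downstream. The shared-count statistic likewise has a
`mode="variants"` alternative counting distinct shared variants instead of
reads.

PE demarcations are **inputs**. Their source — an external demarcation map,
planted synthetic truth labels, or the bundled single-linkage
identity-threshold clusterer — is recorded in every output, because the
identity clusterer is a geometric stand-in, not an evolutionary demarcation
method.

## Constrained ordination

CCA is implemented from first principles. With abundance matrix Y (samples
× variants), grand total y₊₊, P = Y/y₊₊, row masses r and column masses c:

    Q̄ = D_r^{-1/2} (P − r cᵀ) D_c^{-1/2}

Total inertia is ‖Q̄‖², the matrix chi-square statistic divided by y₊₊.
Environmental columns are weighted-standardized (weights r), multiplied by
√r, and Q̄ is projected onto their span by QR; the fitted matrix's SVD gives
constrained eigenvalues (squared singular values), sample scores and variant
scores. The implementation is invariant to rescaling all counts by a
positive constant and to affine maps of any predictor, and constrained plus
residual eigenvalues sum to the total inertia to 1e-8. Eigenvalues are
verified in the tests against an independently coded dense generalized
eigenproblem and against the standard R implementation (`vegan::cca`) on a
small instance.

Score conventions: variant scores use the "species" scaling (weighted
averages scaled by √eigenvalue), sample scores are linear-combination
scores of unit weighted variance, and parameter arrows are weighted
correlations of the standardized predictors with the sample scores — the
scaling that supports plotting variants and arrows together. Axis signs are
fixed by making the largest-magnitude variant loading positive.

**Marginal constrained variability** of one parameter is 100 × constrained
/ total inertia of the single-parameter model (the marginal, not partial,
reading of a per-parameter percentage table).

**Forward stepwise selection.** At each step the candidate adding the most
constrained inertia is tested by permuting the residuals of the current
(reduced) model and comparing its pseudo-F — added inertia over residual
inertia per residual degree of freedom — against the permutation
distribution of the **maximum** pseudo-F over all remaining candidates.
The max-F null is the package's answer to an otherwise open design
question: testing only the best candidate at nominal α would inflate the
chance of admitting a noise parameter roughly k-fold with k candidates,
whereas the max-F reference keeps the probability of any selection on pure
noise near α (verified by simulation in the acceptance suite). Defaults:
α = 0.05, 999 permutations, seedable; with α ≥ 1 the test is skipped and
selection runs until added inertia is numerically zero.

**Cluster tightness.** A PE's tightness is the mean pairwise Euclidean
distance among its variants' scores on the first two constrained axes (the
plotted plane; the axis count is a parameter). The null draws uniform
same-size subsets of all scored variants without replacement;
p = (1 + #{null ≤ observed}) / (1 + draws), never zero by construction.
Ties within a summation-order float tolerance count as ≤. Singleton PEs
have no defined tightness and get no p-value. Under random demarcations the
p-values are approximately uniform (checked by a Kolmogorov–Smirnov test).

**Weighted density.** Variant scores are projected onto the unit vector of
one parameter's biplot arrow; a Gaussian KDE weighted by each variant's
total read count is evaluated on a grid shared by all PEs, with a single
bandwidth from Silverman's rule on the pooled projections using the Kish
effective sample size. Each curve is renormalized to integrate to exactly 1
on the grid, so curves show *where* a PE sits along the gradient, not how
abundant it is.

## The synthetic community generator

The generator plants known structure so every pipeline stage is testable
without any external data. Its defaults encode the emulated study design:

| parameter | default | rationale |
|---|---|---|
| basins | 7 | regions of the emulated survey |
| springs per basin | 1–5 | survey range |
| replicates per spring | 2 | duplicate mat samples |
| read depth per sample | log-uniform 100–5000 | survey's ~10²–10⁴ span |
| ecotypes | 24 | enough for all dispersal classes at desk scale |
| dispersal classes | endemic 0.60, regional 0.25, cosmopolitan 0.15 | roughly two-thirds of demarcated PEs in such surveys are (near-)endemic |
| niche width | 1 sd (z-scored analytes) | order-unity niche in standardized space |
| regional decay length λ | 50 km | the scale at which sharing collapses in the emulated system |
| variants per ecotype | 1–8 | survey-like HFS counts per PE |
| mutation rate | 0.005/site | ~1.5 substitutions per 302-base variant |

Basin centroids are strung along ~10° of longitude; each basin draws
analyte means once and springs add within-basin noise, making chemistry
basin-correlated. Ecotypes get a home basin, a lineage, and a Gaussian
niche optimum drawn within the observed z-scored environmental range;
expected abundance in a sample is niche response × dispersal kernel
(1 in the home basin; 0, or exp(−d/λ), outside, by class), normalized per
sample. `niche_analytes` can restrict the niche response to a subset of
analytes, turning the rest into pure noise columns — used to plant a single
environmental driver. A lineage-dropout switch can silence one lineage in
one named basin, emulating primer failure of a lineage in one region.

Within-ecotype variant proportions are drawn once per spring from a
truncated stick-breaking prior (Beta(1, 1.5) sticks), so replicates of a
spring share proportions while different springs may be dominated by
different variants — a founder effect. The stick-breaking form is a
stand-in: no within-PE variant abundance distribution is established for
this system, and conclusions that depend on its exact shape should not be
drawn from these simulations. Reads are multinomial at each sample's depth.

Sequences: one random 302-base root per ecotype, mutated from its lineage
anchor (anchors 15% divergent; roots ≥5% divergent from each other by
rejection), variants carrying Binomial(302, rate) substitutions. Alphabet
is ACGT with no indels — the analyses match identical sequences, so indels
would add nothing. No chimeras, quality scores or homopolymer errors are
simulated; the generator therefore cannot exercise denoising behaviour,
and passing tests say nothing about robustness to sequencing error beyond
the HFS abundance threshold.

Determinism: each operation draws from its own seed stream derived from
(seed, stage), so identical (config, seed) gives byte-identical files and
any stage can be re-run in isolation.

## Numerical choices and degenerate inputs

- Eigenvalues below `max(total inertia, 1) × 1e-12` are treated as zero;
  the axis count is capped at min(rank of predictors, samples − 1,
  variants − 1).
- All-zero sample or variant rows are dropped with a warning; a matrix with
  identical sample profiles (zero total inertia) is a degenerate-input
  error, as is a constant predictor column (named in the message).
- Collinear stepwise candidates (orthogonalized norm < 1e-10) are skipped,
  so a duplicated or affinely dependent copy of a selected parameter can
  never enter.
- Permutation p-values use the add-one convention throughout.
- Tie-breaks are deterministic everywhere (variant ordering, smaller-sample
  selection, cluster root choice), so reruns are byte-identical.

## Problem sizes used in the test and acceptance runs

The bundled experiments run at desk scale, chosen as the smallest sizes at
which the planted effects are unambiguous: the reference community
(default config) yields ~50–80 k reads over 46 samples; the driver
community uses 12 ecotypes over ~16 springs; oracle equivalence uses 50
random 5–9 × 5–10 instances; null calibration uses 100 noise datasets for
selection and 200 random demarcations for tightness. Full-survey-scale
inputs (tens of thousands of reads per sample, hundreds of PEs) run through
the same code paths unchanged.

## Known limitations

- The identity-threshold demarcator is a labelled stand-in; real ecotype
  demarcation requires an evolutionary simulation tool, consumed here as an
  external map.
- Tightness and density use the first two constrained axes by default;
  structure on higher axes is invisible to them unless the axis count is
  raised.
- The distance-decay model is linear in log distance; strongly non-monotone
  sharing patterns would need a different trend model.
- Stepwise residual permutation treats weighted residual rows as
  exchangeable, which is approximate when sample masses differ greatly.
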