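# Methods

## Problem and data model

The package scores gene sets ("modules", typically the targets of one
transcription factor) for spatial co-localization on a 3D genome model.  A
model is a set of per-chromosome **anchor points**, each an ordered pair of
a genomic coordinate (bp) and a position in model space (x, y, z).  Two
successive anchors delimit a chromosomal region; anchors need not be
equidistant in bp — experimentally derived models place more points where
chromosomes fold or change direction.  Model-space units are arbitrary; the
nucleus radius is the natural scale.

## Feature placement

Each feature (gene, tRNA, ARS, …) is represented by a single point at its
genomic midpoint ⌊(start+end)/2⌋.  If the midpoint falls between anchors
(b₁, P₁) and (b₂, P₂), the position is the affine combination
(1−t)·P₁ + t·P₂ with t = (bp−b₁)/(b₂−b₁); this is exact at anchors (t = 0
or 1 reproduces the anchor coordinates bit for bit).  Midpoints before the
first or after the last anchor are clamped to the terminal anchor rather
than extrapolated, so mapped points cannot leave the modelled volume.
Strand is carried through the tables but ignored for placement, and
features are points, not intervals, in 3D.  Features on chromosomes absent
from the model are skipped and reported, never silently dropped.

Identifier matching throughout the package is exact after uppercasing;
unmatched module members are counted and reported per module.

## Distances and background

All n(n−1)/2 pairwise Euclidean distances are computed in double precision,
blocked over rows of the coordinate array so peak temporary memory is
O(block_size · n); the result is bit-identical to a naive double loop.  The
condensed vector uses the canonical row-major upper-triangle order
(idx(i,j) = n·i − i(i+1)/2 + j − i − 1, i < j), so external tools and
`scipy.spatial.distance.squareform` can address it directly.  Persistence
is a one-column Parquet table (zstd) with the feature index in the file
metadata; storage precision defaults to single (half the size at ~1e−7
relative error) with a double option.

The background distribution is a 100-bin equal-width histogram on
[0, max distance] (bin count configurable), normalized to integrate to 1,
with the CDF accumulated at the bin edges.

## Co-localization test

For a module with k ≥ 2 matched genes, the sample is its k(k−1)/2 pairwise
distances and the reference is the full condensed vector.  The module's own
pairs stay in the reference by default: at genome scale they are a
vanishing fraction (496 of 42 million for k = 32), and keeping the
reference fixed lets it be sorted once and shared across a batch.

The statistic is the two-sided two-sample Kolmogorov–Smirnov
D = sup|F₁ − F₂|, computed exactly: the supremum of the difference of two
right-continuous step functions is attained at (or just before) a jump, so
evaluating both ECDFs at every distinct sample value and at its left limit
— the left limit equals the value at the largest pooled point below, which
covers reference jumps too — reproduces the exhaustive sup over all pooled
points at O(k² log N) cost instead of O(N).  The p-value is the asymptotic
Kolmogorov distribution evaluated at √(n₁n₂/(n₁+n₂))·D.  p-values are never
truncated to zero (the smallest positive double is reported instead) and
never adjusted below the raw value; Bonferroni adjustment multiplies by the
number of modules **actually tested** in the batch, not the number of TFs
in the input file.  Sidedness is deliberate: D is two-sided ("deviation
from background" in either direction), and the sign is reported separately
as the median shift, module median − background median, negative meaning
co-localization.  Batch results are sorted by descending D with ties broken
by module name, making the output invariant to input order.

### Dependence caveat and the permutation null

The k(k−1)/2 distances of one module are not independent draws — they share
the k gene positions.  The analytic KS p-value treats them as independent
and is therefore anti-conservative: random modules in a small genome can
reach nominally significant analytic p-values.  The permutation null is the
dependence-robust path: it draws random k-gene sets from the same index,
computes their D against the same background, and reports the empirical
p-value (1 + #{D_null ≥ D_obs})/(n_perm + 1).  Because the null resamples
whole gene sets, the dependence structure is identical under the null and
the test is calibrated by construction (verified: the rejection rate of
random modules at α = 0.05 lies inside the exact binomial 99% interval
around the attainable level ⌊α(n_perm+1)⌋/(n_perm+1)).  Recommended use:
rank by analytic D, confirm candidates with the permutation p.

## Synthetic genomes

The generator emulates a Rabl-like interphase nucleus: a sphere of radius
R (default 1.0) with centromeres clustered near one pole and telomeres near
the envelope.  Per chromosome, the centromere anchor is drawn at the pole
point (0, 0, −0.9R) plus isotropic Gaussian jitter (sd 0.1R by default),
and the two arms are fixed-step random walks (step 0.05R) whose directions
mix an isotropic unit vector with a weight-0.8 unit vector pointing away
from the pole; positions crossing the envelope are reflected radially back
inside, so every anchor satisfies ‖P‖ ≤ R exactly.  Anchor genomic
spacings are Gamma(shape 4) with mean 10 kb — positive variance, hence
non-equidistant anchors as in real models.  Genes of 1 kb are tiled every
2 kb with ids `G_<CHROM>_<INDEX>`.  Defaults mimic a yeast-scale genome:
16 chromosomes spread over 200–1500 kb.  Everything is reproducible from a
single mandatory seed.

The pole offset, jitter sd, step length and outward bias were fixed once so
that long arms traverse the nucleus and short chromosomes stay polar, the
geometry that produces the Rabl signature (centromere pairs closer than
telomere pairs; observed ratio ≈ 0.3 across seeds).

What the simulator is **not**: a polymer model.  There is no excluded
volume, no persistence length, no nucleolus or rDNA territory, no
chromosome-specific tethering.  Tests passing on simulated genomes
demonstrate the statistical machinery (calibration, power, ranking,
exactness of the numerics) under a realistic geometry; they do not validate
any biological claim about a real nucleus, which requires an experimentally
derived model as input.

Ground-truth modules: `plant_colocalized_module` samples k features
uniformly from within a given radius of a random focal feature (retrying
focal features up to a bounded attempt count and reporting the largest
achievable k on failure); `sample_random_module` samples k features
uniformly — the null case.

## Problem sizes and numerical choices

The calibrated null and power studies run on an 8-chromosome, 200–500 kb
genome (~1,400 features, ~1M background pairs): large enough that a size-30
module's 435 pairs are a negligible fraction of the background, small
enough to recompute from scratch in seconds.  The pair-count law is
exercised at the full n = 9,185 scale.  Permutation nulls use n_perm = 999;
power studies use 100 replicates of k = 30 modules planted within 0.2R.

Numerical details worth knowing: duplicate model anchors at the same
(chromosome, bp) are collapsed by coordinate averaging (deterministic,
order-independent); interpolation uses (1−t)P₁ + tP₂ precisely for anchor
exactness; the degenerate all-equal distance set yields a single occupied
histogram bin with a well-formed CDF; an all-zero distance set falls back
to a unit axis; empty evidence-filter results are legal and reported;
modules with fewer than two matched genes are flagged untested rather than
failing a batch.

## Limitations

* The analytic KS p-values are anti-conservative under pairwise-distance
  dependence (see above); published per-module p-values computed this way
  should be read as ranking scores unless permutation-confirmed.
* A static 3D model is a population-averaged snapshot; distances on it are
  model-space distances, not physical nanometres, and any finding inherits
  the model's own uncertainty.
* The feature-placement rule (midpoint + linear interpolation) is one
  reasonable convention; placement at gene starts or nearest-anchor
  assignment would differ by at most the inter-anchor spacing.
* GFF3 reading resolves no feature hierarchy; records are selected by type
  only.
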