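# coloc3d

Are the target genes of a common transcription factor scattered at random
through the nucleus, or do they sit close to each other in space?  `coloc3d`
answers this question for any gene list given a 3D genome model — a table of
per-chromosome anchor points, each tying a genomic coordinate (bp) to a
position (x, y, z) in model space, such as the chromosome-conformation-
capture-derived models available for *Saccharomyces cerevisiae*.

The pipeline has three stages:

1. **Mapping.** Every genomic feature is reduced to its midpoint
   ⌊(start+end)/2⌋ and placed on its chromosome's 3D path by linear
   interpolation between the bracketing anchors (clamped at chromosome
   ends).
2. **Distances.** All n(n−1)/2 pairwise Euclidean distances between mapped
   features are computed in double precision and stored as a condensed
   vector (canonical row-major upper-triangle order, the same convention as
   `scipy.spatial.distance.pdist`).  For the full yeast feature set
   (n = 9,185) this is 42,177,520 distances.
3. **Statistics.** For each gene module (e.g. a transcription factor's
   regulon) the distribution of its within-module pairwise distances is
   compared to the background distribution of all pairwise distances with a
   two-sided two-sample Kolmogorov–Smirnov test:

   D = sup<sub>x</sub> | F<sub>module</sub>(x) − F<sub>background</sub>(x) |

   with the asymptotic Kolmogorov p-value at effective sample size
   n₁n₂/(n₁+n₂), Bonferroni-corrected across the m modules actually tested
   (p<sub>adj</sub> = min(1, m·p)).  The sign of the effect is reported as
   the **median shift** (module median distance − background median);
   negative values mean spatial co-localization.

Because pairwise distances within a module are dependent, the analytic KS
p-values are anti-conservative.  The package therefore also provides a
**permutation null**: D statistics of random gene sets of the same size,
giving an empirical p-value (1 + #{D<sub>null</sub> ≥ D<sub>obs</sub>}) /
(n<sub>perm</sub> + 1) that is calibrated by construction.  Use it to
confirm any module the analytic test flags.

A synthetic-genome generator with Rabl-like architecture (centromeres
clustered at one pole of a spherical nucleus, arms random-walking outward,
telomeres near the envelope) makes the whole pipeline testable end to end
without any download, including planting spatially clustered modules as
ground truth.

## Worked example

```python
from coloc3d import (SimulationParams, simulate_genome3d, map_features,
                     pairwise_distances, plant_colocalized_module,
                     test_module)

params = SimulationParams(n_chromosomes=8, chromosome_lengths=[300_000] * 8,
                          seed=42)
model, features = simulate_genome3d(params)
coords = map_features(model, features)
dset = pairwise_distances(coords)
print(f"{coords.n} features mapped, {len(dset):,} pairwise distances")

planted = plant_colocalized_module(coords, k=30, radius=0.2, seed=1)
res = test_module(dset, planted, m=10)
print(f"planted module: D = {res.ks:.3f}, adjusted p = {res.pval_adjusted:.3g}, "
      f"median shift = {res.direction:+.3f}")
```

prints

```
1200 features mapped, 719,400 pairwise distances
planted module: D = 0.643, adjusted p = 1.03e-155, median shift = -0.253
```

The 30 genes planted inside a ball of radius 0.2 (a fifth of the nucleus
radius) have strongly left-shifted pairwise distances: the KS statistic is
large, the adjusted p-value is astronomically small, and the negative
median shift identifies the direction as co-localization.  Random modules
of the same size in the same genome score D ≈ 0.16–0.18 — small, but with
analytic p-values that still look significant because of the dependence
between pairs; their empirical permutation p-values are uniform, which is
why the permutation null is the recommended confirmatory path.

## Command line

```
coloc3d simulate --seed 3 -o model.tsv --out-features genes.gff3
coloc3d map --model model.tsv --features genes.gff3 --class gene -o coords.tsv
coloc3d distances coords.tsv -o dist.parquet --block-size 1000
coloc3d test --distances dist.parquet --genes list.txt --m 176
coloc3d batch --distances dist.parquet --regulons regulons.tsv \
    --evidence binding --min-targets 2 -o results.tsv
coloc3d run --config pipeline.toml
coloc3d plot background --distances dist.parquet -o fig.png
```

Input formats: the model is a tab-separated table (chromosome, bp, x, y, z;
other layouts via a dialect option), features are GFF3 (1-based inclusive)
or BED (0-based half-open, converted on read), regulons are TSV with
columns `tf`, `target`, `evidence` (evidence classes `binding` /
`expression` / `both`, case-insensitive synonyms accepted), gene lists are
one identifier per line.  Results are TSV with columns
`tf, n_targets, n_pairs, ks, pval, pval_adjusted, direction`.

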