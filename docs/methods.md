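# Methods

## Problem and model

Large perturbational gene-expression resources profile RNAi (shRNA) and
CRISPR (sgRNA) reagents as z-score signatures over the 978 L1000 landmark
transcripts, typically from 3 biological replicates per reagent per cell
line. A reagent's signature mixes three reproducible components plus
noise:

* **on-target** — expression changes caused by suppressing the intended
  gene, shared by independent reagents targeting that gene;
* **seed off-target** (shRNA only) — miRNA-like repression driven by the
  seed sequence (nts 2–8 of the targeting strand, corresponding to
  heptamers starting at positions 11–12 of the 21-nt sense strand),
  shared by reagents with the same seed regardless of target gene;
* **generic response** — a single axis along which signatures of all
  perturbation types move, empirically the first principal component
  (PC1) of the collection.

All similarity is Spearman rank correlation in the landmark space.
The package implements the statistical machinery to separate these
components:

1. **modz consensus.** A group of signatures (same target gene → CGS;
   same seed → CSS; or a reagent's replicates) is combined as a weighted
   average. The pairwise Spearman correlation matrix has its diagonal set
   to 0; each member's raw weight is its row sum; negative row sums are
   clipped to 0 and the weights normalized to sum to 1 (equal weights if
   all row sums are ≤ 0). The consensus is therefore always a convex
   combination of its members.
2. **Holdout validation.** For a gene with ≥ 6 reagents in a cell line,
   the reagents are split into two disjoint halves (⌊n/2⌋ / ⌈n/2⌉),
   a consensus is built from each half, and the halves are correlated;
   the statistic is the median over 30 random partitions. A size-matched
   permutation null repeats the computation on random groups drawn one
   reagent per gene (10,000 draws by default; smaller values are used at
   desk scale). p = (1 + #{null ≥ observed}) / (1 + n_null), with ties
   counted as exceeding. Storey q-values (single-λ estimator at λ = 0.5,
   π0 capped at 1) are computed across groups and thresholded at
   q < 0.25.
3. **PC1 removal.** PCA is fitted globally (all signatures, per-gene mean
   centering, SVD); to remove PC1 a signature is centered, its component
   along the PC1 direction subtracted, and the mean added back. The
   operation is idempotent and removes exactly the PC1 variance share.
   Only the first component is removable: the generic response is
   one-dimensional in this model, and removing further components would
   begin to eat perturbation-specific signal.
4. **Projection decomposition.** For each reagent, a unit reference is
   the modz consensus of the *other* same-gene reagents (collapsed
   signatures). The on-target magnitude is
   `a = mean_i (rep_i · ref / ||rep_i||)` over replicates. Residuals
   `res_i = rep_i − (rep_i · ref) ref` give the reproducible off-target
   magnitude `b = sqrt(max(0, mean_{i<j} res_i · res_j /
   (||rep_i|| ||rep_j||)))`. With these definitions `a² + b²` is the
   reproducible fraction of the signature and is bounded by 1
   (Cauchy–Schwarz); the bound is exercised over 10,000 random replicate
   sets in the test suite. Defining `b` as the square root of the mean
   pairwise residual product (rather than the mean itself) is what makes
   the Pythagorean identity hold, and the identity is treated as
   normative. Magnitudes are only reported when the collapsed signature's
   cosine to its reference is significant (q < 0.25) against consensus
   vectors of size-matched unrelated reagent groups (1,000 nulls by
   default) — otherwise the reference is not a trustworthy on-target
   estimate and the decomposition would misattribute on-target signal to
   `b`.
5. **Seed analyses.** Pair-correlation distributions contrast same-gene,
   same-seed (6- and 7-mer), and all pairs within cell lines, excluding
   pairs that share both gene and seed from the focal groups; per-pair
   significance is the upper-tail rank within the all-pairs distribution
   (+1 pseudocount, the focal pair excluded from its own null), with
   Storey q per group. The heptamer window scan groups reagents by each
   7-nt sense-strand window and averages within-group pair correlations.
   The magnitude-consistency F-test compares, for each seed, the variance
   of its per-cell-line mean leave-one-out CSS correlations against the
   variance of the pooled collection of all seed-by-cell-line means
   (one-sided for smaller variance, dof (n_cells − 1, N − 1)); the same
   computation keyed by gene provides the on-target analogue.
6. **Connectivity.** A consensus signature queries a database of
   consensus signatures by Spearman correlation; the designated same-gene
   counterpart's p-value is its score's rank among non-match members, and
   Storey q-values are computed across the queries of a run. Spearman
   correlation is used for consistency with every other similarity in the
   pipeline.

## Synthetic data generator

The generator produces replicate-level datasets with exactly the
structure the analyses assume. Replicate r of reagent j (gene g, seed s,
cell line c):

```
x = alpha_j · u_g + beta_{s,c} · v_s + gamma_j · w + noise − delta · e_g
```

`u_g`, `v_s`, `w` are i.i.d. Gaussian directions normalized to unit
length (isotropic, no hidden structure); noise is i.i.d. N(0, σ²) per
gene; `e_g` depresses the target landmark directly (the first
`n_genes_targeted` landmarks double as target genes so target-rank
analyses need no separate gene universe).

Defaults (z-score units) and rationale:

| parameter | default | meaning |
| --- | --- | --- |
| `n_genes_targeted` | 50 | genes, 6 reagents each |
| `n_cell_lines` / `replicates` | 3 / 3 | typical replicate structure |
| `n_seed_pool` | 40 | seed collisions at a realistic rate; < 1% of reagent pairs share both gene and seed |
| `alpha_on` | 6.5 | on-target scale ≈ 20% of signature length (‖x‖ ≈ 33) |
| `beta_seed` | 10.0 | seed scale ≈ 30% of length — stronger than the gene effect, the defining RNAi pathology; 0 for sgRNA |
| `gamma_pc1` | 10.0 | generic-axis scale; drawn per reagent from an exponential so the axis carries the large across-signature variance that makes it the empirical PC1 (≈ 8% variance share at the defaults, with the 10–20% seen on real collections within reach of the tail) |
| `sigma_noise` | 1.0 | per-gene replicate noise |
| `delta_knockdown` | 4.0 | direct z-score depression of the landmark target |
| `seed_consistent_fraction` | 0.7 | seeds whose β is constant across cell lines (drives the F-test contrast) |
| `dicer_shift_fraction` | 0.2 | shRNAs whose effective seed is written one position downstream (position 12), reflecting heterogeneous Dicer processing |

Per-reagent magnitudes `alpha_j` vary uniformly ±50% around their scale;
per-seed cell-line magnitudes `beta_{s,c}` are constant across cell lines
for the consistent fraction and drawn independently per cell line
otherwise.

Sequence model: each reagent gets a random 21-nt sense strand whose
positions 11–17 (12–18 when Dicer-shifted) carry the reverse complement
of a heptamer drawn from the shared pool, so the recorded seed equals the
reverse complement of that window. Two deliberate choices make the
window scan behave as it does at production scale:

* the off-target pattern `v` attaches to the seed's **6-mer class**
  (nts 1–6 of the heptamer) — the hexamer is the core determinant of
  miRNA-like targeting, and 6-/7-mer analyses give comparable results;
* seed heptamers are drawn with a skewed base composition
  (0.75/0.1/0.1/0.05). A small pool of uniformly random 7-mers almost
  never shares subwords across distinct seeds, whereas a real population
  of thousands of seeds does constantly; without the skew, every window
  partially overlapping the seed region conditions on full seed identity
  and the scan plateaus instead of peaking.

sgRNA datasets reuse the same machinery with `beta_seed = 0`
(`GeneratorConfig.sgrna()`); their seed annotations are inert and provide
the null contrast in which same-seed pairs behave like random pairs.
Passing a previous run's `GroundTruth` as `patterns` reuses its `u`, `v`,
`w`, giving matched shRNA/sgRNA datasets for cross-technology analyses.

What the generator does **not** emulate: strand-loading bias and
sequence thermodynamics; graded partial-seed matches (a pair either
shares the hexamer pattern or not); gene–gene co-regulation (on-target
patterns are isotropic); batch effects beyond the single generic axis;
and realistic signature sparsity. Passing tests therefore demonstrate
that the machinery recovers the structure it models, not that the
biological effect sizes of any particular real dataset will reproduce.

## Numerical and design choices

* Spearman ties get average ranks; constant vectors are assigned
  correlation 0 (a flat profile carries no rank information) rather than
  NaN.
* Gene order is canonicalized (sorted by gene id) when a matrix is
  constructed, making all correlation operations order-safe; GCT files
  are written at `repr` precision so round-trips are bit-exact.
* Replicate collapse uses the same modz weighting as the consensus
  operations; a two-member group always gets equal weights by symmetry.
* `replicate_q75` uses linear interpolation between order statistics.
* Permutation p-values use the +1/(N+1) pseudocount and count ties as
  exceeding (strictly valid, conservative).
* Partition sizes for odd holdout groups are ⌊n/2⌋/⌈n/2⌉; partitions are
  sampled independently without deduplication.
* Storey π0 uses the single-λ estimator at 0.5; the spline-smoothed
  estimator is out of scope.
* The seed-consistency F-test compares each seed against the pooled
  variance of *all* seed-by-cell-line means (the focal seed is not left
  out) — the simplest reading of the population contrast.
* `seed_window_scan` reports positions supported by fewer than
  `min_pairs = 50` pairs (after pooling cell lines) as missing: group
  pairs share reagents, so a mean over a few dozen chance window matches
  is dominated by whichever reagents happen to collide and carries no
  information at desk scale. Set `min_pairs=0` to disable.
* The on-target cross-cell-line filter flags reagents with
  |CSS correlation| < 0.2 and CGS correlation > 0.15; 2×2 contingency
  tables across cell lines use the Haldane–Anscombe 0.5 correction only
  when a cell is empty, so clean tables reproduce the exact odds ratio.
* PC1 sign is fixed so the largest-magnitude loading is positive;
  downstream direction comparisons use absolute cosines. Genes are not
  re-standardized after removal.
* `on_target_filter_crosscell`, `holdout_analysis`,
  `projection_pipeline` and the seed analyses accept replicate-level
  input and collapse it internally when `replicate_group` contains
  multiple members.

## Problem sizes

Tests and the acceptance script run the default study conditions
(50 genes × 6 reagents × 3 cell lines × 3 replicates = 2,700 signatures ×
978 landmarks) for dataset-level properties, 1,000 permutation nulls for
holdout calibration/power (500 for the PC1-removal comparison), and
1,000 null references per projection run; these sizes give stable
directional results on a single CPU while preserving every algorithmic
path of the full-scale analyses.

## Known limitations

* The holdout null pool draws from the same dataset being tested; on very
  small datasets the null and observed groups overlap substantially.
* Storey q-values can reach 0 when every p-value is at the permutation
  floor (π0 estimates to 0); interpret q = 0 as "smaller than resolvable
  at this null size".
* The window scan's support rule trades coverage for stability; sparse
  datasets may report no supported peak.
* Connectivity uses the designated-match rank only; enrichment-style
  weighted connectivity scores are out of scope.
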