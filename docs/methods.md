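# Methods

This note records the models, parameter choices, and numerical conventions
behind each stage, what the synthetic fixtures do and do not emulate, and
the known limitations.

## Gene selection

The selection stage assumes genes acting in a shared developmental program
co-vary across samples. The model is the standard weighted co-expression
construction: unsigned adjacency `|pearson|^β` with soft power β = 10
(default; `SelectionConfig.soft_power`), topological overlap smoothing, and
average-linkage clustering of `1 − TOM`.

Numerical conventions:

* **Missing data.** Genes missing in more than `max_missing_frac` (0.2) of
  samples are dropped; remaining gaps are imputed by the gene mean. Mean
  imputation slightly shrinks correlations toward zero, which is
  conservative for module detection.
* **Sample outliers.** Samples are clustered by average linkage on
  euclidean distance; a sample is removed when its first-merge height
  exceeds mean + 2 sd of all samples' first-merge heights. The statistics
  run on the per-sample heights (not the full set of internal merge
  heights) so a single extreme sample cannot inflate the spread enough to
  mask itself. With few samples this rule is intentionally hard to trigger:
  the maximum standardized height in n values is bounded by √(n−1).
* **Tree cut.** The dynamic-tree-cut family is implemented in its
  static-height form: cut at `cut_height_frac` × (maximum merge height),
  prune clusters below `min_module_size` (30) into an unassigned pool. The
  default cut is 0.95. At cuts very close to 1, chance module-level
  correlations (which the power transform does not fully suppress — a
  chance correlation of 0.7 still yields adjacency ≈ 0.03 and a nonzero
  topological overlap) can place cross-module merges below the cut and fuse
  distinct modules; 0.95 leaves a robust margin while background genes,
  whose overlap with any module is orders of magnitude smaller, still fall
  outside every cluster.
* **Zero-variance genes** get correlation 0 to all partners (flagged by a
  warning), not an exception.
* **Fold-change gate.** Module fold change is the ratio of linear-scale
  means (early over late); values are linearized from log2 when the matrix
  is flagged `log_scale`. The gate is `≥ downreg_fold` (2.0). Because the
  linear mean is dominated by the highest-expressed samples, the ratio is a
  noisy functional of log-scale effects; the gate is a screen, not a test.
* **Time-course DE.** A one-way F-test across time groups on log-scale
  values with Benjamini–Hochberg correction stands in for a full
  count-model fit; it is a replacement for the published differential
  expression tooling, not a reproduction, and requires ≥ 2 replicates per
  group (otherwise the fold-change-only path is the supported route).
* **GO gate.** Upper-tail hypergeometric p per term within the user-supplied
  universe, BH across tested terms, and a mandatory term whitelist
  (mirroring a curated literature-driven term selection). Selected genes
  are the query members of whitelisted terms with q < fdr (0.05).

## Enhancer assignment (ABC)

Candidate elements come either from a user BED/peak file or from the
built-in strongest-window selector: fixed windows (500 bp, step 250 bp)
scored by summed coverage, greedy non-overlapping selection, book-ended
merging, top-n by score with ties broken by coordinate. This is a
deliberate simplification of external peak calling — only the "n strongest
regions" contract matters downstream.

Activity is the geometric mean of accessibility and H3K27ac counts over the
element. Contact uses 5 kb bins and the power-law distance curve
`(res / max(d, res))^γ` with γ = 0.87; when sparse Hi-C counts are given
they are rescaled so their distance-binned mean lies on that curve
(pseudocount 0.3 per bin), and distances with no data fall back to the
curve itself. Matrix balancing (KR/ICE) is out of scope. The candidate
window is ±5 Mb around the TSS; per-gene scores normalize to 1 over all
in-window elements, promoters included. Promoter-flagged elements stay in
the denominator but are excluded from the retained enhancer report, so the
enhancer compartment passed to motif analysis contains no promoter
sequence. Coordinates are 0-based half-open throughout; TSSs are
strand-aware.

## Anchored co-occupancy

Promoters default to 1500 bp upstream / 300 bp downstream of the TSS; a
1000/300 preset mirrors an alternative convention used for whole-promoter
scans, and both appear in the config surface rather than silently picking
one.

PWM scanning: probabilities use a 0.25 pseudocount per base; scores are
log2 odds against a uniform background; the relative score is
`(score − min) / (max − min)` over the attainable score range of the
matrix, and hits require relative score ≥ 0.9 on either strand. Windows
containing N are skipped. Motifs below 8 bits of total information content
are excluded from candidate sets. An optional per-base mask restricts
scanning (e.g. a precomputed conservation mask at the 0.40 cutoff);
conservation itself is not computed here. Thresholds are inclusive (≥) at
8 bits, 0.9 relative score, and Z = 10.

Anchored windows are the union of ±D (default 100 bp) flanks around anchor
hits minus the anchor footprints, clipped to the sequence; a partner hit
counts when its start lies in a window and it does not overlap an anchor
footprint. Enrichment is the binomial Z of the foreground hit count
against the background rate u: `z = (fg − u·fg_nt) / sqrt(fg_nt·u·(1−u))`.

Background modes:

* `shuffle` (default) — seeded per-sequence dinucleotide shuffle
  (Altschul–Erickson), background rate = partner density over the shuffled
  sequences. Self-contained and appropriate for real sequence, where motif
  occurrences arise from sequence composition.
* `outside` — partner density in the same sequences outside the anchor
  windows. This is the right null when occurrences are a per-nucleotide
  process that may differ from composition expectations (as in the planted
  fixtures, where a shuffle would destroy planted instances and overstate
  z); it is what the calibration tests use.
* `regions` — user-supplied background sequences.

The Z-score treats the background rate as known; its null sd therefore
exceeds 1 by roughly `sqrt(1 + fg_nt/bg_nt)`, which is why backgrounds
should be several times larger than the searchable foreground. A one-tailed
Fisher exact p on sequence counts is available as a companion statistic.

Partners are categorized per compartment: `both` when z ≥ 10 in promoters
and enhancers, `promoter_only`/`enhancer_only` accordingly, else `none`;
a TF missing from one compartment is treated as z = −∞ there and flagged.

## TF network

Target sets merge into an undirected graph (duplicate edges collapsed,
self-loops dropped); connectivity is plain degree — the ranking statistic
is not specified beyond "connectivity" in the source protocol, and degree
is the simplest faithful choice (betweenness and weighted variants are
deliberately not implemented). Expansion is a single pass: an external node
joins when it has ≥ `min_links` (2) distinct interaction edges into the
current node set — multi-evidence attachment avoids a halo of degree-1
additions. Shells are equal-frequency bins of the degree-sorted node list
(ties by node id), shell 1 = core; n_shells defaults to 4. Per-subnetwork
motif enrichment scans each batch's promoters against a shuffled background
and reports the per-TF z ranking; batches under 3 genes are skipped.

## In vivo quantification

Inputs are count tables, not images (tracing is manual and blinded in the
source protocol; the module fixes the arithmetic so analyses are
auditable). Medulla total = Σ line counts × (pyramid area / sampled area).
Fiber index at distance d = mean section count at d divided by the medulla
total; it is invariant to a common rescaling of all counts. Branch
frequency = Σ branches / Σ traced length (in mm) over segments ≥ 100 µm;
totals under 5 mm warn but still compute. A per-animal `include` flag
carries the lesion-completeness exclusion criterion. Observer counts are
combined by simple mean.

## Synthetic fixtures

All generators are pure functions of a `FixtureSpec` (bit-reproducible per
seed) and emit exactly the formats the readers consume.

* **Expression**: 2 modules × 40 genes + 40 background genes, 4 time
  points × 3 replicates. Genes in a module share a per-sample latent
  profile (jitter 0.3 log2) plus gene noise (0.05 log2), giving
  intra-module correlations ≈ 0.97; the down module's latent falls 3 log2
  units (8-fold) across the time course, comfortably past the 2-fold gate
  after linear averaging. Centered module profiles are orthogonalized
  against earlier ones: with only 12 samples, chance inter-module
  correlation is otherwise non-negligible, and the fixtures are meant to
  emulate statistically independent programs. Background genes are iid
  N(8, 0.5) in log2.
* **Regulatory genome**: 4 Mb, 40 growth genes (random strand), promoters
  1500/300, two 1.5 kb enhancers per gene at 10–45 kb plus two decoy
  elements elsewhere. One anchor consensus is planted per promoter and
  enhancer. Each partner motif is planted as a Poisson process at
  1/1500 nt outside anchor windows and at 10× that rate inside windows of
  its planned compartments; a multiplier of 1 is therefore an exact null
  against the `outside` background. Planting windows are computed with the
  same merge/subtract interval code the analysis uses, positions are
  length-weighted, and collisions retry, so realized planting rates match
  their nominal values.
* **Tracks and Hi-C**: Poisson background (mean 1 per 100 bp bin) with
  Poisson peaks (mean 50 per bin) over promoters, enhancers and decoys on
  both assays; Hi-C counts follow `200 × (res/max(d,res))^0.87` with a 10×
  boost at true enhancer–gene bin pairs.
* **TF sets**: 4 core TFs sharing a 40-gene target pool and targeting each
  other; 8 peripheral TFs with 3 disjoint targets each; a held-out
  anchor-like TF wired to 12 shared targets only through the interaction
  list, so it can enter the network solely via expansion.

What the fixtures do **not** emulate: read-level noise, GC and
accessibility biases, motif degeneracy families and overlapping motifs,
chromatin-state structure in Hi-C beyond distance decay, probe→gene
mapping artifacts, or batch effects. Passing tests demonstrate that the
algorithms recover the structure they model at realistic signal sizes —
not that real data meet those assumptions.

## Problem sizes

Defaults keep full runs desk-sized: the 4 Mb / 40-gene genome makes a
complete discovery run take a couple of seconds, the 50-simulation null
calibration under a minute, and the whole test suite about a minute. All
sizes are `FixtureSpec` fields and scale up linearly.

## Known limitations

* The enrichment Z is a screen statistic, not a calibrated p-value: it
  ignores background-estimation noise and motif self-overlap
  (clumping).
* The static-height tree cut has no per-branch adaptivity; very unequal
  module densities may need a hand-tuned `cut_height_frac`.
* Replicating published full-genome counts (number of enhancers, candidate
  TF lists) requires the original data accessions and the exact defaults of
  the external tools they were produced with; the package fixes the
  algorithmic contracts instead.
* Gene-id normalization is case-folding plus an optional synonym table;
  cross-species orthology is the user's responsibility.
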