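# Methods

This note documents the models, parameter choices and numerical conventions
behind `diffcoex`, and what the synthetic benchmarks do and do not
demonstrate.

## Expression model and differential expression

The pipeline assumes single-channel array-style intensities: strictly
positive, log-normal-ish, with a shared additive background. Quantile
normalization replaces each column's sorted values with the row means of
the column-sorted matrix; ties are broken by row position (stable argsort),
which makes the transform exactly idempotent and the post-condition
"identical sorted value vector in every column" hold to machine precision.
Log2 ratios are taken against each gene's mean across all samples, so per
gene the arithmetic mean of `2^y` is exactly 1.

The per-gene test is Welch's t by default. The equal-variance Student
variant is available via `equal_var=True`; with n = 4 + 4 replicate groups
the two differ little, and Welch is the safer default when a knockdown
perturbs variance. Genes with zero variance in both groups get `p = 1` and
a `zero_variance` flag — they are never silently dropped. All multiple
testing uses Benjamini–Hochberg; the implementation is
`statsmodels.stats.multitest` and the test suite checks it against a
hand-rolled step-up oracle.

Fold change is computed on log2 means, `2^|Δ|`, with direction from the
sign of Δ and a `1e−12` tie band mapping to "none". The "expressed"
flag — mean pre-transform intensity at or above a detection threshold in at
least one condition — requires an explicit threshold: array platforms do
not share a universal background level, so the package refuses to guess.
The synthetic default is 500 intensity units, five times the generator's
additive background of 100.

**Quantile normalization under asymmetric change.** When a large fraction
of genes shifts in one direction (the knockdown design plants ~20% of
genes, ~95% of them higher in control), quantile normalization partially
absorbs the shift: forcing identical column distributions compresses the
very signal that distinguishes them, attenuating estimated fold changes by
roughly a quarter and perturbing a small fraction of null genes near
DE-dense quantile regions. This is a property of the method, not a bug in
the implementation; it is why the estimator-recovery benchmark (below)
feeds `differential_expression` the log2 ratios of the raw intensities —
the generator plants no between-sample technical variation, so on
synthetic data there is nothing for the normalizer to remove — while the
end-to-end pipeline keeps the full normalize-then-test path.

## Co-expression networks

Pearson correlation is computed per condition over that condition's samples
only, in blocks of 512 genes so memory stays bounded at matrix scale
(~16,000 genes is supported; tests run at ≤ 2,000). Zero-variance genes get
r = 0 to all partners and are flagged. Edges use signed r with an inclusive
threshold — positive co-expression only — with `absolute_r` exposed as an
option.

Threshold selection follows the scale-free criterion: `P(k)` is the exact
fraction of nodes with degree k (k = 0 nodes included in the distribution,
excluded from the fit since log 0 is undefined); the fit is ordinary least
squares of `log10 P(k)` on `log10 k` over distinct observed k ≥ 1 (no log
binning), and the criterion statistic is the squared Pearson correlation of
those points. A fit is valid only with ≥ 3 distinct points and non-zero
variance in both coordinates; degenerate fits score 0. The selector scans
the ascending grid (0.75, 0.80, 0.85, 0.90) and returns the smallest
threshold with fit R² ≥ 0.80, raising (with the full per-grid report) when
none qualifies. The end-to-end pipeline falls back to the top of the grid
in that case and records the fallback in its report — with only 4 samples
per condition the sample correlation of null gene pairs is uniform on
[−1, 1], so degree distributions at desk scale need not pass the criterion.

Hub ranking is by descending degree with lexicographic gene-ID
tie-breaking, making ranks fully reproducible. Network comparison reports
per-gene degrees (0 for absent genes), ranks, lost/gained/retained status
and top-N hub-list intersections.

## Within-pathway co-clustering

The comparative clustering procedure is fixed as: average-linkage
hierarchical clustering on distance 1 − r within the pathway gene set,
using one condition's samples at a time. The dendrogram is cut per branch:
every maximal subtree whose leaves number ≥ `min_size` (default 5) and
whose average pairwise r is ≥ `min_avg_r` (default 0.65) becomes a
cluster. The per-branch rule lets each module surface at its own merge
height; a single global cut level would split a tight module whenever an
unrelated loose branch needed a finer cut. `min_avg_r = 0.65` sits just
below the 0.669–0.838 range that reported within-pathway clusters span, and
both parameters are configurable.

Conserved (O) clusters are the pairwise C×K intersections of size ≥
`min_size` — the simplest reading of "conserved across conditions" — each
annotated with its own average within-cluster r in both conditions.
Classification is: conserved = in any O cluster; divergent = in a C or K
cluster but no O cluster; unclustered otherwise. Clustering is hard: a gene
belongs to at most one cluster per condition, labels order by decreasing
size with ties by smallest member gene ID.

## ChIP targets and histone states

All interval arithmetic is 0-based half-open (BED native). Promoter
windows are strand-aware: `[tss − up, tss + down)` on +, mirrored on −,
clamped at 0; presets are (8000, 2000) for the tiling-array convention and
(1000, 1000) for the tag-mapping convention. A peak assigns a gene when it
overlaps the window by ≥ 1 bp (no minimum-fraction rule); lookup uses an
interval tree, and tests verify equivalence with a brute-force all-pairs
scan. Signal calls are inclusive at 2.2× over unbound background; missing
ratios count as unbound and are tallied in a QC report, as are peaks on
chromosomes absent from the annotation.

Replicate support is cumulative: "bound in t samples" is read as at-least-t
(the multi-replicate target universe used downstream is the ≥ 2 set), so
counts are non-increasing in t by construction and asserted on every run.
Histone states are the exclusive four-way classification
active / repressed / bivalent / none from H3K4me3 and H3K27me3 target sets.

## Overlap statistics

The hypergeometric upper tail is evaluated through `scipy.stats.hypergeom`
(log-gamma arithmetic internally); tests cross-check every
(N ≤ 12, m, n, k) against exact rational enumeration and one larger case
against Monte-Carlo. `R = kN/(mn)` is the observed overlap over its
expectation `mn/N`; k = 0 yields P = 1 and R = 0. Set enrichment intersects
every collection set with the explicit universe first and applies BH within
the collection, not across collections. Co-targeting matrices report two
significance tiers (p < 10⁻³, p < 10⁻¹⁰); multi-factor classes partition
the primary target set by the exact subset of other factors co-binding
each gene, so class counts sum to the primary set size. The universe is
always an explicit argument — whether to condition on array-expressed genes
or all annotated genes is a scientific choice the caller must make.

## Synthetic-data generator

The generator emulates a knockdown microarray study at desk scale: 2,000
genes × (4 control + 4 knockdown) samples, ~70% of genes expressed above
background. Gene g in sample s is built on the log2 scale as

    x_gs = base_g + effect_g·c(s)/2 + σ·( sqrt(r)·f_m(s) + sqrt(1−r)·ε_gs )

with ε ~ N(0,1), c(s) = ±1 for control/knockdown, and σ = 0.25 log2 units
of replicate noise. The variance-partition form gives within-module
correlation exactly r in expectation while keeping every gene's variance at
σ² — a naive additive loading `a·f + ε` with `a = sqrt(r/(1−r))·σ` produces
the same correlation but inflates per-gene variance by 1/(1−r) (20-fold at
r = 0.95), and a large planted module then acts as a spurious sample-level
batch shift that quantile normalization smears across all genes. Modules
inactive in a condition have the shared latent replaced by fresh
independent noise there, so their genes decorrelate to background levels.

Hubs are stars: the hub gene loads on its own latent at `sqrt(0.98)` and
each of the `hub_degree_target` satellites at `0.93/sqrt(0.98)`, giving
hub–satellite correlation 0.93 and satellite–satellite ≈ 0.88 — the centre
is denser than the rim, as a star must be (any single-latent construction
forces satellite–satellite r = (hub–satellite r)²/hub-share, so the rim
cannot be made arbitrarily loose).

Expressed genes draw `base ~ N(12, 1.2)` in log2 — median intensity ≈ 40×
the additive background of 100 units, as detected transcripts sit on
arrays — and unexpressed genes fluctuate around the background level.
Intensities are emitted as `2^x + background`. The DE defaults (20% of
genes shifted by 1.2 log2, 95.5% higher in control) were calibrated so the
observed post-normalization ≥1.5-fold and ≥2.0-fold class rates and their
direction split land near the rates such knockdown arrays report (~19%,
~5%, >80% elevated in control); the calibration accounts for the
normalization attenuation described above. The truth object's expressed
set is the realized one (mean emitted intensity ≥ threshold in at least one
condition), so detection flags recomputed downstream agree with it exactly.

The genome is synthetic: TSSs laid 20 kb apart (so −8 kb/+2 kb windows of
neighbours can never overlap), strands alternating. Factor peaks (width
200 bp) are placed inside true targets' ±1 kb promoter windows, upstream of
the TSS in the transcription direction; each replicate independently misses
each target with probability `peak_dropout` (default 0.4), producing the
decreasing replicate-support gradient real ChIP replicates show. Decoys sit
midway between promoter neighbourhoods and can overlap no window. Histone
marks (55% H3K4me3-only, 4% H3K27me3-only, 10% bivalent, ESC-like) are
emitted as single-replicate peak sets at the TSS. The default ChIP'd
factors are one 4-replicate primary factor (200 targets) and three
2-replicate pluripotency-style factors (150 targets each), all with a 30%
preference for planted-module genes so co-targeting is non-trivial.

What the generator does **not** emulate: probe-level artifacts, dye or GC
bias, replicate-correlated ChIP failures, effect-size distributions
(planted effects are a single magnitude), or sample-level batch effects.
Passing recovery tests therefore shows the algorithms are correct under
the stated statistical model, not that the pipeline is robust to every
artifact of real arrays.

## Benchmark scenario sizes

- **Estimator recovery** (planted 2-fold effects): the study design itself,
  2,000 genes at n = 4 + 4, effect 1.0 log2, measured on the raw-ratio path
  (see the normalization note above).
- **Hub recovery**: 800 genes, one planted hub with 50 satellites, no
  modules, 12 samples per condition. With 4 samples the null Pearson r is
  uniform on [−1, 1] (every noise gene would have expected degree ≈ 0.05·n
  at τ = 0.9), so hub ranking is only assessable once null correlations are
  rare at the threshold; at n = 12 the null tail P(r ≥ 0.9) ≈ 3·10⁻⁵.
- **Module recovery** (ARI of conserved modules vs O clusters; divergence
  of the control-only module): 600 genes, default modules, 25 samples per
  condition. Cluster recovery needs the realized average r of a planted
  module to clear the 0.65 reporting cutoff even when the module's latent
  profile draws a low-variance sample (realized r ≈ r·v/(r·v + 1 − r) with
  v ~ χ²/df); conserved modules planted at r = 0.80 keep that probability
  ≈ 0.3% at n = 25, whereas r = 0.75 would fail ~8% of draws.
- **Target recovery**: 500 genes, dropout 0, no decoys — recovery must be
  exact, and is.
- **Type-I control**: 20 simulations of 400 null genes through the full
  normalize-then-test path.

These sizes keep the full suite and the acceptance script in the
seconds-to-minutes range while leaving each benchmark statistically
identifiable.

## Numerical conventions and degenerate inputs

Correlations are clipped to [−1, 1] after the blocked matrix product;
diagonals set to exactly 1. Quantile normalization of a single-sample
matrix warns and returns the input. Empty pathway gene sets (after
intersection with the matrix) warn and return no clusters. `k = 0` overlaps
short-circuit to P = 1 rather than evaluating a survival function at −1.
Percentages in reports are integer-rounded (matching how such chains are
conventionally quoted); raw counts are always alongside, and machine-
readable outputs carry unrounded values. All randomness flows from a
single integer seed through `numpy.random.default_rng`; two runs with the
same config produce byte-identical outputs, which the manifest's SHA-256
checksums make checkable.

## Known limitations

- The comparative-clustering procedure in the original analyses of this
  kind is under-specified; the per-branch average-linkage rule here is a
  documented stand-in calibrated to the reported cluster statistics, not a
  reimplementation of any specific tool.
- The scale-free criterion at 4 + 4 samples rarely passes at desk scale
  (see above); the pipeline's fallback threshold keeps runs comparable but
  such networks are dominated by sampling noise, exactly as genuine
  4-replicate co-expression networks are.
- Weighted (soft-threshold) networks, topological overlap, module
  eigengenes, probe-to-gene collapsing, moderated-variance tests and
  GSEA-style permutation enrichment are out of scope.
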