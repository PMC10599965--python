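# Methods

## Model and assumptions

The package treats a single-cell experiment as a sparse non-negative
cells × genes count matrix `X` with per-cell categorical annotations. The
working assumption is the usual manifold hypothesis of graph-based
scRNA-seq analysis: expression varies smoothly across transcriptomic
neighborhoods, so a cell's measured profile is a shallow, noisy draw from a
state shared with its nearest neighbors. Replacing each profile with an
adjacency-weighted combination of itself and its neighbors (`M = AX`)
raises abundances, breaks the rank ties that destabilize rank-based
scores, and leaves the cell dimension intact — unlike pseudobulk
aggregation, which collapses it.

Smoothing is only meaningful among cells that may plausibly share a state.
The pipeline therefore partitions cells by the observed value-combinations
of user-chosen `groupby` columns before anything else; graphs, smoothing
and scoring never mix groups, and each group's computation is independent
of every other's (the contract that would make parallel execution legal).
Missing values in a groupby column form their own `"(missing)"` group
rather than silently dropping cells.

## Pipeline per group

1. **Embedding.** Total-count normalization to the median depth of the
   group, `log1p`, per-gene scaling to unit variance (zero-variance genes
   dropped), truncated PCA. Distances for the graph are measured in PCA
   space, the standard practice this stage exists to serve; `n_components`
   (default 50) is clipped to `min(cells, genes) − 1` with a warning.
   Groups of fewer than 3 cells skip the embedding and fall back to the
   all-pairs graph; a group whose counts are constant cannot be embedded
   and is scored unsmoothed, with a note in the run report.
2. **KNN graph.** Exact Euclidean K nearest neighbors (default K = 32,
   clipped to group size − 1), self excluded, neighbor lists sorted by
   distance with ties broken toward the lower cell index. Search is a
   stable argsort of the full distance matrix up to 2048 cells and
   tree-based exact search above; both are deterministic, and the
   truncation of a K-neighbor list to a smaller K' reproduces the K'-NN
   graph exactly — which is what makes overlap-vs-K curves internally
   consistent.
3. **Adjacency.** `binary`: 1 on the union-symmetrized edge set;
   `connectivity`: the density-adjusted Gaussian kernel
   `w_ij = exp(−d_ij²/(σ_i σ_j))` with `σ_i` the distance to the K-th
   listed neighbor, symmetrized by elementwise maximum; `off`: identity.
   The per-cell bandwidth adapts the kernel to local density, and the
   product form makes weights invariant to a global rescaling of all
   distances. The diagonal is fixed at 1 in every mode so smoothing never
   discards a cell's own counts. Degenerate geometry is handled
   explicitly: a zero bandwidth (coincident K-th neighbor) borrows the
   smallest positive distance in the group, and a fully coincident group
   gets uniform weights.
4. **Smoothing.** `M = A·X`, computed sparse end to end. Binary mode
   deliberately **sums** rather than averages: the row of `M` is a
   per-cell mini-pseudobulk, which is the point of the construction, and
   rank-based scores are unaffected by row scale. A row-mean variant
   (each row divided by its adjacency row sum) exists behind
   `row_normalize`; the `auto` setting applies it exactly for the
   scale-sensitive methods (`average_score`, `median_score`,
   `mean_z_score`) and is recorded in the run report.
5. **Scoring.** Gene sets are first restricted to the measured universe
   (exact, case-sensitive matching by default; an opt-in case-folding
   flag exists because symbol-case mismatches are a common silent
   failure). Sets with under half their genes measured trigger a warning;
   sets with nothing measured are flagged unscorable and produce missing
   values, never zeros. Groups below `min_group_size` (default 5, below
   which a neighborhood is noise) are scored with smoothing forced off and
   flagged; a group that fails outright contributes missing values without
   affecting the others.

## Scoring functions

Ranks are always ascending (rank 1 = lowest expression) with average-tie
handling, so the rank sum is exactly N(N+1)/2 and every score is invariant
to the input order of genes. Where a strict walk order is needed (ssGSEA,
RBO), genes are ordered by decreasing expression with ties broken toward
the lower gene index — deterministic, and irrelevant whenever smoothing has
done its job of breaking ties.

- **summed_up** — sum of ranks of up-genes minus sum of ranks of
  down-genes.
- **average_score / median_score** — the statistic over up-gene values
  minus the same over down-genes.
- **mean_z_score** — mean per-gene z-score over the set (up minus down).
  Gene means and standard deviations are computed across the *whole scored
  population* after smoothing, not per group: per-group statistics would
  erase exactly the between-group differences one scores to find. This is
  the one method that is not decomposable across groups, and it is
  documented as such.
- **geneset_overlap** — the number (or fraction) of set genes with
  expression above a threshold (default 0). Under binary smoothing this
  count is non-decreasing in K, which makes the overlap-vs-K curve a
  K-selection diagnostic: the plateau marks the point where larger
  neighborhoods stop recovering signature genes.
- **singscore** — mean rank of the up-genes rescaled by its attainable
  extremes to [0, 1]; down-genes scored the same way against the reversed
  ranking; two-part total = up + down − 1 ∈ [−1, 1], one-directional sets
  report the centered score ∈ [−0.5, 0.5]. A set covering every measured
  gene makes the normalization degenerate and scores 0 with a warning.
- **ssgsea** — the integrated weighted running sum: walking genes by
  decreasing expression, in-set genes add their normalized rank weight
  `(N − pos + 1)^α` (α default 0.75, the method's published default),
  out-of-set genes subtract `1/(N − n)`, and the running statistic is
  summed over all N positions. Two-part sets: up-score minus down-score on
  the same ordering. No across-cell min–max renormalization is applied by
  default — it would couple cells and break per-group independence; it is
  available behind a flag-level choice downstream, not baked in.
- **rank_biased_overlap** — agreement between the cell's top genes and the
  set: `A_d` = fraction of the top-d genes in the set, geometrically
  weighted by persistence p (default 0.9) down to depth D (default, the
  measured set size), normalized so a perfect prefix scores exactly 1.
  Both halves of a two-part set are scored against the same descending
  ranking and subtracted. This is a deliberate design choice: scoring the
  down half on the *reversed* ranking and subtracting looks symmetric but
  collapses — a perfectly concordant cell (up-genes top, down-genes
  bottom) and a perfectly discordant one both score 0. The same-ranking
  subtraction separates them (+1 vs −1) and makes swapping the two halves
  negate the score exactly, matching the behavior of the other
  directional scores.

Separation between labeled populations is quantified by the Mann–Whitney
AUC, `U/(n₁n₀)` from average ranks (tie-corrected, so constant scores give
exactly 0.5).

## Synthetic data

`simulate_two_populations` emulates the droplet regime the package is
built for: negative-binomial counts with variance `μ + μ²/dispersion`
(dispersion default 2; ∞ gives the Poisson limit), long-tailed per-gene
base means (lognormal, σ = 1) averaging `base_mean`, and per-cell size
factors `s_j ~ LogNormal` with unit mean (`depth_variation` default 0.3).
Defaults — 1000 + 1000 cells, 1000 genes, `base_mean` 0.5 (≈500 counts per
cell over the panel, a processed-PBMC-like depth) — define the package's
standard study conditions. Forty marker genes drawn from the 40–70th
percentile of base expression are elevated `fold_change`-fold (default
1.5) in population B only: mid-expression markers are the sparse,
tie-prone regime where smoothing has signal to recover. The generator is
bit-reproducible per seed.

What it does not emulate: batch effects, doublets, trajectories,
cell-type-specific co-expression structure, or any particular published
dataset. Passing tests on these fixtures show that the machinery recovers
a planted signal under realistic noise; they do not certify performance on
real tissues.

## The benchmark protocol and its caveats

`run_robustness_curve` thins the counts binomially (each count →
Binomial(c, f)), re-embeds, re-smooths and re-scores at each (fraction, K)
grid point, and reports the AUC against the population labels. Graphs are
built per population (`groupby=["label"]`), mirroring the common situation
in which the smoothing groups are the annotated phenotypes or samples one
later compares. Two consequences of that protocol are worth stating
plainly:

- At the default effect size the two populations differ in only 40 of
  1000 mid-expression genes — too weak for an unsupervised embedding to
  separate (the spike sits below the detection threshold of sample-PCA at
  this depth). Pooled, label-blind smoothing therefore *dilutes* this
  particular signal; the benefit of smoothing here comes from restricting
  neighborhoods to the correct group, exactly as when a user smooths
  within annotated cell types.
- Smoothing within the groups one then evaluates correlates scores inside
  each group (neighborhoods share cells), reducing the effective number of
  independent cells to roughly n/K. Point estimates of separation are
  unaffected, but their sampling variability is much larger than the cell
  count suggests — visible in the fold-change-1 null calibration, whose
  AUC scatters far more widely around 0.5 than independent scores would.
  Any downstream inference on scores smoothed this way should account for
  that reduced effective sample size.

The acceptance benchmark (`scripts/acceptance.py`) uses the default study
conditions with medians over a five-seed grid, a problem size chosen so
the full run completes in about a minute on one CPU; the test suite
exercises the same machinery at smaller sizes.

## Numerical choices

- Exact KNN everywhere at desk scale; deterministic stable tie-breaks
  (lowest index) in neighbor lists and walk orders; PCA seeded.
- Counts are accepted as non-negative reals (smoothed or renormalized
  matrices are re-scored routinely); binomial thinning alone demands
  integers and rejects anything else.
- Square count matrices with equal ID counts are an ambiguous orientation
  and require an explicit flag rather than a guess.
- Unscorable sets yield missing values, not zeros; degenerate kernels,
  single-cell groups, and all-zero thinned matrices all degrade to
  defined behavior (identity smoothing, AUC 0.5) rather than raising.

## Limitations

Single-step smoothing only (no multi-step diffusion); no empirical
p-values or permutation nulls for the scores; no batch-integrated joint
graphs — separation across batches is delegated to `groupby`; the
`mean_z_score` population statistics make that method non-decomposable
across groups by design.
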