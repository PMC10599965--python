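# smoothscore

Per-cell gene set scoring on nearest-neighbor-graph smoothed single-cell
count data.

## The problem

Single-sample gene set scoring reduces one expression profile to one number
per signature — a cell-type identity, a pathway, a response program — so
that downstream statistics can work with interpretable quantities instead
of thousands of genes. The established single-sample scores (singscore,
ssGSEA, and relatives) were designed for bulk profiling. Droplet
single-cell RNA-seq breaks them: counts are shallow and zero-inflated, so
the rank vector a cell presents is dominated by massive ties at zero and at
one count, and tiny count fluctuations produce large rank — hence score —
fluctuations.

`smoothscore` addresses this by sharing information along the cell-cell
nearest-neighbor graph before scoring. Cells are first partitioned by
user-chosen annotation columns (cell type, cluster, sample, condition) so
that no information crosses phenotype boundaries; within each group a KNN
graph is built in a PCA embedding and the counts matrix is smoothed by one
sparse multiplication

```
M = A X
```

where `X` is the group's cells × genes count matrix and `A` is either a
binary adjacency (row *i* of `M` is then the summed counts of cell *i* and
its neighbors — a per-cell mini-pseudobulk) or a weighted adjacency from a
density-adjusted Gaussian kernel

```
w_ij = exp(−d_ij² / (σ_i σ_j)),   σ_i = distance from cell i to its K-th neighbor,
```

symmetrized by the elementwise maximum and with unit diagonal, so a cell
never loses its own measurements. Each smoothed profile is then scored
per cell against GMT gene sets (including two-part up/down signatures)
with any of eight single-sample functions:

`singscore`, `ssgsea`, `rank_biased_overlap`, `mean_z_score`,
`average_score`, `median_score`, `summed_up`, `geneset_overlap`.

The `geneset_overlap` count doubles as a K-selection diagnostic: under
binary smoothing the number of detected signature genes can only grow with
K, and the K where it plateaus marks the limit of what the data can
recover.

## Worked example

```python
from smoothscore import auc_separation, score_cells, simulate_two_populations

ds, markers = simulate_two_populations(
    n_cells_a=300, n_cells_b=300, n_genes=400, marker_genes=12, seed=0
)
labels = (ds.cell_annotations["label"] == "B").to_numpy()

for mode, knn in (("off", 0), ("connectivity", 16)):
    res = score_cells(ds, markers, method="singscore", smooth_mode=mode,
                      knn=knn, groupby=["label"], seed=0)
    auc = auc_separation(res.scores["markers__singscore"].to_numpy(), labels)
    print(mode, knn, round(auc, 3))
```

prints

```
smooth_mode=         off  K= 0  mean score A=-0.017  B=+0.037  AUC=0.718
smooth_mode=connectivity  K=16  mean score A=+0.015  B=+0.167  AUC=0.998
```

Population B carries a planted 12-gene signature at 1.5-fold elevation. On
raw counts the singscore distributions of the two populations barely
separate (AUC 0.72 — the probability that a random B cell outscores a
random A cell). After smoothing each population's counts along its own
16-nearest-neighbor graph, the same score separates them almost perfectly
(AUC 0.998). The `examples/` directory has one short script per
capability: scoring, K selection by overlap, downsampling robustness, and
two-part up/down signatures.

The same pipeline is available from the shell:

```bash
smoothscore simulate --out-dir data/
smoothscore score --counts data/counts.mtx --genes data/genes.txt \
    --cells data/cells.txt --annotations data/annotations.tsv \
    --gmt data/genesets.gmt --groupby label --method singscore \
    --knn 32 --out scores.tsv
smoothscore overlap --knn-grid 0,8,32 ...   # K-selection diagnostic
```

Every run writes a JSON report of its effective parameters next to the
output.

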