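# tsclust — two-step clustering of single-cell RNA-seq expression matrices

Clustering cells from single-cell RNA-seq is hard at the cluster
boundaries: dropout noise and intermediate expression states blur where
one cell population ends and the next begins, and those ambiguous cells
drag down the quality of the whole partition. `tsclust` implements a
two-step strategy that deals with them explicitly:

1. **Split cells into core and non-core.** Build a fully connected
   similarity graph over cells (Pearson correlation by default; Spearman,
   Euclidean, Manhattan and shared-nearest-neighbour similarities are also
   available), keep only the strongest ~25% of edges, and call the cells
   still incident to an edge *core* cells — they sit in dense regions near
   cluster centers. Cells whose every similarity falls below the cut are
   *non-core* and are set aside.
2. **Cluster the core cells** with agglomerative hierarchical clustering
   under a random-walk graph distance. With transition probabilities
   `M_ij = w_ij / Deg(i)`, two cells are close when their t-step walk
   probability rows (t = 4 by default) are similar:

       d_ij = sqrt( Σ_k (P_ik^t − P_jk^t)² / Deg(k) )

   Merges follow a Ward-style criterion Δσ on the average intra-cluster
   squared distance σ_K, and the number of clusters K is chosen
   automatically where the merge-cost profile jumps
   (argmax of (σ_{K−1} − σ_K)/(σ_K − σ_{K+1})).
3. **Assign the non-core cells** to the cluster whose center — the
   per-gene mean of its core cells — is nearest in expression space.

Preprocessing is deliberately minimal: genes expressed in fewer than 2% of
cells are dropped, and the matrix is log2(x+1)-transformed only when the
**right-skewed coefficient** `RSC = Σ_{g_max ≥ μ}(g_max − μ) / (l·μ)` of the
per-gene maxima (computed after Tukey-fence outlier removal) exceeds 0.8 —
log-transforming data that are not right-skewed distorts gene differences
rather than fixing them.

The package is for computational biologists who want an unsupervised
partition of a cells × genes matrix (UMI, CPM or FPKM units) without
specifying the number of clusters, plus the standard external evaluation
scores (ARI, NMI, AMI, matching accuracy) when ground-truth labels exist.

## Worked example

```python
from tsclust import TSC, SyntheticSpec, generate

x, truth = generate(SyntheticSpec(n_cells=300, n_genes=200, k_true=3,
                                  separation=6, seed=1))
res = TSC(x, metric="pcc", edge_fraction=0.25, walk_steps=4).fit()
print(res.summary())
print(res.score(truth))
```

prints

```
Two-step clustering results
==========================================
cells                      300
genes (after filter)       200
similarity metric          pcc
edge fraction             0.25
walk steps t                 4
RSC                      0.419
log2(x+1) applied        False
core cells                 300
non-core cells               0
clusters K                   3  (auto)
------------------------------------------
cluster sizes         100 100 100

{'ari': 1.0, 'nmi': 1.0, 'ami': 1.0, 'acc': 1.0, 'ari_core': 1.0}
```

RSC = 0.419 is below the 0.8 gate, so the matrix stays on its original
scale; on this well-separated mixture every cell keeps a strong edge (no
non-core cells), the merge-cost jump selects K = 3, and the recovered
labels match the planted ones exactly (ARI = 1). `res.to_frame()` gives the
per-cell table, `res.centers` the cluster centers, and
`res.plot_merge_costs()` the σ_K curve behind the K choice.

The same pipeline is available from the shell:

```bash
tsclust simulate --cells 300 --genes 200 --k 3 --separation 6 --seed 1 --out-prefix syn
tsclust cluster --input syn_matrix.tsv --truth syn_labels.tsv --output-dir out
tsclust evaluate --truth syn_labels.tsv --pred out/tsc_labels.tsv
tsclust sweep --input syn_matrix.tsv --truth syn_labels.tsv \
              --param walk_steps --values 2,4,8,15
```

`tsclust cluster` accepts dense CSV/TSV (genes in rows by default, see
`--orientation`) or MatrixMarket `.mtx` with `.rows`/`.cols` sidecar label
files, and `--one-step` runs the ablation that clusters all cells directly
without the core/non-core split.

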