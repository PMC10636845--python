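# Methods

## The model

`tsclust` partitions a cells × genes nonnegative expression matrix in two
steps. The premise is that clustering errors concentrate on cells near
cluster boundaries, so those cells should not be allowed to distort the
cluster structure: they are identified up front, excluded from the
hierarchy, and assigned at the end.

**Preprocessing.** Genes expressed (value > 0) in fewer than
`min_expressed_fraction` of cells (default 0.02; genes at exactly the
threshold are kept) are removed — near-silent genes carry no clustering
signal. Whether to log-transform is then decided by the right-skewed
coefficient of the per-gene maxima `g_max`:

    RSC = Σ_{g_max ≥ μ} (g_max − μ) / (l · μ)

with μ the mean of the maxima, l the number of maxima at or above μ, after
discarding maxima outside the Tukey fence [Q1 − 1.5·IQR, Q3 + 1.5·IQR]
(linear-interpolation quartiles; the convention is recorded in the
`RSCReport` so alternates can be compared). RSC is scale-invariant and
zero for symmetric-topped maxima; values above `rsc_threshold` (default
0.8) indicate that a few genes dominate all distances, and the matrix is
replaced by log2(x + 1). The fence applies to the RSC computation only —
no gene is removed from the matrix by it. A `force_log` switch overrides
the gate in either direction. The filter runs before the RSC decision;
both operate on the raw scale.

**Core-cell selection.** Cells become nodes of a fully connected graph
weighted by a similarity in [0, 1]:

| metric | definition | notes |
|---|---|---|
| `pcc`, `scc` | Pearson / Spearman correlation, negatives clamped to 0 | default `pcc`; only positive correlation counts as similarity |
| `ed`, `md` | `1 − d/d_max` for Euclidean / Manhattan distance | simplest order-reversing map onto [0, 1] |
| `snn` | \|kNN(i) ∩ kNN(j)\| / k, Euclidean neighbourhoods, self excluded | `snn_k` default 20 |

Zero-weight pairs are treated as absent edges throughout (a clamped
correlation of 0 is "no evidence of similarity", and retaining such an
edge could create zero-degree nodes in the walk). All edge weights are
sorted and the top `⌈edge_fraction · E⌉` retained (default 0.25), keeping
every edge tied with the weight at the cut so the split is deterministic
and order-independent. Cells incident to a retained edge are *core*; the
rest are *non-core*. Self-similarities are never stored, so the weighted
degree Deg(i) sums over genuine neighbours only.

**Random-walk distance.** On the thresholded core graph the transition
matrix is `M_ij = w_ij / Deg(i)`; the t-step probability rows are the rows
of `M^t` (`walk_steps` default 4), and the distance between core cells is
the degree-weighted L2 distance between their rows. Small t sees only
immediate neighbourhoods; large t approaches the stationary distribution
(which depends only on degrees) and all distances collapse — the test
suite checks both limits. If the thresholded graph is disconnected, walks
stay inside components and cross-component distances are finite and
large; clustering proceeds normally.

**Agglomeration.** Starting from singletons, the pair minimising

    Δσ(Ci, Cj) = (1/n) ( Σ_{k∈Cu} d²_{Cu,k} − Σ_{k∈Ci} d²_{Ci,k} − Σ_{k∈Cj} d²_{Cj,k} ),  Cu = Ci ∪ Cj

is merged at each step, ties broken on the lexicographically smallest pair
of cluster ids (ids are smallest member indices), which makes runs
deterministic and permutation-equivariant away from exact ties. Two
readings of the cell-to-cluster quantity `d_Ck` are implemented, selected
by `linkage`:

* `walktrap` (default): `d_Ck` is the degree-weighted L2 distance between
  the cluster's averaged probability row and the cell's row. Under this
  reading Δσ is a genuine Ward criterion; by the Huygens decomposition it
  equals `|Ci||Cj|/(|Ci|+|Cj|) · ||P̄_Ci − P̄_Cj||²_Deg / n`, which is the
  closed form the implementation uses (the generic evaluation is kept and
  the two are asserted equal to 1e−10 in the tests).
* `literal`: `d_Ck` is the plain average of the reaching probabilities
  `P_ik`. A probability average is *large* for close cells, so this is not
  a proper distance and the merge objective loses its Ward meaning; the
  mode exists because the definitions admit both readings, and exposing
  both makes the choice inspectable rather than silent.

σ_K (the average intra-cluster squared distance) is recorded at every
level. Merge costs are kept in a lazy min-heap with version-stamped
entries, so a full run is O(n² log n) in walktrap mode at desk scale
(a few thousand core cells).

**Choosing K.** The selected K (searched in `[k_min, k_max]`, default
[2, min(50, n−1)]) maximises the merge-cost jump ratio

    η_K = (σ_{K−1} − σ_K) / (σ_K − σ_{K+1})

— the level just before the first expensive merge, i.e. the last point at
which merging still combined fragments of the same population. The ratio
compares each merge with its predecessor, so it is scale-free; levels with
a zero denominator (exact cost plateaus, e.g. all-identical walk rows) are
skipped with a warning and the search falls back to `k_min` if every level
is degenerate. The orientation of the ratio matters: the reciprocal
(comparing each merge with its successor) peaks on noise rather than at
the planted structure, which we verified on planted mixtures before fixing
this form. `fixed_k` bypasses the search entirely (used by the one-step
ablation benchmarks).

**Assignment.** Cluster centers are per-gene means of core-cell expression
in the preprocessed matrix; each non-core cell takes the label of the
nearest center (Euclidean by default; `assign_metric="pcc"` uses
1 − Pearson for correlation-built graphs), ties to the smallest cluster
id. Assignment is single-pass: no re-centering or iterative refinement
afterwards, so core-cell labels are exactly the hierarchy's level-K
partition.

**One-step ablation.** `one_step=True` forces `edge_fraction = 1`: all
cells (with any positive similarity) enter the hierarchy directly. With no
non-core cells the two paths coincide exactly; with boundary noise the
two-step path is expected to win, and both the tests and the acceptance
script measure that comparison.

## Evaluation metrics

ARI is computed from the contingency-table formula (row sums a_i, column
sums b_j, m cells):

    ARI = ( Σ_ij C(t_ij,2) − Σ_i C(a_i,2) Σ_j C(b_j,2) / C(m,2) )
        / ( ½[Σ_i C(a_i,2) + Σ_j C(b_j,2)] − Σ_i C(a_i,2) Σ_j C(b_j,2) / C(m,2) )

and is cross-checked in the tests against an explicit pair-counting
implementation and against scikit-learn. When both partitions are trivial
the degenerate 0/0 is defined as 1. NMI uses the arithmetic-mean
normalisation and AMI the expected-MI correction (both via scikit-learn;
the normalisation choice is part of the output metadata since variants
differ); accuracy is the best one-to-one cluster-to-class matching found
by the Hungarian algorithm.

## Synthetic study conditions

The generator (`tsclust.simulate`) produces the matrices every stage is
tested on. Design, chosen once:

* **Shape.** Defaults 300 cells × 200 genes — large enough for stable
  graph statistics, small enough that a full pipeline run takes well under
  a second. Real datasets have tens of thousands of genes; the gene axis
  here is a scaled-down stand-in whose signal-to-noise is controlled by
  the marker-block design below.
* **Cluster structure.** Each of `k_true` clusters owns a disjoint block
  of up to 20 marker genes whose mean is raised by `separation` ×
  `noise_sd` over a shared base profile; within-cluster noise is unit-SD
  Gaussian truncated at zero. `separation` is therefore a per-marker-gene
  effect size in SD units: at 6 SD the mixture is essentially perfectly
  clusterable, at 2–4 SD errors appear.
* **Skewness regimes.** `heavy_tail` draws gene means from
  lognormal(2, 2) and additionally scales the top 1% by 100 — gene maxima
  are then strongly right-skewed and RSC lands around 1.0–1.3, well above
  the 0.8 gate. `uniform` draws means from Uniform[2, 6], giving RSC
  around 0.37–0.44, safely below the gate. (Gamma-distributed means were
  rejected: their own skewness puts RSC ≈ 0.5, on top of the gate.)
* **Boundary cells.** A `boundary_fraction` of cells is moved to
  `α·c_own + (1−α)·c_other` with α ~ Uniform(0.5, 0.7) and noise inflated
  3× (`boundary_noise_factor`). They keep the source-cluster label. The
  α-spread keeps them diffuse — exact midpoints form a coherent phantom
  cluster that any good clusterer (this one included) discovers as extra
  structure — and the extra noise makes their similarities weak enough
  that part of them genuinely falls below the edge cut. Leaning α toward
  the source keeps the planted label the nearest center, so the assignment
  step can in principle recover them.
* **Dropout.** Every entry is zeroed independently with probability
  `dropout_rate` (default 0.1); the mask is drawn even at rate 0 so runs
  with different rates share the remaining stream.

What the generator does **not** emulate: protocol-specific noise
(UMI counting statistics, batch effects, library-size variation),
gene–gene correlation beyond the marker blocks, and biologically graded
(non-linear) transitions between cell types. Passing tests therefore show
that the machinery behaves as designed under its stated geometry, not that
it ranks well on any particular real dataset.

## Numerical choices and edge cases

* Quartiles: linear interpolation between order statistics.
* Log transform: base 2 with pseudocount 1 (`log2(x+1)`), preserving zeros.
* Exact symmetry of similarity matrices is enforced by averaging `W` with
  its transpose before use.
* Constant cell vectors make correlations undefined; their pairs get
  similarity 0 with a warning.
* If the nominal edge cut falls inside the zero-weight block, only
  positive-weight edges are retained (with a warning); an all-equal-weight
  graph retains everything.
* Walk length t = 0 returns the identity profile (documented, not an
  error); probability rows are conserved to 1e−12 across t = 2..15.
* An fp guard defines RSC = 0 when rounding pushes the mean one ulp above
  identical maxima.
* Merge-cost ties and assignment-distance ties resolve to the smallest
  cluster id.

## Known limitations

* Dense O(n²) matrices throughout: fine for desk-scale core sets
  (≤ a few thousand cells), not for atlas-scale data.
* Near-isolated cells that survive the edge cut with one weak edge can
  dominate the top of the dendrogram (their walk profiles are extreme
  under the degree weighting); with automatic K this occasionally absorbs
  the cluster budget into singleton peel-offs. The one-step mode and very
  noisy outlier populations are the risky combination.
* The jump-ratio K selection assumes merge costs grow smoothly within
  populations; on data with near-duplicate cells the early cost ratios are
  noisy and `k_min`/`k_max` bounds are the practical guard.
* The literal linkage mode is a faithful transcription of the averaged
  probability reading, exposed for comparison; its objective is not a
  distance criterion and its σ is not monotone, so the walktrap mode is
  the default for any real use.
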