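# mdimpute

Multidimensional dropout imputation for single-cell RNA-seq expression
matrices.

Single-cell RNA-seq count matrices are riddled with *dropouts* —
transcripts present in a cell but unobserved because of capture and
sequencing inefficiency — which distort expression distributions,
gene–gene correlations and every downstream analysis built on them.
`mdimpute` recovers these entries by combining three sources of
information tied together by the cells' pseudo-time:

1. **Transcriptome dynamics.** Cells are ordered along a cluster-based
   minimum-spanning-tree trajectory (PCA → Gaussian-mixture clustering →
   MST over cluster centers → projection onto the diameter path) and the
   ordered cells are split into consecutive *cell-state specific spaces*
   of `m = 5(⌈J/1000⌉ + 1)` cells each, which share an expression state.
2. **Cell-level information.** Within each space, every cell is predicted
   from the other cells with adaptive Gaussian-kernel weights
   `k_jj' = exp(−d²_jj'/σ²_j)`, where `σ_j` is the mean distance from cell
   `j` to its in-space neighbours.
3. **Gene-level information.** Per-gene means over each space's cells form
   *pseudo-cells*; a per-space gene co-expression network is built by a
   cell-specific-network style independence test (box-count statistic
   `z = (n·n_xy − n_x·n_y)/√(n_x n_y (n−n_x)(n−n_y)/(n−1))`, required to
   clear the normal quantile at every neighbourhood size), and each gene
   is predicted as the |Pearson|-weighted average of its network
   neighbours.

A per-space decreasing logistic curve fitted to (mean expression, zero
fraction) pairs gives every entry a dropout probability
`p_ij = 1 − 1/(1 + e^{a + b·x_ij})`, and the final estimate blends the
three layers:

```
x̂_ij = p_ij ( β/(α+β)·c_ij + α/(α+β)·g_ij ) + (1 − p_ij)·x_ij
```

with `α = sd(C)`, `β = sd(G)`. High-expression entries have `p ≈ 0` and
are left untouched; only probable dropouts move.

The package is aimed at computational biologists who want a transparent,
fully inspectable imputation pipeline: every intermediate layer (ordering,
partition, `C`, `G`, `P`, per-space logistic fits) is retained on the
results object. A ground-truthed synthetic generator and the standard
evaluation metrics (Gini, RMSE, CMD, POS, Kendall τ, ARI/Jaccard/FM, ACC)
are included.

## Worked example

```python
import mdimpute as mi
from mdimpute.metrics import rmse, kendall_tau

# synthetic trajectory with known truth; hide 20% of the nonzero entries
ds = mi.simulate_trajectory(n_genes=300, n_cells=150, seed=7)
masked, mask = mi.mask_entries(ds.observed_matrix(), 0.2, seed=7)

model = mi.ImputationModel(masked)     # or mi.run_pipeline(masked, seed=7)
res = model.fit(seed=7)
print(res.summary())
```

```
Multidimensional imputation results
===================================
genes x cells          300 x 150
spaces (S) / per-space m  15 / 10
alpha (sd of C)        2.8700
beta  (sd of G)        4.0467
mean dropout prob      0.3879
gene-level fallback    51.4% of gene-space pairs
zeros in input         0.6% remain zero

Per-space logistic dropout fits:
 space        a         b  fallback  converged  resid_norm
     0 1.856357 -0.330615     False       True    0.825406
     1 1.974481 -0.347085     False       True    0.797468
     ...
```

`alpha`/`beta` are the dispersions of the cell- and gene-level prediction
layers (the less dispersed layer gets the larger blend weight); each
space's `(a, b)` are the fitted logistic dropout parameters — negative
slopes confirm dropout probability falls with expression. Checking
recovery of the hidden entries:

```python
obs = mi.log_transform(mi.normalize_cpm(masked)).values
print(rmse(obs[mask], ds.true_log[mask]))          # 11.359  (zeros vs truth)
print(rmse(res.values[mask], ds.true_log[mask]))   #  5.013  (imputed vs truth)
print(abs(kendall_tau(res.pseudotime.ranks, ds.true_time)))  # 0.813
```

Imputation cuts the masked-entry error by more than half, and the inferred
pseudo-time ordering tracks the latent simulation time.

The same pipeline is available from the shell:

```
mdimpute simulate --genes 300 --cells 150 --seed 7 --out-dir sim/
mdimpute impute --input sim/observed.csv --output imputed.csv --seed 7
mdimpute evaluate --matrix imputed.csv --reference sim/true_counts.csv --output metrics.csv
```

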