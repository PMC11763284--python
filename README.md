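# cciseq

Consensus clustering-based imputation (CCI) of dropout events in
single-cell RNA-seq data, with a Splat-style count simulator and an
evaluation suite for the downstream analyses that dropout corrupts:
cell clustering, differential-expression calling and per-gene
expression recovery.

## Who this is for

scRNA-seq count matrices are zero-inflated: besides biological zeros,
technical capture failures record present transcripts as zeros, with
failure probability rising as expression falls (missing *not* at
random).  If your clustering falls apart or DE calls vanish once
dropout gets heavy, this package imputes the zeros from cells that are
*robustly* similar — similarity measured not by one clustering but by
an ensemble of them.

## The method

Given a log-normalized gene-by-cell matrix X:

1. sample a proportion p of a variable-gene pool (defaults: p = 0.8 of
   the top 100 genes), m = 50 times;
2. embed each subset (PCA → 2-D UMAP) and cluster it (K-means, k = 4);
3. average the m binary co-membership matrices into a consensus matrix
   W̃ ∈ [0,1]^(cells×cells): W̃_ik is the fraction of runs in which
   cells i and k co-clustered;
4. threshold at c = 0.2 to define neighbors, w_ik = W̃_ik·1{W̃_ik ≥ c},
   with w_ii = 0;
5. impute each zero entry with the weighted neighbor average

       x̂_ij = Σ_{k≠i} w_ik x_kj / (Σ_{k≠i} w_ik + ε),   ε = 1e-6.

Nonzero entries are never touched; a cell with no qualifying neighbor
keeps its zero (the biological-zero-preserving case).  An unweighted
variant replaces the weights by indicators.  See `docs/methods.md` for
assumptions, defaults, and the simulator's generative model.

## Worked example

```python
from cciseq import (SimParams, CCIParams, simulate_counts, apply_dropout,
                    log_normalize, cci_run, snn_cluster, adjusted_rand_index)

sim = apply_dropout(simulate_counts(
    SimParams(seed=11, cells_per_group=500, de_fac_loc=0.1, dropout_mid=4.0)))
corrupt = log_normalize(sim.counts_dropout)

result = cci_run(corrupt, CCIParams(seed=12, umap_n_epochs=100))
for name, matrix in [("with dropout", corrupt), ("imputed", result.imputed)]:
    labels = snn_cluster(matrix, with_embedding=False).labels
    print(name, adjusted_rand_index(sim.group_labels, labels))
```

prints (weak DE signal, ~60% zeros after dropout, 1000 cells):

```
with dropout 0.0
imputed 0.813
```

Dropout erased the agreement between SNN clusters and the true groups
entirely; imputation with consensus neighbors restores most of it
(recovery sharpens further with more cells — around 0.92 at 3000).  The scripts in
`examples/` walk through simulation, imputation, DE calling, recovery
correlation, and benchmark grids, each printing the numbers it
computes.

A thin CLI mirrors the library for shell pipelines:

```bash
cciseq simulate --seed 1 --out-dir sim/
cciseq impute --input sim/counts_dropout --m 50 --cutoff 0.2 --out imputed.csv
cciseq evaluate --imputed imputed.csv --truth truth.csv \
    --labels sim/group_labels.tsv --de-genes sim/true_de_genes.tsv \
    --report report.tsv
```

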