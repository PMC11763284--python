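"""Impute a corrupted dataset and compare clustering before and after.

Simulates a weak-signal dataset, corrupts it with moderate dropout,
runs consensus-clustering imputation, and prints the adjusted Rand
index of SNN clustering against the true group labels at each stage.
"""

from cciseq import (
    CCIParams,
    SimParams,
    adjusted_rand_index,
    apply_dropout,
    cci_run,
    log_normalize,
    simulate_counts,
    snn_cluster,
)

sim = apply_dropout(simulate_counts(
    SimParams(seed=11, cells_per_group=500, de_fac_loc=0.1, dropout_mid=4.0)
))
truth_norm = log_normalize(sim.counts)
corrupt_norm = log_normalize(sim.counts_dropout)

result = cci_run(corrupt_norm, CCIParams(seed=12, umap_n_epochs=100))
print(f"imputed {result.imputed.n_imputed} zero entries "
      f"({result.imputed.imputed_mask.mean():.0%} of the matrix)")

for name, matrix in [
    ("without dropout", truth_norm),
    ("with dropout", corrupt_norm),
    ("after imputation", result.imputed),
]:
    labels = snn_cluster(matrix, with_embedding=False).labels
    ari = adjusted_rand_index(sim.group_labels, labels)
    print(f"{name:>18}: ARI vs true groups = {ari:.3f}")

# Dropout destroys the two-group structure (ARI near 0); the imputed
# matrix recovers most of it by borrowing expression from consensus
# neighbors.  ARI approaches the dropout-free value as cells increase.
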