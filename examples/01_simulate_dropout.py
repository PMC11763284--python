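"""Simulate scRNA-seq counts with group structure and dropout.

Generates a two-group dataset, applies mean-dependent logistic dropout
at three severities, and prints the resulting overall zero fractions —
the dial that downstream examples corrupt data with.
"""

from cciseq import SimParams, apply_dropout, simulate_counts, zero_fraction

params = SimParams(seed=1, cells_per_group=500, n_genes=500, de_fac_loc=0.1)
dataset = simulate_counts(params)

print(f"{dataset.n_genes} genes x {dataset.n_cells} cells, "
      f"{len(dataset.true_de_genes)} true DE genes")
print(f"zero fraction before dropout: {zero_fraction(dataset.counts):.3f}")

for mid, label in [(2.0, "weak"), (4.0, "moderate"), (5.0, "strong")]:
    dropped = apply_dropout(dataset, mid=mid, shape=-1.0, seed=1)
    frac = zero_fraction(dropped.counts_dropout)
    step = dropped.dropout_mask.mean()
    print(f"dropout mid={mid} ({label}): overall zero fraction {frac:.3f} "
          f"(zeroed by the dropout step alone: {step:.3f})")

# The zero fraction rises with the dropout midpoint because entries whose
# log mean falls below the midpoint are zeroed with probability > 1/2.
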