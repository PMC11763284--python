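"""Shared fixtures: small simulated datasets generated at test time."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from cciseq import (
    SimParams,
    apply_dropout,
    log_normalize,
    simulate_counts,
)

warnings.filterwarnings("ignore", category=UserWarning, module="umap")
warnings.filterwarnings("ignore", message=".*n_jobs value 1.*")


SMALL = dict(cells_per_group=60, n_genes=150)


@pytest.fixture(scope="session")
def small_clean():
    """Strong-signal dataset without dropout, 120 cells x 150 genes."""
    return simulate_counts(SimParams(seed=7, de_fac_loc=0.3, **SMALL))


@pytest.fixture(scope="session")
def small_dropout(small_clean):
    """The same dataset with moderate dropout applied."""
    return apply_dropout(small_clean, mid=4.0, shape=-1.0, seed=7)


@pytest.fixture(scope="session")
def small_norm(small_dropout):
    return log_normalize(small_dropout.counts_dropout)


@pytest.fixture(scope="session")
def small_truth_norm(small_clean):
    return log_normalize(small_clean.counts)


@pytest.fixture(scope="session")
def blobs():
    """Two well-separated Gaussian blobs in gene space (genes x cells)."""
    rng = np.random.default_rng(0)
    n_genes, per = 40, 50
    center_a = rng.normal(0, 1, n_genes)
    center_b = center_a + 6.0
    a = center_a[:, None] + rng.normal(0, 0.5, (n_genes, per))
    b = center_b[:, None] + rng.normal(0, 0.5, (n_genes, per))
    values = np.concatenate([a, b], axis=1)
    labels = np.repeat([1, 2], per)
    return values, labels
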