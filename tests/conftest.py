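import numpy as np
import pytest

from tdcss import (
    CountSimConfig,
    SecretionTrace,
    StateCountMatrix,
    TraceSimConfig,
    simulate_secretion_traces,
    simulate_state_counts,
)


@pytest.fixture(scope="session")
def noisy_traces():
    """Forty secreting + twenty drift-only traces at the default SNR."""
    cfg = TraceSimConfig(n_cells=60, frac_secreting=40 / 60, seed=101)
    traces, truth = simulate_secretion_traces(cfg)
    return cfg, traces, truth


@pytest.fixture(scope="session")
def planted_matrix():
    """Small planted-class count matrix shared by classification tests."""
    cfg = CountSimConfig(
        n_genes_per_class=40,
        n_null_genes=300,
        n_cells_per_state=30,
        seed=17,
    )
    matrix, truth = simulate_state_counts(cfg)
    return matrix, truth


def tiny_matrix(counts, states, gene_ids=None, **kwargs):
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    return StateCountMatrix(
        counts=counts,
        gene_ids=gene_ids or [f"g{i}" for i in range(n_genes)],
        cell_ids=[f"c{i}" for i in range(n_cells)],
        state=np.asarray(states),
        **kwargs,
    )


def make_trace(times, signal, cell_id="cell", **kwargs):
    return SecretionTrace(cell_id=cell_id, times=np.asarray(times, float),
                          signal=np.asarray(signal, float), **kwargs)
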