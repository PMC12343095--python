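import numpy as np
import pytest

import combosyn as cs
from combosyn.evaluate import TrainConfig
from combosyn.model import ModelConfig


def small_synth_config(seed: int = 0, **overrides) -> cs.SynthConfig:
    """Scaled-down study conditions for fast per-module tests."""
    base = dict(
        n_drugs=16, n_cell_lines=12, n_combinations=400,
        n_genes=40, n_proteins=80, n_clusters=3,
        signature_size=6, gene_signature_size=6, seed=seed,
    )
    base.update(overrides)
    return cs.SynthConfig(**base)


def tiny_model_config(n_genes=40, n_proteins=80, **overrides) -> ModelConfig:
    base = dict(
        variant="gatfp", task="classification",
        n_genes=n_genes, n_proteins=n_proteins,
        graph_dim=8, fp_dim=8, omics_dim=8, head_dims=(16, 8),
        gat_heads=2, dropout=0.0, seed=0,
    )
    base.update(overrides)
    return ModelConfig(**base)


def fast_train_config(**overrides) -> TrainConfig:
    base = dict(lr=3e-3, max_epochs=60, seed=0)
    base.update(overrides)
    return TrainConfig(**base)


def fixed_relu_net():
    """A small fixed two-layer ReLU network and a probe input.

    Along the straight path from the zero baseline each hidden unit's
    pre-activation is linear, so the gradient is piecewise constant with
    at most one kink per unit; the weights are sized so the midpoint
    integration error at a few hundred steps is well below 1e-3.
    """
    from combosyn.nn import Tensor

    W1 = np.array([
        [0.5, -0.3, 0.2, 0.1, -0.4],
        [0.2, 0.4, -0.5, 0.3, 0.1],
        [-0.3, 0.2, 0.1, -0.2, 0.5],
        [0.1, -0.1, 0.3, 0.4, -0.2],
    ])
    b1 = np.array([[0.05, -0.1, 0.2, -0.05, 0.1]])
    W2 = np.array([[0.6], [-0.4], [0.5], [0.3], [-0.2]])
    x = np.array([1.2, -0.7, 0.4, 0.9])

    def f(X):
        return ((X @ Tensor(W1) + Tensor(b1)).relu() @ Tensor(W2)).reshape(-1)

    return f, x


@pytest.fixture(scope="session")
def small_fixture():
    """(comb_df, gene_df, protein_df, truth) from the scaled generator."""
    return cs.make_fixture(small_synth_config())


@pytest.fixture(scope="session")
def small_bundle(small_fixture):
    comb, gdf, pdf, _ = small_fixture
    return cs.assemble_bundle(comb, gdf, pdf)


def standardized_copy(bundle, train_line_ids=None):
    """Deep-enough copy of a bundle with freshly standardized omics."""
    import copy

    b = cs.DatasetBundle(
        records=list(bundle.records),
        graphs=dict(bundle.graphs),
        fingerprints=dict(bundle.fingerprints),
        omics=copy.deepcopy(bundle.omics),
        audit=dict(bundle.audit),
    )
    cs.standardize_omics(b, train_line_ids or b.cell_line_ids)
    return b
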