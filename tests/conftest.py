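import numpy as np
import pandas as pd
import pytest

from cerna_forge.model import Config, ExpressionMatrix
from cerna_forge.simulate import SimulationSpec, simulate_expression


def make_matrix(values, gene_ids=None, biotypes=None, n_pairs=None):
    """Small ExpressionMatrix helper: columns alternate case/control pairs."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    assert n_samples % 2 == 0
    n_pairs = n_pairs or n_samples // 2
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    samples = [f"case_{i}" for i in range(n_pairs)] + [f"ctrl_{i}" for i in range(n_pairs)]
    biotypes = biotypes or ["mRNA"] * n_genes
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_ids, columns=samples),
        biotype_of=dict(zip(gene_ids, biotypes)),
        group_of={s: ("case" if s.startswith("case") else "control") for s in samples},
        pair_of={s: int(s.split("_")[1]) for s in samples},
    )


@pytest.fixture
def default_config():
    return Config()


@pytest.fixture(scope="session")
def small_spec():
    """A fast spec used where planted structure, not scale, is under test."""
    return SimulationSpec(
        n_lnc=40, n_mrna=50, n_mirna=30,
        n_de_lnc=8, n_de_mrna=8, n_de_mirna=8,
        n_triplets=5, n_pairs=10, seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return simulate_expression(small_spec)
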