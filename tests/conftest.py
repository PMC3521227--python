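import numpy as np
import pandas as pd
import pytest

from pathagg.data_io import CASE, CONTROL, ExpressionDataset, GeneSet, GeneSetCollection


def make_dataset(values, labels, genes=None, samples=None, name="toy"):
    """Build an ExpressionDataset from a 2-D array and a label sequence."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return ExpressionDataset(
        name=name,
        values=pd.DataFrame(values, index=genes, columns=samples),
        labels=pd.Series(list(labels), index=samples),
    )


def balanced_labels(n_per_class):
    return [CONTROL] * n_per_class + [CASE] * n_per_class


def random_dataset(rng, n_genes, n_control, n_case, name="rand"):
    values = rng.normal(size=(n_genes, n_control + n_case))
    return make_dataset(values, [CONTROL] * n_control + [CASE] * n_case, name=name)


def collection_of(*member_lists, prefix="P"):
    return GeneSetCollection.from_sets(
        GeneSet(f"{prefix}{i}", "", tuple(m)) for i, m in enumerate(member_lists)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
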