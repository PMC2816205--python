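import numpy as np
import pandas as pd
import pytest

from coexpredict import ExpressionDataset, TargetSet


def make_random_dataset(
    seed,
    n_genes=30,
    n_strains=3,
    n_timepoints=4,
    n_replicates=1,
    n_targets=3,
    prediction_strain=None,
):
    """A random (structure-free) dataset with the first genes as masked targets.

    Returns (masked dataset, target set, gold-standard frame).
    """
    rng = np.random.default_rng(seed)
    strains = [f"s{i}" for i in range(n_strains)]
    prediction_strain = prediction_strain or strains[-1]
    timepoints = np.arange(n_timepoints) * 10.0
    genes = [f"g{i:03d}" for i in range(n_genes)]
    values = rng.normal(5.0, 2.0, (n_genes, n_strains, n_timepoints, n_replicates))
    ds = ExpressionDataset(genes, strains, prediction_strain, timepoints, values)
    targets = TargetSet(tuple(genes[:n_targets]), prediction_strain)
    truth = pd.DataFrame(
        values[:n_targets, strains.index(prediction_strain)].mean(axis=2),
        index=genes[:n_targets],
        columns=timepoints,
    )
    return ds.mask_targets(targets), targets, truth


@pytest.fixture
def random_dataset():
    return make_random_dataset(seed=42)


@pytest.fixture
def tiny_fixture():
    from coexpredict import make_fixture

    return make_fixture("tiny", seed=7)
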