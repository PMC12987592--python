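import numpy as np
import pytest

from circdsa.data_io import AssociationMatrix, RunConfig
from circdsa.similarity import sequence_similarity, structure_similarity
from circdsa.synthetic_data import SyntheticSpec, generate_dataset


@pytest.fixture()
def toy_Y():
    """The 3x3 worked example: every drug has degree 2, N = 6."""
    return AssociationMatrix(
        [[1, 1, 0], [1, 0, 1], [0, 1, 1]],
        ["c1", "c2", "c3"], ["d1", "d2", "d3"])


@pytest.fixture(scope="session")
def small_dataset():
    """Desk-scale dataset for fast mechanical tests (not the default spec)."""
    spec = SyntheticSpec(n_circ=40, n_drug=30, rank=3, density=0.1,
                         n_clusters=3, seq_length=60, fp_length=64, seed=11)
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def small_kernels(small_dataset):
    ds = small_dataset
    return (sequence_similarity(ds.sequences, ds.Y.circ_ids),
            structure_similarity(ds.fingerprints, ds.Y.drug_ids))


@pytest.fixture(scope="session")
def fast_config():
    """Reduced-epoch configuration for mechanics tests; defaults otherwise."""
    return RunConfig(collab_epochs=30, warmup_epochs=10, stageb_epochs=40,
                     folds=3, seed=5)


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic dataset used by the recovery/ablation checks."""
    return generate_dataset(SyntheticSpec(seed=0))


@pytest.fixture(scope="session")
def default_kernels(default_dataset):
    ds = default_dataset
    return (sequence_similarity(ds.sequences, ds.Y.circ_ids),
            structure_similarity(ds.fingerprints, ds.Y.drug_ids))
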