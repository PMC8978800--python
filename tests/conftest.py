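import numpy as np
import pytest

from dwppi import RunConfig, SyntheticSpec
from dwppi.synthetic import generate_in_memory


@pytest.fixture(scope="session")
def small_spec():
    """A miniature planted-partition dataset for fast unit tests."""
    return SyntheticSpec(
        n_proteins=60,
        n_blocks=3,
        p_in=0.35,
        p_out=0.03,
        seq_length_range=(60, 120),
        motif_length=6,
        motifs_per_block=2,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    """(graph, block assignment, sequence records, labeled pairs)."""
    return generate_in_memory(small_spec)


@pytest.fixture(scope="session")
def fast_config():
    """Down-scaled hyperparameters so embedding/classifier tests stay quick."""
    return RunConfig(
        sigma=16,
        walks_per_node=4,
        walk_length=16,
        window=3,
        sg_epochs=2,
        cbow_epochs=2,
        epochs=15,
        folds=3,
        tower_widths=(16,),
        fused_widths=(16, 8),
        batch_size=64,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
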