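import numpy as np
import pandas as pd
import pytest

from chicogs.genome_model import Fragment, FragmentMap, InteractionSet, PIRSet
from chicogs.synthetic import SyntheticGenomeSpec, make_genome


@pytest.fixture(scope="session")
def genome_small():
    """A small synthetic genome shared by the cheaper integration tests."""
    spec = SyntheticGenomeSpec(
        n_blocks=6, variants_per_block=(40, 60), n_genes=50
    )
    return make_genome(spec, seed=7)


@pytest.fixture
def toy_fmap():
    """Ten contiguous 1-kb fragments on one chromosome, ids 1..10."""
    return FragmentMap(
        [Fragment(i, "chr1", (i - 1) * 1000, i * 1000) for i in range(1, 11)]
    )


@pytest.fixture
def toy_interactions():
    df = pd.DataFrame(
        {
            "bait_id": [1, 1, 2, 5],
            "oe_id": [3, 4, 3, 8],
            "activated": [5.1, 4.9, 6.0, 0.2],
            "non_activated": [2.0, 7.5, 6.0, 5.5],
        }
    )
    return InteractionSet(df, ["activated", "non_activated"])


def make_pir_sets(test_ids, control_ids):
    return (
        PIRSet("test", frozenset(test_ids)),
        PIRSet("control", frozenset(control_ids)),
    )
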