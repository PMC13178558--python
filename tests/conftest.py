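import numpy as np
import pandas as pd
import pytest

from burstfish import ZINBParams, sample_zinb


def make_counts(values, strain="wt", condition_uM=0.0):
    """Hand-built count table from a plain list of counts."""
    values = list(values)
    return pd.DataFrame(
        {
            "cell_id": [f"c{i:04d}" for i in range(len(values))],
            "strain": strain,
            "condition_uM": float(condition_uM),
            "count": np.asarray(values, dtype=np.int64),
        }
    )


@pytest.fixture
def canonical_params():
    """The reference ZINB parameter set used throughout the recovery tests."""
    return ZINBParams(omega=0.5, r=2.0, p=0.7)


@pytest.fixture
def small_counts(canonical_params):
    """A 20-cell draw, small enough for brute-force posterior work."""
    return sample_zinb(canonical_params, 20, seed=11)
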