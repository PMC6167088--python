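import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles.py importable

from scdisp.data import ExpressionDataset


@pytest.fixture
def tiny_ds():
    """3 biological genes + 1 spike-in x 4 cells."""
    counts = np.array(
        [
            [0, 1, 2, 3],
            [3, 0, 0, 0],
            [2, 2, 2, 2],
            [5, 4, 6, 5],
        ]
    )
    return ExpressionDataset(
        counts=counts,
        gene_ids=np.array(["a", "b", "c", "spk"], dtype=object),
        is_spike=np.array([False, False, False, True]),
        batch=np.array(["b1", "b1", "b2", "b2"]),
        spike_input=np.array([5.0]),
    )


@pytest.fixture(scope="session")
def small_fit():
    """A short but real spikes-model fit on simulated data (shared)."""
    from scdisp.sampler_spikes import run_chain
    from scdisp.simulate import default_truth, simulate_spikes

    truth = default_truth(n_genes=120, n_cells=40, seed=5)
    ds = simulate_spikes(truth, seed=6)
    chain = run_chain(ds, n_iter=1200, burn_in=600, thin=3, seed=7)
    return truth, ds, chain
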