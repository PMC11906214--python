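import numpy as np
import pytest

from flyephys import synthgen
from flyephys.gmm_interval_model import SecondOrderIntervalModel


@pytest.fixture(scope="session")
def three_cluster_spec():
    return synthgen.three_cluster_spec()


@pytest.fixture(scope="session")
def three_cluster_train(three_cluster_spec):
    """A 5000-event PSP train from the canned cyclic three-component mixture."""
    return synthgen.gen_psp_train(three_cluster_spec, n_events=5000, mean_rate=5.0, seed=3)


@pytest.fixture(scope="session")
def fitted_results(three_cluster_train):
    """Second-order mixture fitted (k=3) to the canned train."""
    model = SecondOrderIntervalModel.from_event_series([np.diff(three_cluster_train)])
    return model.fit(k_range=(3,), seed=0, n_restarts=2)
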