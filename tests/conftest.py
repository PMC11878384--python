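import logging

import numpy as np
import pytest

from efcpipe.design import StimulusDesign, StimulusEvent
from efcpipe.synth import default_design, simulate_dataset, two_subnetwork_truth

logging.disable(logging.WARNING)


@pytest.fixture
def small_design() -> StimulusDesign:
    """Three blocks per condition, short run, TR 2 s."""
    events = []
    onset = 30.0
    for cond in ("heat", "heat_fus", "fus", "heat", "heat_fus", "fus"):
        events.append(StimulusEvent(onset=onset, duration=16.0, condition=cond))
        onset += 46.0
    return StimulusDesign(tr=2.0, n_volumes=int(np.ceil(onset / 2.0)), events=tuple(events))


@pytest.fixture
def paper_scale_design() -> StimulusDesign:
    return default_design(rng_seed=7)


@pytest.fixture
def truth():
    return two_subnetwork_truth(n_rois=8, suppression_factor=0.6, noise_sd=0.4)


@pytest.fixture
def dataset(paper_scale_design, truth):
    return simulate_dataset(paper_scale_design, truth, rng_seed=11)
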