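import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from apcdetect.model import Deployment
from apcdetect.synthetic import SimConfig, generate_deployment, truth_to_events


@pytest.fixture(scope="session")
def clean_deployment():
    """Small high-SNR deployment without distractors, prepared for detection."""
    cfg = SimConfig(seed=11, n_dives=6)
    accel, depth, truth = generate_deployment(cfg)
    dep = Deployment("T1", accel, depth, truth_to_events(truth)).prepare()
    return dep, truth, cfg


@pytest.fixture(scope="session")
def distractor_deployment():
    """Deployment with non-feeding head-movement bursts injected."""
    cfg = SimConfig(seed=19, n_dives=8, distractor_rate=1.0)
    accel, depth, truth = generate_deployment(cfg)
    dep = Deployment("T2", accel, depth, truth_to_events(truth)).prepare()
    return dep, truth, cfg
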