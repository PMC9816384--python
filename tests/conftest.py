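import numpy as np
import pytest

import microkmer as mk


@pytest.fixture(scope="session")
def planted_templates() -> mk.TemplateSet:
    return mk.make_templates(4, 32, seed=7)


@pytest.fixture(scope="session")
def dwell_model() -> mk.MarkovModel:
    """4-state chain with ~100 ms geometric dwell at 128 Hz."""
    return mk.MarkovModel.with_dwell(4, 0.1, 128.0)


@pytest.fixture(scope="session")
def planted_sequence(dwell_model) -> mk.MicrostateSequence:
    return mk.sample_microstate_sequence(dwell_model, 2000, 128.0, seed=2)


@pytest.fixture(scope="session")
def noiseless_recording(planted_templates, planted_sequence) -> mk.EEGRecording:
    return mk.synthesize_recording(planted_templates, planted_sequence,
                                   snr=1e9, seed=3)


@pytest.fixture(scope="session")
def noisy_recording(planted_templates, planted_sequence) -> mk.EEGRecording:
    return mk.synthesize_recording(planted_templates, planted_sequence,
                                   snr=4.0, seed=3)


@pytest.fixture(scope="session")
def synthetic_clustering_config() -> mk.ClusteringConfig:
    """Smoothing window matched to the 100 ms synthetic GFP envelope."""
    return mk.ClusteringConfig(smoothing_window=5)
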