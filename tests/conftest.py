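"""Shared fixtures: small synthetic corpora, featurized once per session."""

import numpy as np
import pytest

from somnostage.pipeline import featurize_night
from somnostage.synth import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def tiny_corpus():
    """Six subjects x one 60-epoch night, default montage, fixed seed."""
    cfg = SynthConfig(n_epochs=60)
    return generate_dataset(cfg, n_subjects=6, seed=1234)


@pytest.fixture(scope="session")
def tiny_features(tiny_corpus):
    return [featurize_night(n.recording, n.hypnogram) for n in tiny_corpus]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
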