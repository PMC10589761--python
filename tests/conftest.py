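import numpy as np
import pandas as pd
import pytest

from ldlsim.engine import Lexicon
from ldlsim.synth import SynthConfig, make_experiment


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_lexicon():
    """Five short words with hand-sized embeddings and full structure."""
    words = ["back", "lack", "tack", "sack", "rock"]
    rng = np.random.default_rng(7)
    S = rng.normal(size=(5, 4))
    return Lexicon.build(words, S)


@pytest.fixture(scope="session")
def small_experiment():
    """A complete small synthetic experiment (1 subject, 400 trials)."""
    cfg = SynthConfig(n_subjects=1, n_words=60, trials_per_subject=400,
                      block_size=100, n_sessions=4, seed=42)
    return cfg, make_experiment(cfg)


def make_trials(stimuli, lexicality, responses, subject=1, session=1):
    """Assemble a minimal ordered trial table for engine tests."""
    n = len(stimuli)
    return pd.DataFrame({
        "subject": subject,
        "trial": np.arange(1, n + 1),
        "block": 1,
        "session": session,
        "stimulus": stimuli,
        "lexicality": lexicality,
        "response": responses,
        "rt": 600.0,
    })
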