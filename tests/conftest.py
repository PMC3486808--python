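import numpy as np
import pytest

from cortimbre import synth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_dataset():
    """A small benchmark: 11 instruments x 12 notes (shared across tests)."""
    return synth.make_dataset(12, seed=7)


@pytest.fixture(scope="session")
def violin_note():
    return synth.synth_note(synth.INSTRUMENTS["violin"], seed=11)


@pytest.fixture(scope="session")
def violin_spectrogram(violin_note):
    from cortimbre import pipeline

    return pipeline.note_spectrogram(violin_note)
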