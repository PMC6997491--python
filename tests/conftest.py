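import numpy as np
import pytest

from somnistage import (
    default_hypnogram_model,
    default_templates,
    generate_hypnogram,
    synthesize_record,
)


@pytest.fixture(scope="session")
def templates():
    return default_templates()


@pytest.fixture(scope="session")
def short_night(templates):
    """A clean 20-epoch synthetic night at 125 Hz with known hypnogram."""
    model = default_hypnogram_model(20)
    hyp = generate_hypnogram(model, seed=42)
    return synthesize_record(hyp, templates, sampling_rate=125.0, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
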