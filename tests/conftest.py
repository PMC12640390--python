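import numpy as np
import pytest

from embryostage.ontology import ALL_STAGES, parse_label
from embryostage.postprocess import FramePrediction, PredictionSequence


def labels_of(*names):
    """Expand 'name' or ('name', count) specs into a StageLabel list."""
    out = []
    for item in names:
        if isinstance(item, tuple):
            name, count = item
        else:
            name, count = item, 1
        out.extend([parse_label(name)] * count)
    return out


def prediction_vector(name: str, confidence: float) -> np.ndarray:
    """Probability vector with ``confidence`` on ``name``, rest spread evenly."""
    label = parse_label(name)
    probs = np.full(len(ALL_STAGES), (1.0 - confidence) / (len(ALL_STAGES) - 1))
    probs[label.ordinal] = confidence
    return probs


def make_sequence(spec, video_id="vid", interval=20.0) -> PredictionSequence:
    """Build a PredictionSequence from (label_name, confidence) pairs."""
    frames = tuple(
        FramePrediction.from_probabilities(i, i * interval, prediction_vector(name, conf))
        for i, (name, conf) in enumerate(spec)
    )
    return PredictionSequence(video_id, frames)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
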