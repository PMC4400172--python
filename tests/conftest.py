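import numpy as np
import pytest

from entrainkit.synth import DebateConfig, GenerativeTruth
from entrainkit.pipeline import simulate_event
from entrainkit.timeline import DebateAnnotation, Message, SpeechTurn


@pytest.fixture
def toy_annotation() -> DebateAnnotation:
    """Two clean 10-s turns: A then B."""
    return DebateAnnotation(
        onset_timestamp=1000.0,
        duration_s=20.0,
        speakers=("a", "b"),
        turns=[
            SpeechTurn(speaker="a", start_s=0.0, end_s=10.0),
            SpeechTurn(speaker="b", start_s=10.0, end_s=20.0),
        ],
    )


@pytest.fixture
def filter_fixture_messages() -> list[Message]:
    """The four-message hand-enumeration fixture."""
    return [
        Message(timestamp=1000.5, text="Obama wins"),
        Message(timestamp=1001.0, text="RT @x Obama"),
        Message(timestamp=1002.0, text="Romney http://a.b"),
        Message(timestamp=1003.0, text="obama & romney"),
    ]


@pytest.fixture(scope="session")
def small_event():
    """A short (1200 s) simulated event shared by fit-shaped unit tests."""
    return simulate_event(seed=11, config=DebateConfig(duration_s=1200.0))


@pytest.fixture(scope="session")
def default_event():
    """A full-length (5400 s) simulated event at the default study conditions."""
    return simulate_event(seed=23)


def rate_ratio_truth(boost: float) -> GenerativeTruth:
    """Truth with only the speaker boost on (for ratio-style oracles)."""
    return GenerativeTruth(
        speaker_boost=boost,
        speaking_time_slope_own=0.0,
        speaking_time_slope_cross=0.0,
        interruption_boost=1.0,
        quad_coeffs=(0.0, 0.0),
        meme_kernels=(),
        retweet_fraction=0.0,
        url_spam_rate=0.0,
    )


def brute_force_bin(messages, onset, duration, bin_width):
    """Independent binning oracle: test each message against each bin interval."""
    n = int(np.ceil(duration / bin_width))
    counts = np.zeros(n, dtype=int)
    dropped = 0
    for m in messages:
        placed = False
        for k in range(n):
            lo = onset + k * bin_width
            hi = onset + (k + 1) * bin_width
            if lo <= m.timestamp < hi and m.timestamp < onset + duration:
                counts[k] += 1
                placed = True
                break
        if not placed:
            dropped += 1
    return counts, dropped
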