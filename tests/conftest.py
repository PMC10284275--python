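import numpy as np
import pytest

from elevdec.dictionary import EmotionDictionary
from elevdec.synthetic import SimulationConfig


@pytest.fixture
def tiny_dictionary() -> EmotionDictionary:
    """A handful of entries at each score level plus default modifiers."""
    return EmotionDictionary(
        entries={
            "touching": 2, "inspiring": 2,
            "nice": 1, "kind": 1,
            "lol": 0, "first": 0,
        },
        negators=frozenset({"not", "never"}),
        degree_words={"a little": 0.75, "more": 1.25, "very": 1.5, "most": 2.0},
    )


@pytest.fixture
def small_sim_config() -> SimulationConfig:
    """A scaled-down study: 3 participants, 8 channels, 55 s."""
    return SimulationConfig(
        n_participants=3,
        channel_names=("Fz", "F4", "FC2", "P7", "P8", "Cz", "Pz", "Oz"),
        video_durations_s=(30, 25),
        comment_rate=20.0,
        seed=7,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
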