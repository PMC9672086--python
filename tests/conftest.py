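import numpy as np
import pytest
from hypothesis import settings

from bedmot.lexicon import Lexicon

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def tiny_lexicon() -> Lexicon:
    """Minimal Danish-style fixture lexicon used throughout the rule tests."""
    return Lexicon(
        valences={"god": 3.0, "fantastisk": 5.0, "dårlig": -2.0, "forfærdelig": -4.0, "neutral": 0.0},
        modifiers={"meget": 1.5, "lidt": 0.5},
        negators={"ikke", "aldrig"},
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
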