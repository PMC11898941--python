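import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_table():
    """A hand-built score table: 6 known queries (3 classes) + 4 unknowns.

    Known rows: (true, predicted, score)
      a a 0.9 | a a 0.8 | b b 0.7 | b c 0.6 | c c 0.85 | c c 0.4
    Unknown rows: scores 0.75, 0.5, 0.3, 0.2 (predictions arbitrary knowns).
    """
    from herdid.gallery import UNKNOWN
    from herdid.openset_eval import OpenSetScoreTable

    true = ["a", "a", "b", "b", "c", "c", UNKNOWN, UNKNOWN, UNKNOWN, UNKNOWN]
    pred = ["a", "a", "b", "c", "c", "c", "a", "b", "c", "a"]
    score = [0.9, 0.8, 0.7, 0.6, 0.85, 0.4, 0.75, 0.5, 0.3, 0.2]
    return OpenSetScoreTable(true_labels=np.array(true, dtype=object),
                             predicted=np.array(pred, dtype=object),
                             scores=np.array(score))
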