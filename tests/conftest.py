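import numpy as np
import pytest

import hosbeat as hb


@pytest.fixture(scope="session")
def small_dataset():
    """40 beats per class, default templates, fixed seed."""
    return hb.generate_dataset({c: 40 for c in hb.CLASSES}, seed=7)


@pytest.fixture(scope="session")
def one_beat_per_class():
    return [hb.generate_beat(c, seed=11 + i) for i, c in enumerate(hb.CLASSES)]


@pytest.fixture(scope="session")
def fast_ga():
    """GA config trimmed for unit tests (fewer generations, same structure)."""
    return hb.GAConfig(generations=12, seed=0)


@pytest.fixture(scope="session")
def tiny_classifier(one_beat_per_class, fast_ga):
    """Fused classifier trained on one beat per class."""
    return hb.CumulantHermite1NN(ga_config=fast_ga, random_state=3).fit(
        one_beat_per_class)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
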