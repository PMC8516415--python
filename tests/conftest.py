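import numpy as np
import pytest

import somnostage as ss


@pytest.fixture(scope="session")
def short_night():
    """One 1-hour synthetic night (120 epochs) shared across tests."""
    hm = ss.HypnogramModel(n_epochs=120)
    return ss.generate_night(11, hm=hm)


@pytest.fixture(scope="session")
def short_features(short_night):
    rec, _hyp = short_night
    return ss.night_features(rec)


@pytest.fixture(scope="session")
def small_model(short_night, short_features):
    """A quick low-capacity model for unit tests."""
    _rec, hyp = short_night
    hp = ss.Hyperparameters(n_estimators=60, seed=7)
    return ss.fit(short_features, hyp, hp)


def random_hypnogram(rng: np.random.Generator, n: int, unscored_frac: float = 0.0) -> ss.Hypnogram:
    stages = np.asarray(ss.STAGES)[rng.integers(0, 5, n)].astype("<U3")
    if unscored_frac > 0:
        stages[rng.random(n) < unscored_frac] = ss.UNSCORED
    return ss.Hypnogram(stages=stages)
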