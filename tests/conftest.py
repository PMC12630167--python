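"""Shared fixtures: small synthetic event sets and a tiny trained model.

Everything is generated programmatically at test time; 32-px frames at
4 um/px keep training fast while preserving the morphological contrasts
(smooth droplets vs textured pollen) the classifier relies on.
"""

import numpy as np
import pytest

import holopollen as hp
from holopollen.utils import derive_seed

SIDE = 32
SCALE = 4.0


def make_events(profiles, classes, n_per_class, seed, side=SIDE, scale=SCALE):
    events = []
    for name in classes:
        for j in range(n_per_class):
            events.append(hp.generate_event(
                profiles[name], "2024-06-01T10:00", "testsite",
                derive_seed(seed, name, j), image_side=side, pixel_scale=scale,
            ))
    rng = np.random.default_rng(seed)
    rng.shuffle(events)
    return events


@pytest.fixture(scope="session")
def profiles():
    return hp.default_profiles()


@pytest.fixture(scope="session")
def small_events(profiles):
    """30 mixed events (grass/Betula/droplet) at 32 px."""
    return make_events(profiles, ("Poaceae", "Betula", "droplet"), 10, seed=7)


@pytest.fixture(scope="session")
def tiny_fit(profiles):
    """A quickly trained 2-class grass/droplet model plus its test set."""
    train = make_events(profiles, ("Poaceae", "droplet"), 40, seed=11)
    test = make_events(profiles, ("Poaceae", "droplet"), 15, seed=12)
    cfg = hp.ModelConfig(
        class_names=("Poaceae", "droplet"), image_side=SIDE,
        conv_blocks=((8, 1), (16, 1)), epochs=4, rng_seed=0,
    )
    fit = hp.PollenClassifier(cfg).fit(train, test)
    return fit, train, test
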