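import numpy as np
import pytest
from hypothesis import settings

from graspquant.classification import build, train
from graspquant.config import PipelineConfig
from graspquant.pipeline import training_set_for_finger
from graspquant.synthetic import default_templates

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def templates():
    return default_templates()


@pytest.fixture(scope="session")
def default_config():
    return PipelineConfig(seed=0)


@pytest.fixture(scope="session")
def training_sets(default_config, templates):
    """Per-finger (images, labels) of the static training protocol, cached."""
    cache = {}

    def get(finger):
        if finger not in cache:
            cache[finger] = training_set_for_finger(finger, default_config, templates)
        return cache[finger]

    return get


@pytest.fixture(scope="session")
def trained_models(training_sets):
    """Per-finger classifiers trained with the default protocol (seed 0)."""
    cache = {}

    def get(finger):
        if finger not in cache:
            images, labels = training_sets(finger)
            model = build(finger)
            report = train(model, images, labels, seed=0)
            cache[finger] = (model, report)
        return cache[finger]

    return get


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
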