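import numpy as np
import pytest
from hypothesis import settings

from foveloc.classifier import ClassifierSpec, train
from foveloc.scene import SceneParams, generate_scene, make_labeled_bscans

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")

# study conditions of the classifier experiments: a 60-image balanced
# set of synthetic B-scans, trained with the default 30-epoch batch-12
# recipe at a 64x64 resize
TRAIN_SET_SEED = 11
TRAIN_SPEC = ClassifierSpec(input_size=(64, 64), seed=1)


@pytest.fixture(scope="session")
def labeled_set():
    images, labels = make_labeled_bscans(30, 30, seed=TRAIN_SET_SEED)
    return images, labels


@pytest.fixture(scope="session")
def trained_classifier(labeled_set):
    """One full default-recipe training run, shared across the session."""
    images, labels = labeled_set
    model, report = train(images, labels, TRAIN_SPEC)
    return model, report


@pytest.fixture(scope="module")
def default_scene():
    return generate_scene(SceneParams())
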