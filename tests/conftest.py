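import numpy as np
import pytest

from myotune.preprocess import SEMGImageSet, SegmentationSpec, session_to_images
from myotune.synth import (
    GestureProtocol,
    make_subject_model,
    synthesize_session,
)


@pytest.fixture(scope="session")
def default_protocol():
    return GestureProtocol()


@pytest.fixture(scope="session")
def small_protocol():
    """Short schedule: 3 classes, 2 reps, 2 s contraction, 1 s rest, 4 channels."""
    return GestureProtocol(
        n_classes=3, n_reps=2, contraction_s=2.0, rest_s=1.0, fs=200.0, n_channels=4
    )


@pytest.fixture(scope="session")
def small_session(small_protocol):
    model = make_subject_model(small_protocol, separability=0.8, seed=11)
    return synthesize_session(model, small_protocol, seed=12)


@pytest.fixture(scope="session")
def small_images(small_session):
    return session_to_images(small_session, SegmentationSpec("overlap", 200.0, 0.8))


@pytest.fixture(scope="session")
def toy_separable():
    """Two-class constant-image toy set: class 0 all zeros, class 1 all ones."""
    imgs = np.concatenate(
        [np.zeros((12, 4, 8), dtype=np.float32), np.ones((12, 4, 8), dtype=np.float32)]
    )
    labels = np.array([0] * 12 + [1] * 12)
    return SEMGImageSet(imgs, labels)
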