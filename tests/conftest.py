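import numpy as np
import pytest

from consensusconf import (
    BehavioralDataset,
    LuminanceTransform,
    ModelParams,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def params():
    """Default (full-size) parameter set."""
    return ModelParams()


@pytest.fixture
def small_params():
    """A few modules: fast enough for unit tests of the dynamics."""
    return ModelParams(n_modules=9)


@pytest.fixture
def transform():
    return LuminanceTransform()


def make_dataset(
    lum,
    choice,
    confidence,
    rt,
    target_patch=None,
    mean_target=55.0,
    frame_ms=40.0,
):
    """Hand-build a behavioral dataset from explicit per-trial arrays."""
    lum = np.asarray(lum, dtype=float)
    n = lum.shape[0]
    if target_patch is None:
        target_patch = np.zeros(n, dtype=int)
    target_patch = np.asarray(target_patch)
    means = np.full((n, 2), 50.0)
    np.put_along_axis(
        means, target_patch[:, None], np.full((n, 1), mean_target), axis=1
    )
    return BehavioralDataset(
        lum=lum,
        nominal_means=means,
        target_patch=target_patch,
        choice=np.asarray(choice),
        confidence=np.asarray(confidence, dtype=float),
        rt=np.asarray(rt, dtype=float),
        frame_ms=frame_ms,
    )


@pytest.fixture
def dataset_factory():
    return make_dataset
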