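import numpy as np
import pytest

import camroad as cr
from camroad import nn


@pytest.fixture(scope="session")
def dataset():
    """The default synthetic lesion dataset (n=400, contrast 0.4, seed 0)."""
    return cr.make_dataset(n=400, contrast=0.4, seed=0)


@pytest.fixture(scope="session")
def trained(dataset):
    """The test-bed CNN trained once for the whole session, plus its metrics."""
    model = cr.make_tiny_cnn(seed=0)
    metrics = cr.train_fixture(model, dataset, epochs=10, seed=0)
    model.eval()
    return model, metrics


@pytest.fixture(scope="session")
def trained_model(trained):
    return trained[0]


@pytest.fixture(scope="session")
def lesion_samples(dataset):
    """Ten held-out test images of the lesion class."""
    return [s for s in dataset.test if s.label == 1][:10]


def build_gap_model(conv_weight: float = 1.0, head_weight: float = 1.0,
                    size: int = 8) -> nn.Sequential:
    """One-channel model y = head_weight * GAP(conv_weight * x).

    The closed-form CAM oracle: the class-score gradient at the conv output
    is head_weight / (H*W) everywhere, so a GradCAM map is proportional to
    the activation itself.
    """
    conv = nn.Conv2d(1, 1, 1, bias=True)
    conv.params["weight"][:] = conv_weight
    conv.params["bias"][:] = 0.0
    head = nn.Linear(1, 1, bias=True)
    head.params["weight"][:] = head_weight
    head.params["bias"][:] = 0.0
    return nn.Sequential(
        [("conv", conv), ("gap", nn.GlobalAvgPool()),
         ("flatten", nn.Flatten()), ("head", head)],
        input_shape=(1, size, size),
    )


def build_two_logit_model(size: int = 8) -> nn.Sequential:
    """Two classes with spatially disjoint evidence: left half vs right half.

    The conv copies the image into two channels, a fixed mask layer restricts
    channel 0 to the left half and channel 1 to the right half, and an
    identity head turns each channel's spatial mean into a logit.
    """
    conv = nn.Conv2d(1, 2, 1, bias=True)
    conv.params["weight"][:] = 1.0
    conv.params["bias"][:] = 0.0
    masks = np.zeros((2, size, size))
    masks[0, :, : size // 2] = 1.0
    masks[1, :, size // 2 :] = 1.0
    head = nn.Linear(2, 2, bias=True)
    head.params["weight"][:] = np.eye(2)
    head.params["bias"][:] = 0.0
    return nn.Sequential(
        [("conv", conv), ("halves", nn.ChannelMask(masks)),
         ("gap", nn.GlobalAvgPool()), ("flatten", nn.Flatten()), ("head", head)],
        input_shape=(1, size, size),
    )


@pytest.fixture
def gap_model():
    return build_gap_model()


@pytest.fixture
def two_logit_model():
    return build_two_logit_model()
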