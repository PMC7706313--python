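"""Shared fixtures: the synthetic 4-class leaf dataset and a trained
fixture classifier (session-scoped; training takes ~15 s once)."""

import numpy as np
import pytest

from leafscope import attention as att
from leafscope import synthgen as sg


@pytest.fixture(scope="session")
def class_specs():
    return sg.default_class_specs()


@pytest.fixture(scope="session")
def splits(class_specs):
    return sg.make_dataset(class_specs, n_per_class=40, size=64, seed=0)


@pytest.fixture(scope="session")
def fixture_model(splits):
    model, history = sg.make_fixture_model(splits, arch="tiny_cnn", seed=0)
    return model


@pytest.fixture(scope="session")
def healthy_refs(splits):
    imgs = np.stack([s.image for s in splits.train if s.label == 0][:8])
    return att.ReferenceSet(imgs)


@pytest.fixture(scope="session")
def diseased_test(splits):
    return [s for s in splits.test if s.label != 0][:20]


@pytest.fixture(scope="session")
def inception38():
    from leafscope.netcore import build_inception_v3_like

    return build_inception_v3_like(38, input_size=224)
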