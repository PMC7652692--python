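import numpy as np
import pytest

import fedbench as fb


@pytest.fixture(scope="session")
def image_ds():
    """Small 10-class image train/test pair shared across tests."""
    cfg = fb.GeneratorConfig("image10", n_train=600, n_test=150, seed=11)
    return fb.generate_split_pair(cfg)


@pytest.fixture(scope="session")
def linear_spec():
    return fb.ModelSpec("linear_oracle", n_features=784, n_classes=10)


@pytest.fixture
def tiny_linear_fixture():
    """4-record, 3-feature, 2-class fixture for hand-checked gradients."""
    records = [np.array(r, dtype=float) for r in
               ([1.0, 0.0, -1.0], [0.5, 2.0, 0.0], [-1.0, 1.0, 1.0], [0.0, -0.5, 2.0])]
    labels = np.array([0, 1, 1, 0])
    spec = fb.ModelSpec("linear_oracle", n_features=3, n_classes=2)
    return spec, records, labels
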