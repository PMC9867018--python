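import numpy as np
import pytest

from pollenseg.synth import SyntheticSpec, generate_sample


@pytest.fixture(scope="session")
def clean_sample():
    """One impurity-free, noise-free particle image with ground truth."""
    return generate_sample(
        SyntheticSpec(class_id=0, impurity_count_range=(0, 0), noise_sd=0.0, seed=5)
    )


@pytest.fixture(scope="session")
def cluttered_sample():
    """A particle image with impurity specks under the default conditions."""
    return generate_sample(SyntheticSpec(class_id=0, impurity_count_range=(5, 5), seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def iou(a: np.ndarray, b: np.ndarray) -> float:
    union = (a | b).sum()
    return (a & b).sum() / union if union else 1.0
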