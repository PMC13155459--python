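import numpy as np
import pytest

from xakd.fixtures import (
    ModelSpec,
    SyntheticDatasetSpec,
    build_tiny_teacher,
    build_tiny_vit_student,
    make_synthetic_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """8 classes x 12 images at 32x32 — enough for probing and smoke training."""
    spec = SyntheticDatasetSpec(n_classes=8, n_per_class=12, image_size=32, seed=7)
    return make_synthetic_dataset(spec)


@pytest.fixture(scope="session")
def teacher_spec():
    return ModelSpec(role="teacher", family="convolutional", depth=4, width=8,
                     n_classes=8, image_size=32)


@pytest.fixture(scope="session")
def student_spec():
    return ModelSpec(role="student", family="transformer", depth=4, width=32,
                     patch_size=8, n_heads=4, n_classes=8, image_size=32)


@pytest.fixture
def tiny_teacher(teacher_spec):
    return build_tiny_teacher(teacher_spec)


@pytest.fixture
def tiny_student(student_spec):
    return build_tiny_vit_student(student_spec)


@pytest.fixture
def probe_batch(small_dataset):
    images, _, splits = small_dataset
    return images[splits["train"][:16]]
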