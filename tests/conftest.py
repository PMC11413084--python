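import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tauconcord.synthetic import CohortConfig, ImageSpec, StainModel, render_histology_field

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_field():
    """128x128 field with ~1% planted positive area at default stain."""
    spec = ImageSpec(width=128, height=128, target_positive_fraction=0.01, seed=11)
    return render_histology_field(spec)


@pytest.fixture(scope="session")
def scaled_field_pair():
    """Same planted fraction, two background staining intensities."""
    spec = ImageSpec(width=256, height=256, target_positive_fraction=0.01, seed=5)
    light = render_histology_field(spec, StainModel(per_subject_intensity_scale=1.0))
    dark = render_histology_field(spec, StainModel(per_subject_intensity_scale=1.3))
    return light, dark


@pytest.fixture(scope="session")
def tiny_cohort_config():
    return CohortConfig(n_subjects=30, seed=9, fields_per_region=2, image_size=64)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
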