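import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "fusioncad",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fusioncad")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def planted_table():
    """Balanced 200/class table, 10 features, indices {0, 1} informative at
    effect size 3 -- the reference dataset for both selectors."""
    from fusioncad import PlantedDatasetSpec, make_planted_feature_table

    return make_planted_feature_table(
        PlantedDatasetSpec(
            n_per_class=200, n_features=10, informative_indices=(0, 1),
            effect_size=3.0, seed=42,
        )
    )


@pytest.fixture(scope="session")
def benign_lesion():
    from fusioncad import LesionSpec, make_lesion_image

    spec = LesionSpec(
        modality="MG", class_label="benign", base_radius=30, aspect=1.0,
        spiculation_depth=0.0, noise_level=0.0, seed=3,
    )
    return make_lesion_image(spec)


@pytest.fixture(scope="session")
def malignant_lesion():
    from fusioncad import LesionSpec, make_lesion_image

    spec = LesionSpec(
        modality="MG", class_label="malignant", base_radius=30, aspect=1.0,
        spiculation_count=8, spiculation_depth=0.25, noise_level=0.0, seed=3,
    )
    return make_lesion_image(spec)
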