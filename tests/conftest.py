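import numpy as np
import pytest

from nucleoscore import model_selection, pipeline, synthetic


@pytest.fixture(scope="session")
def small_generator_config() -> synthetic.GeneratorConfig:
    """Compact two-class cohort: 6 patients/class, 1 tile each."""
    return synthetic.GeneratorConfig(
        n_patients_per_class=6,
        images_per_patient=1,
        nuclei_per_image=(14, 20),
        image_size=(224, 224),
        seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_generator_config) -> synthetic.SyntheticDataset:
    return synthetic.generate_dataset(small_generator_config)


@pytest.fixture(scope="session")
def nucleus_table(small_dataset):
    """Per-nucleus 36-feature table for the whole small cohort."""
    return pipeline.nucleus_table_from_dataset(small_dataset)


@pytest.fixture(scope="session")
def patient_table(small_dataset):
    """72-feature patient table for the small cohort."""
    return pipeline.patient_table_from_dataset(small_dataset)


@pytest.fixture(scope="session")
def single_image(small_dataset):
    pat = small_dataset.patients[0]
    return pat.images[0], pat.label_maps[0]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def fast_cv_config() -> model_selection.PipelineConfig:
    """Nested-CV config with a small SVC grid to keep tests quick."""
    return model_selection.PipelineConfig(
        quantile_transform=True,
        standard_scale=True,
        selector="none",
        classifier="svc",
        hyper_grid={"C": [1, 10], "kernel": ["rbf", "linear"]},
        seed=7,
    )
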