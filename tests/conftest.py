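import pytest

from optiscreen.synth import (
    ImageSceneParams,
    RamanCohortParams,
    generate_multimodal_pair,
    generate_raman_cohort,
)


@pytest.fixture(scope="session")
def small_scene():
    """256x256 scene with 2x2 tiles: fast but structurally complete."""
    params = ImageSceneParams(
        image_shape=(256, 256), tile_shape=(128, 128), n_nuclei=40, seed=11
    )
    return params, generate_multimodal_pair(params)


@pytest.fixture(scope="session")
def tiny_cohort():
    """3 individuals x 2 scans on a 12x14 grid: covers all classes."""
    params = RamanCohortParams(
        n_individuals=3, scans_per_individual=2, grid_shape=(12, 14), seed=5
    )
    return params, generate_raman_cohort(params)
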