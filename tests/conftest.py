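import numpy as np
import pytest
from hypothesis import settings

from testecho import synthetic as syn
from testecho.echotexture import UltrasoundFrame
from testecho.pipeline import measure_cohort

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def cohort_cfg():
    return syn.CohortConfig(n_dogs=8, master_seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def cohort(cohort_cfg):
    """Raw exam table for the canonical 8-dog cohort."""
    return syn.generate_cohort(cohort_cfg)


@pytest.fixture(scope="session")
def measured(cohort_cfg):
    """Fully measured cohort: echotexture + morphometry + Doppler re-scoring."""
    return measure_cohort(cohort_cfg)


@pytest.fixture(scope="session")
def default_profile():
    return syn.MaturationProfile()


@pytest.fixture(scope="session")
def adult_parenchyma_mask(default_profile):
    """Parenchyma mask of a mature-testis frame, for Doppler overlay tests."""
    frame = syn.render_bmode_frame(default_profile, 36, seed=11)
    return frame.masks["parenchyma"]


def make_flat_frame(value=100, size=60, mm_per_pixel=0.1, masks=None):
    """Uniform-intensity frame with a full-field parenchyma mask by default."""
    pixels = np.full((size, size), value, dtype=np.uint8)
    if masks is None:
        masks = {"parenchyma": np.ones((size, size), dtype=bool)}
    return UltrasoundFrame(pixels=pixels, mm_per_pixel=mm_per_pixel, masks=masks)
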