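import numpy as np
import pytest

from pibquant.maskbuild import build_roi_set
from pibquant.synthcohort import (
    CentreProfile,
    GeneratorConfig,
    render_gm_probability_maps,
    sample_cohort,
)
from pibquant.templates import build_atlas


@pytest.fixture(scope="session")
def full_atlas():
    return build_atlas()


@pytest.fixture(scope="session")
def full_rois(full_atlas):
    maps = render_gm_probability_maps(10, full_atlas, seed=5)
    return build_roi_set(maps, full_atlas)


@pytest.fixture(scope="session")
def small_grid():
    from pibquant.experiments import reduced_grid
    return reduced_grid()


@pytest.fixture(scope="session")
def default_cohort():
    return sample_cohort(GeneratorConfig(seed=11))


@pytest.fixture
def identity_centre():
    """No blur, no noise, unit dose, four 5-min frames covering 40-60 min."""
    return CentreProfile("ident", psf_fwhm=0.0, noise_sd_fraction=0.0,
                         dose_scale=1.0,
                         frame_schedule=tuple((40.0 + 5 * i, 45.0 + 5 * i)
                                              for i in range(4)))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
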