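import warnings

import numpy as np
import pytest

from astroquant import imaging, mito, synthetic

# scikit-image deprecation chatter from upstream pin differences is not
# actionable here
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def mito_field():
    """Small noiseless field: 3 cells x 8 non-touching filaments."""
    spec = synthetic.SyntheticImageSpec(
        image_size_px=(640, 640), n_cells=3, mito_per_cell=8, seed=7
    )
    return spec, synthetic.generate_image(spec)


@pytest.fixture(scope="session")
def mito_metrics(mito_field):
    spec, (stack, nuclei, cells, truth) = mito_field
    return mito.analyze_mito(stack, nuclei, cells)


@pytest.fixture(scope="session")
def marker_field():
    """Noiseless nucleus field with marker-positive and GFAP-ringed subsets."""
    spec = synthetic.SyntheticImageSpec(
        image_size_px=(512, 512),
        pixel_size_um=0.5,
        n_cells=40,
        nucleus_radius_um=(3.0, 4.5),
        cell_radius_um=(7.0, 11.0),
        mito_per_cell=0,
        frac_marker_pos_nuclei=0.4,
        frac_gfap_among_pos=0.5,
        frac_gfap_pos_cells=0.0,
        noise_sd=0.0,
        seed=3,
    )
    return spec, synthetic.generate_image(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
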