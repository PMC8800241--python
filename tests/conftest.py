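import numpy as np
import pytest

import gliaclust as g


@pytest.fixture(scope="session")
def small_feature_spec():
    """A reduced synthetic layout (fast): 3+3 sections, 14x14 windows,
    6x6-window implant with a 3x3 focal core."""
    return g.SyntheticFeatureSpec(
        n_sections_control=3,
        n_sections_test=3,
        grid_shape=(14, 14),
        activation_rect=(4, 4, 9, 9),
        focal_rect=(6, 6, 8, 8),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_tables(small_feature_spec):
    return g.generate_feature_table(small_feature_spec)


@pytest.fixture(scope="session")
def fitted_small_pipeline(small_tables):
    ctrl, _, _ = small_tables
    return g.fit_pipeline(ctrl, g.OcsvmConfig(nu=0.05, gamma=0.1), min_size=5)


@pytest.fixture(scope="session")
def rendered_section():
    planes, truth = g.render_section(g.SyntheticTissueSpec(seed=5))
    return planes, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
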