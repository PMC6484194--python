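import numpy as np
import pytest

from fcshrink import FisherPanel, SyntheticConfig, TimeSeriesPanel, generate_fisher_panel


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_ts_panel(rng):
    """Random 3-subject, 2-session, 7-voxel, 20-timepoint panel."""
    return TimeSeriesPanel(
        rng.standard_normal((3, 2, 7, 20)),
        subjects=["a", "b", "c"],
        sessions=["1", "2"],
    )


@pytest.fixture
def model_panel():
    """Model-level Fisher panel with known generative variances."""
    cfg = SyntheticConfig(
        n_subjects=20, n_voxels=30, mu_x=0.3, sigma2_x=0.04, sigma2_u=0.01, rng_seed=7
    )
    panel, truth = generate_fisher_panel(cfg)
    return panel, truth, cfg


@pytest.fixture
def hand_panel():
    """3 subjects, 1 voxel, with hand-computable variance components."""
    v = np.array([[[0.1], [0.3]], [[0.2], [0.2]], [[0.0], [0.4]]])
    return FisherPanel(v, subjects=["s1", "s2", "s3"], sessions=["1", "2"])
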