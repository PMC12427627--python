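import numpy as np
import pytest

import neurofuse as nf


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small dual-signal cohort shared by fast end-to-end tests."""
    return nf.generate_cohort(
        n=48, n_features=8, behavioral_effect=2.0, n_informative_features=3,
        roi_effect=2.0, informative_rois=2, shape=(6, 6, 6), n_rois=8,
        missing_rate=0.05, seed=7,
    )


@pytest.fixture
def fast_config():
    """Pipeline configuration scaled down for unit-test speed."""
    cfg = nf.PipelineConfig(seed=3)
    cfg.gami = nf.GAMIConfig(epochs=4, max_interactions=2, seed=3)
    cfg.encoder = nf.EncoderConfig(embed_dim=16, gnn_hidden=8, epochs=3, seed=3)
    cfg.fusion = nf.FusionConfig(epochs=4, seed=3)
    cfg.hypernet = nf.HyperNetConfig(epochs=8, seed=3)
    return cfg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
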