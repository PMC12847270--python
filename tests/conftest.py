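import numpy as np
import pytest

from paddy_soilqual.synth import default_calibration, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One small dataset with the full study design (5 x 2 x 3)."""
    cfg = default_calibration()
    cfg.seed = 42
    cfg.n_taxa = 60
    cfg.count_depth = 5000
    return cfg, generate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
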