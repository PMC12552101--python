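import numpy as np
import pytest

import velotime as vt


@pytest.fixture(scope="session")
def small_linear():
    """120 cells x 30 genes linear simulation (shared, read-only)."""
    cfg = vt.SimulationConfig(n_cells=120, n_genes=30, noise_sd=0.1, seed=0)
    ds, truth = vt.simulate_linear(cfg)
    return ds, truth


@pytest.fixture(scope="session")
def small_fit(small_linear):
    """A quick fit on the small simulation (5 epochs, deterministic)."""
    ds, truth = small_linear
    dsp = vt.preprocess(ds, vt.PreprocessConfig(knn_k=10))
    res = vt.fit(dsp, vt.ModelConfig(seed=0), vt.LossWeights(),
                 vt.TrainConfig(epochs=5, seed=0))
    return dsp, truth, res


@pytest.fixture
def rng():
    return np.random.default_rng(42)
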