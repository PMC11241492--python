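import numpy as np
import pytest

from lactosense.pipeline import PipelineParams, fit_pipeline


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_random_fitted(seed, n=60, p=40, n_components=5):
    """Small fitted pipeline on random continuous-signal binary data."""
    rng = np.random.default_rng(seed)
    X = (rng.random((n, p)) < rng.uniform(0.2, 0.8, p)).astype(float)
    beta = rng.standard_normal(p) * (rng.random(p) < 0.3)
    y = X @ beta + 0.1 * rng.standard_normal(n)
    params = PipelineParams(
        variance_threshold=0.0,
        percentile=80,
        rfecv_step=2,
        min_features_to_select=10,
        scoring="r2",
        n_components=n_components,
    )
    return fit_pipeline(params, X, y, seed=seed)


@pytest.fixture
def fitted_pipeline():
    return make_random_fitted(7)
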