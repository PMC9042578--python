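import numpy as np
import pytest

import infogeom as ig
from infogeom.synthetic_data import builtin_fixtures, generate


@pytest.fixture(scope="session")
def fixtures():
    return builtin_fixtures()


@pytest.fixture(scope="session")
def uninormal_data(fixtures):
    """A seeded univariate-normal dataset (N=10) plus its model/noise."""
    cfg = fixtures["uninormal"].with_seed(3)
    data = generate(cfg)
    model = cfg.build_model()
    noise = ig.NoiseModel(sigma_known=False)
    return model, data, noise


@pytest.fixture(scope="session")
def mvnormal_data(fixtures):
    """A seeded multivariate-normal-means dataset (N=10, sigma known)."""
    cfg = fixtures["mvnormal"].with_seed(1)
    data = generate(cfg)
    model = cfg.build_model()
    noise = ig.NoiseModel(sigma=cfg.sigma)
    return model, data, noise


@pytest.fixture(scope="session")
def normal_metric_n10():
    """Fisher metric field of the (mu, sigma) manifold with N=10."""
    return ig.MetricField.normal(10)
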