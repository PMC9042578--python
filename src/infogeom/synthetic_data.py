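"""Seeded synthetic-data generators for every model in the zoo.

Observations are drawn as x = mu(Theta_truth, t_j) + sigma * z with z
standard normal, independently per replicate, time point and species.
The built-in fixtures encode the study designs used throughout the
package's examples and tests: sample sizes, time points, noise levels
and truth values all come from published parameter estimates for the
coral-regrowth logistic data and the boarding-school influenza SIR
data, plus the plain normal-distribution designs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .observation_models import ObservationSet
from .process_models import get_model

__all__ = ["FixtureConfig", "generate", "builtin_fixtures"]


@dataclass(frozen=True)
class FixtureConfig:
    """A fully specified synthetic-data design.

    ``counts`` may be a scalar (same N at every time) or one entry per
    time point. ``free`` records which coordinates downstream analyses
    infer (metadata; the generator itself always uses the full truth).
    ``positive_only`` optionally rejects-and-redraws negative values;
    default off — the designs instead keep sigma small enough that
    negative draws are improbable.
    """

    model: str
    truth: dict
    times: tuple
    counts: tuple | int = 10
    sigma: float = 1.0
    observed: tuple | None = None
    free: tuple = ()
    seed: int = 0
    positive_only: bool = False

    def counts_array(self) -> np.ndarray:
        return np.broadcast_to(np.atleast_1d(self.counts), (len(self.times),)).astype(int)

    def build_model(self):
        free = self.free if self.free else None
        fixed = dict(self.truth)
        fixed.setdefault("sigma", self.sigma)
        return get_model(self.model, free=free, fixed=fixed, observed=self.observed)

    @property
    def n_total(self) -> int:
        model = self.build_model()
        return int(self.counts_array().sum() * len(model.observed))

    def with_seed(self, seed: int) -> "FixtureConfig":
        return replace(self, seed=int(seed))


def generate(config: FixtureConfig, rng=None) -> ObservationSet:
    """Draw a dataset from a fixture config; deterministic given the seed."""
    model = config.build_model()
    model.validate([model.params[p] for p in model.free])
    if rng is None:
        rng = np.random.default_rng(config.seed)
    times = np.asarray(config.times, float)
    # truth mean, evaluated at the model's full parameter set
    theta_truth = np.array([model.params[p] for p in model.free])
    mu = model.mean(theta_truth, times)  # (L, S_obs)
    counts = config.counts_array()
    blocks = []
    for j, n in enumerate(counts):
        draw = mu[j] + config.sigma * rng.standard_normal((n, mu.shape[1]))
        if config.positive_only:
            for _ in range(1000):
                bad = draw <= 0
                if not bad.any():
                    break
                draw[bad] = mu[j] + config.sigma * rng.standard_normal(int(bad.sum()))
        blocks.append(draw)
    return ObservationSet(times, blocks, species=model.observed)


_T_GROWTH = (0.1, 0.25, 0.5)
_T_LOGISTIC = (2.74, 6.84, 10.95)
_CORAL = {"r": 0.9131, "C0": 0.7237, "K": 79.74}
_SIR_TRUTH = {"beta": 1.6633, "gamma": 0.44036, "S0": 762.0 / 763.0, "I0": 1.0 / 763.0, "R0": 0.0}


def builtin_fixtures() -> dict:
    """Named fixture configs for the package's reference designs."""
    fx = {
        "uninormal": FixtureConfig(
            "normal", {"mu": 0.7, "sigma": 0.5}, times=(0.0,), counts=10, sigma=0.5,
            free=("mu", "sigma"),
        ),
        "mvnormal": FixtureConfig(
            "mvnormal", {"mu1": 0.8, "mu2": 1.2, "sigma": 0.3}, times=(0.0,), counts=10,
            sigma=0.3, free=("mu1", "mu2"),
        ),
        "linear": FixtureConfig(
            "linear", {"a": 0.9131, "C0": 0.7237}, times=_T_GROWTH, counts=10, sigma=0.2301,
            free=("a", "C0"),
        ),
        "exponential": FixtureConfig(
            "exponential", {"a": 0.9131, "C0": 0.7237}, times=_T_GROWTH, counts=10,
            sigma=0.2301, free=("a", "C0"),
        ),
        "logistic": FixtureConfig(
            "logistic", _CORAL, times=_T_LOGISTIC, counts=10, sigma=2.301, free=("r", "C0"),
        ),
        "logistic-early-mid": FixtureConfig(
            "logistic", _CORAL, times=_T_LOGISTIC[:2], counts=15, sigma=2.301,
            free=("r", "C0"),
        ),
        "logistic-mid-late": FixtureConfig(
            "logistic", _CORAL, times=_T_LOGISTIC[1:], counts=15, sigma=2.301,
            free=("r", "C0"),
        ),
        "logistic-curved": FixtureConfig(
            "logistic", {"r": 0.9, "C0": 0.2, "K": 79.74}, times=_T_LOGISTIC, counts=10,
            sigma=2.301, free=("r", "C0"),
        ),
        "logistic-curved-n50": FixtureConfig(
            "logistic", {"r": 0.9, "C0": 0.2, "K": 79.74}, times=_T_LOGISTIC, counts=50,
            sigma=2.301, free=("r", "C0"),
        ),
        "sir-I": FixtureConfig(
            "sir", _SIR_TRUTH, times=(4.0, 7.0, 10.0), counts=10, sigma=0.05,
            observed=("I",), free=("beta", "gamma"),
        ),
        "sir-SIR": FixtureConfig(
            "sir", _SIR_TRUTH, times=(4.0, 7.0, 10.0), counts=3, sigma=0.03,
            observed=("S", "I", "R"), free=("beta", "gamma"),
        ),
    }
    fx["uninormal-n100"] = replace(fx["uninormal"], counts=100)
    fx["mvnormal-n100"] = replace(fx["mvnormal"], counts=100)
    return fx
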