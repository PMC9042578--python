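"""Likelihood-ratio and geodesic-distance hypothesis tests.

Both tests target H0: theta_t = theta_0 against H1: theta_t != theta_0.
The likelihood-ratio statistic is lambda_LR = -2 (l(theta_0) -
l(thetahat)); the geodesic-distance statistic is the squared Fisher-Rao
distance lambda_GD = d(theta_0, thetahat)^2 computed from the geodesic
boundary value problem. Both are asymptotically chi-square(nu) under
the null, giving approximate p-values via the chi-square survival
function.

The module also provides the Monte-Carlo coverage study: repeated
simulate / fit / test-at-truth cycles measuring how often the nominal
alpha-level criterion covers the true parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from . import geometry
from .inference import chi2_threshold, find_mle
from .observation_models import NoiseModel, log_likelihood
from .synthetic_data import FixtureConfig, generate

__all__ = [
    "TestResult",
    "CoverageResult",
    "lr_test",
    "gd_test",
    "lr_statistic_normal",
    "lr_statistic_mvn_means",
    "coverage_study",
]


@dataclass(frozen=True)
class TestResult:
    method: str  # "likelihood-ratio" | "geodesic-distance"
    statistic: float
    nu: int
    p_value: float
    null_point: np.ndarray
    mle: np.ndarray

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def _p_value(stat: float, nu: int) -> float:
    return float(chi2.sf(stat, df=nu))


def lr_test(model, data, noise: NoiseModel, theta0, mle=None, **mle_kwargs) -> TestResult:
    """Likelihood-ratio test of theta_0, lambda_LR = -2(l(theta0) - l(thetahat))."""
    theta0 = np.atleast_1d(np.asarray(theta0, float))
    model.validate(theta0)
    if mle is None:
        mle = find_mle(model, data, noise, **mle_kwargs)
    stat = -2.0 * (log_likelihood(model, theta0, data, noise) - mle.log_likelihood)
    stat = max(stat, 0.0) if stat > -1e-6 else stat
    nu = theta0.size
    return TestResult(
        method="likelihood-ratio",
        statistic=float(stat),
        nu=nu,
        p_value=_p_value(stat, nu),
        null_point=theta0,
        mle=np.asarray(mle.values, float),
    )


def gd_test(
    metric,
    theta0,
    mle,
    closed_form_normal: int | None = None,
    **bvp_kwargs,
) -> TestResult:
    """Geodesic-distance test, lambda_GD = d(theta0, thetahat)^2.

    By default the distance comes from the geodesic boundary value
    problem on ``metric``. On the univariate-normal manifold the
    closed-form Fisher-Rao distance may be routed instead by passing
    the observation count as ``closed_form_normal`` (a speed path; the
    BVP remains the default to exercise the general machinery).
    """
    theta0 = np.atleast_1d(np.asarray(theta0, float))
    mle_vals = np.asarray(mle.values if hasattr(mle, "values") else mle, float)
    if closed_form_normal is not None:
        d = geometry.fisher_rao_normal_distance(mle_vals, theta0, n_obs=closed_form_normal)
    else:
        d = geometry.geodesic_bvp(metric, theta0, mle_vals, **bvp_kwargs).length
    stat = d * d
    nu = theta0.size
    return TestResult(
        method="geodesic-distance",
        statistic=float(stat),
        nu=nu,
        p_value=_p_value(stat, nu),
        null_point=theta0,
        mle=mle_vals,
    )


# -- sufficiency identities (closed-form statistics) -----------------------

def lr_statistic_normal(mle, theta0, n_obs: int) -> float:
    """lambda_LR for N(mu, sigma^2) with both coordinates inferred.

    With MLE (muhat, sighat) = (sample mean, biased sample SD),
    lambda = 2N [ log(sig0/sighat) + (sighat^2 + (muhat - mu0)^2)
                  / (2 sig0^2) - 1/2 ].
    """
    (mh, sh), (m0, s0) = mle, theta0
    if not (sh > 0 and s0 > 0):
        raise ValueError("standard deviations must be positive")
    return float(2.0 * n_obs * (np.log(s0 / sh) + (sh**2 + (mh - m0) ** 2) / (2.0 * s0**2) - 0.5))


def lr_statistic_mvn_means(mle, theta0, sigma: float, n_obs: int) -> float:
    """lambda_LR for MVN means with known sigma: (N/sigma^2) ||thetahat - theta0||^2."""
    d = np.asarray(mle, float) - np.asarray(theta0, float)
    return float(n_obs / sigma**2 * d @ d)


@dataclass
class CoverageResult:
    coverage: float  # fraction of replicates with lambda <= Delta_{nu,alpha}
    statistics: np.ndarray
    method: str
    alpha: float
    n_used: int
    n_excluded: int


def coverage_study(
    config: FixtureConfig,
    n_datasets: int = 1000,
    method: str = "lr",
    alpha: float = 0.95,
    base_seed: int = 0,
    fast: bool = True,
    **fit_kwargs,
) -> CoverageResult:
    """Monte-Carlo coverage of the nominal alpha-level criterion.

    For each replicate: simulate a dataset at the fixture's truth, fit
    the MLE, compute the test statistic at the truth, and record it.
    Coverage is the fraction of statistics at or below Delta_{nu,alpha}.
    Replicates use a counter-based seed stream (base_seed, index) so any
    single one is reproducible in isolation.

    For the plain normal and multivariate-normal-means designs the MLE
    and statistics have closed forms (sample mean / biased SD and the
    sufficiency identities); ``fast=True`` routes through them. The
    generic path (simulate -> find_mle -> test) is used otherwise.
    """
    if method not in ("lr", "gd"):
        raise ValueError("method must be 'lr' or 'gd'")
    model = config.build_model()
    truth = np.array([model.params[p] for p in model.free])
    nu = model.nu
    crit = chi2_threshold(alpha, nu)

    stats = []
    excluded = 0
    fast_normal = fast and config.model == "normal" and tuple(model.free) == ("mu", "sigma")
    fast_mvn = fast and config.model == "mvnormal" and tuple(model.free) == ("mu1", "mu2")
    counts = config.counts_array()
    for i in range(n_datasets):
        rng = np.random.default_rng((base_seed, i))
        try:
            if fast_normal:
                n = int(counts.sum())
                x = truth[0] + config.sigma * rng.standard_normal(n)
                mh, sh = float(x.mean()), float(x.std())  # biased sample SD
                if method == "lr":
                    lam = lr_statistic_normal((mh, sh), truth, n)
                else:
                    lam = geometry.fisher_rao_normal_distance((mh, sh), truth, n_obs=n) ** 2
            elif fast_mvn:
                n = int(counts.sum())
                x = truth[:2] + config.sigma * rng.standard_normal((n, 2))
                mhat = x.mean(axis=0)
                # flat manifold: lambda_GD == lambda_LR identically
                lam = lr_statistic_mvn_means(mhat, truth, config.sigma, n)
            else:
                data = generate(config, rng=rng)
                noise = NoiseModel(
                    sigma=None if model.sigma_inferred else config.sigma,
                    sigma_known=not model.sigma_inferred,
                )
                mle = find_mle(model, data, noise, **fit_kwargs)
                if method == "lr":
                    lam = lr_test(model, data, noise, truth, mle=mle).statistic
                else:
                    metric = geometry.fisher_metric_field(
                        model, np.asarray(config.times), counts, noise
                    )
                    lam = gd_test(metric, truth, mle).statistic
            stats.append(lam)
        except Exception:
            excluded += 1
    if excluded > 0.01 * n_datasets:
        raise RuntimeError(
            f"{excluded}/{n_datasets} coverage replicates failed (> 1% exclusions)"
        )
    stats = np.asarray(stats)
    return CoverageResult(
        coverage=float(np.mean(stats <= crit)),
        statistics=stats,
        method=method,
        alpha=alpha,
        n_used=stats.size,
        n_excluded=excluded,
    )
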