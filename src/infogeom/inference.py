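"""Maximum-likelihood estimation, likelihood surfaces and confidence regions.

An approximate alpha-level confidence region for theta is the sublevel
set of the normalized log-likelihood lhat(theta) = l(theta) - l(thetahat)
above -Delta_{nu,alpha}/2, where Delta_{nu,alpha} is the alpha-quantile
of chi-square(nu) (Wilks). The boundary of that region is traced as a
level curve of lhat with a Heun predictor and per-step 1-D root
projection back onto the level set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize
from scipy.stats import chi2, qmc

from .observation_models import NoiseModel, ObservationSet, ParameterPoint, log_likelihood

__all__ = [
    "MLEResult",
    "LikelihoodSurface",
    "ConfidenceRegion",
    "MLEConvergenceError",
    "RegionUndefinedError",
    "find_mle",
    "chi2_threshold",
    "evaluate_surface",
    "trace_confidence_boundary",
]


class MLEConvergenceError(RuntimeError):
    """Optimizer failed to converge; carries the best point found."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class RegionUndefinedError(RuntimeError):
    """No level-set crossing exists within the searched box.

    The normalized log-likelihood never reaches the confidence
    threshold along any search ray: the region at this level is
    undefined within the box — a symptom of practical
    non-identifiability.
    """


@dataclass
class MLEResult:
    theta: ParameterPoint
    log_likelihood: float
    converged: bool = True

    @property
    def values(self) -> np.ndarray:
        return self.theta.theta


def find_mle(
    model,
    data: ObservationSet,
    noise: NoiseModel,
    start=None,
    bounds=None,
    n_restarts: int = 20,
    seed: int = 0,
    maxiter: int = 2000,
) -> MLEResult:
    """Maximize the log-likelihood over the model's free coordinates.

    Bound-constrained derivative-free maximization (Powell), restarted
    from Latin-hypercube starts as a multimodality guard; ties broken by
    best objective then lexicographic theta. Convergence tolerances:
    objective change < 1e-10, parameter change < 1e-8.
    """
    nu = model.nu
    if bounds is None:
        bounds = model.free_bounds()
    # finite search box for starts: clip infinite bounds around defaults
    defaults = np.array([model.params[p] for p in model.free])
    lo = np.array([b[0] for b in bounds], float)
    hi = np.array([b[1] for b in bounds], float)
    lo_f = np.where(np.isfinite(lo), lo, defaults - 5.0 * np.maximum(np.abs(defaults), 1.0))
    hi_f = np.where(np.isfinite(hi), hi, defaults + 5.0 * np.maximum(np.abs(defaults), 1.0))

    def objective(theta):
        try:
            return -log_likelihood(model, theta, data, noise)
        except (ValueError, FloatingPointError):
            return 1e12

    starts = []
    if start is not None:
        s0 = np.atleast_1d(np.asarray(start, float))
        if np.any(s0 < lo) or np.any(s0 > hi):
            raise ValueError(f"start {s0.tolist()} outside bounds")
        starts.append(s0)
    if n_restarts > 0:
        sampler = qmc.LatinHypercube(d=nu, seed=seed)
        pts = qmc.scale(sampler.random(n_restarts), lo_f, hi_f)
        starts.extend(pts)
    if not starts:
        starts.append(np.clip(defaults, lo_f, hi_f))

    best = None
    any_ok = False
    for s in starts:
        res = minimize(
            objective,
            s,
            method="Powell",
            bounds=list(zip(lo, hi)),
            options={"xtol": 1e-8, "ftol": 1e-10, "maxiter": maxiter},
        )
        any_ok = any_ok or res.success
        key = (res.fun, tuple(res.x))
        if best is None or key < best[0]:
            best = (key, res)
    res = best[1]
    result = MLEResult(
        theta=ParameterPoint(res.x, labels=tuple(model.free)),
        log_likelihood=-float(res.fun),
        converged=bool(res.success),
    )
    if not any_ok:
        raise MLEConvergenceError(
            f"optimizer failed to converge after {len(starts)} starts", best=result
        )
    if start is not None and result.log_likelihood < -objective(starts[0]) - 1e-9:
        raise MLEConvergenceError("optimizer returned a value below the start", best=result)
    return result


def chi2_threshold(alpha: float, nu: int) -> float:
    """Delta_{nu,alpha}: the alpha-quantile of chi-square(nu)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if nu < 1:
        raise ValueError(f"degrees of freedom must be >= 1, got {nu}")
    return float(chi2.ppf(alpha, df=nu))


@dataclass
class LikelihoodSurface:
    """Normalized log-likelihood on a rectangular lattice (two coordinates)."""

    axis1: np.ndarray
    axis2: np.ndarray
    values: np.ndarray  # (res1, res2), lhat; NaN where evaluation failed
    mle: ParameterPoint
    mle_value: float  # l(thetahat), unnormalized
    labels: tuple = ()


def evaluate_surface(
    model,
    data: ObservationSet,
    noise: NoiseModel,
    box,
    resolution: int = 100,
    mle: MLEResult | None = None,
    **mle_kwargs,
) -> LikelihoodSurface:
    """Normalized log-likelihood lhat on a uniform lattice over a 2-D box."""
    if model.nu != 2:
        raise ValueError("surfaces are defined over exactly two free coordinates")
    if mle is None:
        mle = find_mle(model, data, noise, **mle_kwargs)
    (lo1, hi1), (lo2, hi2) = box
    ax1 = np.linspace(lo1, hi1, resolution)
    ax2 = np.linspace(lo2, hi2, resolution)
    vals = np.full((resolution, resolution), np.nan)
    for i, a in enumerate(ax1):
        for j, b in enumerate(ax2):
            try:
                vals[i, j] = log_likelihood(model, np.array([a, b]), data, noise)
            except (ValueError, FloatingPointError):
                pass
    vals -= mle.log_likelihood
    return LikelihoodSurface(
        ax1, ax2, vals, mle.theta, mle.log_likelihood, labels=tuple(model.free)
    )


@dataclass
class ConfidenceRegion:
    """A traced likelihood-based confidence-region boundary."""

    level: float
    threshold: float  # lhat on the boundary: -Delta_{nu,alpha}/2
    boundary: np.ndarray  # (k, 2) ordered polyline
    closed: bool  # False flags practical non-identifiability in the box


def trace_confidence_boundary(
    model,
    data: ObservationSet,
    noise: NoiseModel,
    box,
    level: float = 0.95,
    mle: MLEResult | None = None,
    step: float | None = None,
    n_rays: int = 36,
    max_steps: int | None = None,
    **mle_kwargs,
) -> ConfidenceRegion:
    """Trace the level set lhat = -Delta_{nu,alpha}/2 inside a box.

    A seed point is bracketed by 1-D root finding along rays from the
    MLE; the contour is then followed along the normalized tangent
    (perpendicular to grad lhat) with a two-stage second-order
    Runge-Kutta (Heun) stepper, re-projected onto the level set each
    step by 1-D root refinement along the gradient. The trace runs
    counter-clockwise with step 1/400 of the box diagonal and closes
    when it returns within two step lengths of its start; exiting the
    box sets ``closed=False``.

    Raises
    ------
    RegionUndefinedError
        If no ray from the MLE crosses the threshold within the box.
    """
    if model.nu != 2:
        raise ValueError("contour tracing is implemented for two free coordinates")
    if mle is None:
        mle = find_mle(model, data, noise, **mle_kwargs)
    center = mle.values
    l_hat_max = mle.log_likelihood
    thr = -0.5 * chi2_threshold(level, 2)

    def f(theta):
        try:
            return log_likelihood(model, theta, data, noise) - l_hat_max - thr
        except (ValueError, FloatingPointError):
            return np.nan

    (lo1, hi1), (lo2, hi2) = box
    lo = np.array([lo1, lo2])
    hi = np.array([hi1, hi2])
    diag = float(np.linalg.norm(hi - lo))
    h = step if step is not None else diag / 400.0

    # --- seed search: bracket f = 0 along rays from the MLE -------------
    seed_pt = None
    for ang in 2.0 * np.pi * np.arange(n_rays) / n_rays:
        u = np.array([np.cos(ang), np.sin(ang)])
        # distance to box edge along u
        with np.errstate(divide="ignore"):
            t_edge = np.min(
                [t for t in np.concatenate([(hi - center) / u, (lo - center) / u]) if t > 0]
            )
        ts = np.linspace(1e-9, t_edge * (1 - 1e-9), 64)
        vals = np.array([f(center + t * u) for t in ts])
        ok = np.isfinite(vals)
        sign_change = np.where(ok[:-1] & ok[1:] & (vals[:-1] * vals[1:] < 0))[0]
        if sign_change.size:
            k = sign_change[0]
            t_root = brentq(lambda t: f(center + t * u), ts[k], ts[k + 1], xtol=1e-13)
            seed_pt = center + t_root * u
            break
    if seed_pt is None:
        raise RegionUndefinedError(
            f"the normalized log-likelihood never reaches the {level:.0%} threshold "
            f"along any of {n_rays} rays within the box: the region is undefined here "
            "(practical non-identifiability)"
        )

    # --- tracing ---------------------------------------------------------
    gstep = 1e-7 * np.maximum(np.abs(hi - lo), 1e-12)

    def grad(theta):
        g = np.empty(2)
        for i in range(2):
            e = np.zeros(2)
            e[i] = gstep[i]
            g[i] = (f(theta + e) - f(theta - e)) / (2.0 * gstep[i])
        return g

    def tangent(theta, prev=None):
        g = grad(theta)
        ng = np.linalg.norm(g)
        if not np.isfinite(ng) or ng == 0:
            raise RuntimeError("vanishing gradient on the level set")
        t = np.array([-g[1], g[0]]) / ng
        if prev is None:
            # counter-clockwise orientation about the MLE for the first step
            rel = theta - center
            if rel[0] * t[1] - rel[1] * t[0] < 0:
                t = -t
        elif t @ prev < 0:
            # keep continuity with the previous tangent (thin or hairpin
            # contours would otherwise flip direction)
            t = -t
        return t

    def project(theta):
        # Newton along the gradient direction, with a bracketed root as
        # the polishing step
        for _ in range(20):
            val = f(theta)
            if not np.isfinite(val):
                return theta
            if abs(val) < 1e-10:
                return theta
            g = grad(theta)
            ng2 = float(g @ g)
            if ng2 == 0 or not np.isfinite(ng2):
                return theta
            delta = -val / ng2 * g
            # keep the correction from jumping across a thin contour
            nd = np.linalg.norm(delta)
            if nd > h:
                delta *= h / nd
            theta = theta + delta
        u = grad(theta)
        u = u / np.linalg.norm(u)
        a, b = -h, h
        fa, fb = f(theta + a * u), f(theta + b * u)
        if np.isfinite(fa) and np.isfinite(fb) and fa * fb < 0:
            t_root = brentq(lambda t: f(theta + t * u), a, b, xtol=1e-13)
            return theta + t_root * u
        return theta

    if max_steps is None:
        max_steps = 4000
    pts = [project(seed_pt)]
    closed = False
    t_prev = None
    for k in range(max_steps):
        p = pts[-1]
        t1 = tangent(p, t_prev)
        p_pred = p + h * t1  # Heun: two-stage second-order step
        if np.any(p_pred < lo) or np.any(p_pred > hi):
            break
        try:
            t2 = tangent(p_pred, t1)
        except RuntimeError:
            break
        t_prev = t1
        p_new = project(p + 0.5 * h * (t1 + t2))
        if np.any(p_new < lo) or np.any(p_new > hi):
            break
        pts.append(p_new)
        # closure: back within two step lengths of the start *and* moving in
        # the starting direction (guards against meeting the opposite side
        # of a contour thinner than the step length)
        if k > 4 and np.linalg.norm(p_new - pts[0]) < 2.0 * h:
            if tangent(p_new, t_prev) @ tangent(pts[0]) > 0:
                closed = True
                pts.append(pts[0])
                break
    return ConfidenceRegion(level=level, threshold=thr, boundary=np.array(pts), closed=closed)
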