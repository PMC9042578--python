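"""The model zoo: mean functions mu(theta, t) and parameter Jacobians.

Each :class:`ProcessModel` maps a full parameter set to expected
observables at requested times, together with the Jacobian of the mean
with respect to the *inferred* coordinates. Analytic partials are used
where available (linear, exponential, logistic, constant-mean normal
models); the SIR model falls back to central finite differences around
repeated ODE solves.

Time is treated as unitless; the registry documents the conventional
units per model (years for the growth models, days for SIR).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "ProcessModel",
    "get_model",
    "numeric_jacobian",
    "sir_solve",
    "MODEL_REGISTRY",
    "IntegrationError",
]


class IntegrationError(RuntimeError):
    """Raised when the ODE integrator fails, with solver diagnostics."""


@dataclass(frozen=True)
class ProcessModel:
    """A process model with a chosen set of inferred coordinates.

    Attributes
    ----------
    name
        Registry identifier.
    params
        The full parameter set Theta as label -> value, including
        ``sigma``; entries not in ``free`` stay fixed at these values.
    free
        Labels of the inferred coordinates theta, ordered; if ``sigma``
        is inferred it is by convention the last label.
    bounds
        Admissible interval per coordinate label.
    species
        All model outputs.
    observed
        The subset of outputs that are observed.
    """

    name: str
    params: dict
    free: tuple
    bounds: dict
    species: tuple = ("C",)
    observed: tuple | None = None
    _mean: Callable = None
    _partials: dict | None = None

    def __post_init__(self):
        object.__setattr__(self, "free", tuple(self.free))
        obs = self.observed if self.observed is not None else self.species
        object.__setattr__(self, "observed", tuple(obs))
        unknown = [p for p in self.free if p not in self.params]
        if unknown:
            raise ValueError(f"free labels {unknown} not in parameter set {list(self.params)}")
        if "sigma" in self.free and self.free[-1] != "sigma":
            raise ValueError("when sigma is inferred it must be the last coordinate")
        bad = [s for s in self.observed if s not in self.species]
        if bad:
            raise ValueError(f"observed species {bad} not among model outputs {self.species}")

    # -- coordinate bookkeeping ------------------------------------------
    @property
    def nu(self) -> int:
        """Number of inferred coordinates, nu = dim(theta)."""
        return len(self.free)

    @property
    def sigma_inferred(self) -> bool:
        return "sigma" in self.free

    @property
    def model_free(self) -> tuple:
        """Inferred coordinates that the mean actually depends on."""
        return tuple(p for p in self.free if p != "sigma")

    def full_params(self, theta) -> dict:
        theta = np.atleast_1d(np.asarray(theta, float))
        if theta.size != self.nu:
            raise ValueError(f"theta has {theta.size} coordinates, expected {self.nu}")
        full = dict(self.params)
        full.update(dict(zip(self.free, theta)))
        return full

    def free_bounds(self) -> list:
        return [self.bounds[p] for p in self.free]

    def validate(self, theta) -> None:
        for label, value in zip(self.free, np.atleast_1d(theta)):
            lo, hi = self.bounds[label]
            if not (lo <= value <= hi):
                raise ValueError(f"{label}={value} outside bounds ({lo}, {hi})")

    def with_free(self, free, **fixed) -> "ProcessModel":
        """A copy with a different inferred-coordinate selection."""
        params = dict(self.params)
        params.update(fixed)
        return replace(self, free=tuple(free), params=params)

    def with_observed(self, observed) -> "ProcessModel":
        return replace(self, observed=tuple(observed))

    # -- evaluation -------------------------------------------------------
    def mean(self, theta, times) -> np.ndarray:
        """Expected observables, shape ``(len(times), len(observed))``.

        ``theta`` is the free coordinate vector (a trailing sigma, if
        inferred, is carried but does not affect the mean).
        """
        times = np.atleast_1d(np.asarray(times, float))
        full = self.full_params(theta)
        out = np.asarray(self._mean(full, times), float)
        if out.ndim == 1:
            out = out[:, None]
        cols = [self.species.index(s) for s in self.observed]
        return out[:, cols]

    def jacobian(self, theta, times) -> np.ndarray:
        """d mu / d theta for the model coordinates (sigma column excluded).

        Rows are time-major over (time x observed species); one column
        per entry of :attr:`model_free`. Analytic partials where the
        registry provides them, else central finite differences.
        """
        times = np.atleast_1d(np.asarray(times, float))
        labels = self.model_free
        if self._partials is not None and all(p in self._partials for p in labels):
            full = self.full_params(theta)
            cols = []
            for p in labels:
                part = np.asarray(self._partials[p](full, times), float)
                if part.ndim == 1:
                    part = part[:, None]
                sel = [self.species.index(s) for s in self.observed]
                cols.append(part[:, sel].ravel())
            return np.column_stack(cols) if cols else np.zeros((times.size * len(self.observed), 0))
        return numeric_jacobian(self, theta, times)


def numeric_jacobian(model: ProcessModel, theta, times, rel_step: float = 1e-6) -> np.ndarray:
    """Central finite-difference Jacobian of the model mean.

    The step is relative, ``h_i = rel_step * max(|theta_i|, 1)``. If a
    stencil point leaves the declared bounds the scheme shrinks to a
    one-sided difference and warns.
    """
    theta = np.atleast_1d(np.asarray(theta, float))
    times = np.atleast_1d(np.asarray(times, float))
    labels = model.model_free
    free_idx = [model.free.index(p) for p in labels]
    n_rows = times.size * len(model.observed)
    J = np.zeros((n_rows, len(labels)))
    for col, i in enumerate(free_idx):
        h = rel_step * max(abs(theta[i]), 1.0)
        lo, hi = model.bounds[model.free[i]]
        up, dn = theta.copy(), theta.copy()
        up[i] += h
        dn[i] -= h
        if up[i] > hi or dn[i] < lo:
            warnings.warn(
                f"finite-difference stencil for {model.free[i]} clipped by bounds; "
                "falling back to a one-sided difference"
            )
            if up[i] > hi:
                up = theta
            else:
                dn = theta
        span = up[i] - dn[i]
        J[:, col] = (model.mean(up, times) - model.mean(dn, times)).ravel() / span
    return J


# ---------------------------------------------------------------------------
# mean functions and analytic partials
# ---------------------------------------------------------------------------

def _linear_mean(p, t):
    return p["a"] * t + p["C0"]


def _exponential_mean(p, t):
    return p["C0"] * np.exp(p["a"] * t)


def _logistic_mean(p, t):
    C0, K, r = p["C0"], p["K"], p["r"]
    if not (C0 > 0 and K > 0):
        raise ValueError(f"logistic model requires C0 > 0 and K > 0, got C0={C0}, K={K}")
    return C0 * K / (C0 + (K - C0) * np.exp(-r * t))


def _logistic_partials():
    def d_r(p, t):
        C0, K, r = p["C0"], p["K"], p["r"]
        e = np.exp(-r * t)
        return C0 * K * t * (K - C0) * e / (C0 + (K - C0) * e) ** 2

    def d_C0(p, t):
        C0, K, r = p["C0"], p["K"], p["r"]
        e = np.exp(r * t)
        return K**2 * e / (C0 * (e - 1.0) + K) ** 2

    def d_K(p, t):
        C0, K, r = p["C0"], p["K"], p["r"]
        e = np.exp(r * t)
        return C0**2 * e * (e - 1.0) / (C0 * (e - 1.0) + K) ** 2

    return {"r": d_r, "C0": d_C0, "K": d_K}


def sir_solve(beta, gamma, s0, i0, r0, times, rtol: float = 1e-8, atol: float = 1e-10) -> np.ndarray:
    """Solve the SIR proportions model at the requested times.

    dS/dt = -beta S I, dI/dt = beta S I - gamma I, dR/dt = gamma I, with
    S + I + R = 1. Integrated with an adaptive 5(4) Runge-Kutta pair;
    conservation is monitored, not imposed, and drift beyond 1e-6 warns.
    """
    if beta < 0 or gamma < 0:
        raise ValueError("beta and gamma must be non-negative")
    y0 = np.array([s0, i0, r0], float)
    if np.any(y0 < -1e-12) or abs(y0.sum() - 1.0) > 1e-8:
        raise ValueError("initial proportions must be in [0,1] and sum to 1")
    times = np.atleast_1d(np.asarray(times, float))

    def rhs(_, y):
        s, i, _r = y
        inf = beta * s * i
        rec = gamma * i
        return [-inf, inf - rec, rec]

    t_span = (0.0, float(times.max())) if times.max() > 0 else (0.0, 1e-12)
    sol = solve_ivp(rhs, t_span, y0, t_eval=times, method="RK45", rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(f"SIR integration failed: {sol.message}")
    y = sol.y.T  # (L, 3)
    drift = np.max(np.abs(y.sum(axis=1) - 1.0))
    if drift > 1e-6:
        warnings.warn(f"S+I+R conservation drift {drift:.2e} exceeds 1e-6")
    return y


def _sir_mean(p, t):
    return sir_solve(p["beta"], p["gamma"], p["S0"], p["I0"], p["R0"], t)


def _normal_mean(p, t):
    return np.full((np.atleast_1d(t).size, 1), p["mu"])


def _mvnormal_mean(p, t):
    L = np.atleast_1d(t).size
    return np.column_stack([np.full(L, p["mu1"]), np.full(L, p["mu2"])])


_POS = (1e-8, np.inf)
_REAL = (-np.inf, np.inf)

MODEL_REGISTRY: dict[str, dict] = {
    "linear": dict(
        params={"a": 0.9131, "C0": 0.7237, "sigma": 0.2301},
        mean=_linear_mean,
        partials={"a": lambda p, t: t, "C0": lambda p, t: np.ones_like(t)},
        bounds={"a": _REAL, "C0": _REAL, "sigma": _POS},
        species=("C",),
    ),
    "exponential": dict(
        params={"a": 0.9131, "C0": 0.7237, "sigma": 0.2301},
        mean=_exponential_mean,
        partials={
            "a": lambda p, t: p["C0"] * t * np.exp(p["a"] * t),
            "C0": lambda p, t: np.exp(p["a"] * t),
        },
        bounds={"a": _REAL, "C0": _REAL, "sigma": _POS},
        species=("C",),
    ),
    "logistic": dict(
        params={"r": 0.9131, "C0": 0.7237, "K": 79.74, "sigma": 2.301},
        mean=_logistic_mean,
        partials=_logistic_partials(),
        bounds={"r": _POS, "C0": _POS, "K": _POS, "sigma": _POS},
        species=("C",),
    ),
    "sir": dict(
        params={
            "beta": 1.6633,
            "gamma": 0.44036,
            "S0": 762.0 / 763.0,
            "I0": 1.0 / 763.0,
            "R0": 0.0,
            "sigma": 0.05,
        },
        mean=_sir_mean,
        partials=None,  # sensitivities via repeated ODE solves
        bounds={
            "beta": (0.0, np.inf),
            "gamma": (0.0, np.inf),
            "S0": (0.0, 1.0),
            "I0": (0.0, 1.0),
            "R0": (0.0, 1.0),
            "sigma": _POS,
        },
        species=("S", "I", "R"),
        observed=("I",),
    ),
    "normal": dict(
        params={"mu": 0.7, "sigma": 0.5},
        mean=_normal_mean,
        partials={"mu": lambda p, t: np.ones_like(np.atleast_1d(t))},
        bounds={"mu": _REAL, "sigma": _POS},
        species=("x",),
    ),
    "mvnormal": dict(
        params={"mu1": 0.8, "mu2": 1.2, "sigma": 0.3},
        mean=_mvnormal_mean,
        partials={
            "mu1": lambda p, t: np.column_stack(
                [np.ones(np.atleast_1d(t).size), np.zeros(np.atleast_1d(t).size)]
            ),
            "mu2": lambda p, t: np.column_stack(
                [np.zeros(np.atleast_1d(t).size), np.ones(np.atleast_1d(t).size)]
            ),
        },
        bounds={"mu1": _REAL, "mu2": _REAL, "sigma": _POS},
        species=("x", "y"),
    ),
}


def get_model(name: str, free=None, fixed: dict | None = None, observed=None) -> ProcessModel:
    """Build a model from the registry.

    Parameters
    ----------
    name
        One of ``linear``, ``exponential``, ``logistic``, ``sir``,
        ``normal``, ``mvnormal``.
    free
        The inferred coordinate labels (sigma last if inferred). When
        omitted, all non-sigma parameters are free.
    fixed
        Overrides for fixed parameter values.
    observed
        Observed species subset (defaults per registry entry).
    """
    if name not in MODEL_REGISTRY:
        raise KeyError(f"unknown model {name!r}; choose from {sorted(MODEL_REGISTRY)}")
    entry = MODEL_REGISTRY[name]
    params = dict(entry["params"])
    if fixed:
        params.update(fixed)
    if free is None:
        free = tuple(p for p in params if p != "sigma")
    return ProcessModel(
        name=name,
        params=params,
        free=tuple(free),
        bounds=dict(entry["bounds"]),
        species=entry["species"],
        observed=tuple(observed) if observed is not None else entry.get("observed"),
        _mean=entry["mean"],
        _partials=entry["partials"],
    )
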