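"""Normal observation processes.

Observations are modelled as independent draws about the expected model
behaviour with constant standard deviation sigma:

    x_ij ~ Normal(mu(theta, t_j), sigma^2),

independently over replicates i, time points t_j and (for multi-output
models) observed species. The log-likelihood, the Fisher information of
the observation process, and the normal-normal Kullback-Leibler
divergence live here; everything model-specific is delegated to
:mod:`infogeom.process_models`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "NoiseModel",
    "ParameterPoint",
    "ObservationSet",
    "log_likelihood",
    "observation_fisher",
    "kl_divergence_normal",
    "resolve_sigma",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class NoiseModel:
    """Constant additive normal noise.

    Parameters
    ----------
    sigma
        Standard deviation of the observation noise, in model output
        units. May be ``None`` when ``sigma_known`` is ``False`` (sigma
        is then read from the last coordinate of the inferred parameter
        vector).
    sigma_known
        If ``True`` sigma is fixed; otherwise sigma is an inferred
        coordinate and is, by project convention, the *last* entry of
        the free parameter vector.
    """

    sigma: float | None = None
    sigma_known: bool = True

    def __post_init__(self) -> None:
        if self.sigma_known:
            if self.sigma is None or not self.sigma > 0:
                raise ValueError(f"sigma must be positive, got {self.sigma}")


@dataclass(frozen=True)
class ParameterPoint:
    """An ordered point in parameter space with coordinate labels."""

    theta: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "theta", np.atleast_1d(np.asarray(self.theta, float)))
        if self.theta.ndim != 1 or self.theta.size < 1:
            raise ValueError("theta must be a non-empty 1-D coordinate vector")
        if self.labels and len(self.labels) != self.theta.size:
            raise ValueError("labels length must match theta length")

    @property
    def nu(self) -> int:
        return self.theta.size


def resolve_sigma(noise: NoiseModel, theta: np.ndarray) -> float:
    """Return the operative sigma: fixed, or the last free coordinate."""
    sigma = noise.sigma if noise.sigma_known else float(np.asarray(theta, float)[-1])
    if not sigma > 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    return float(sigma)


class ObservationSet:
    """Replicated observations indexed by time point and species.

    Internally a ragged structure: one ``(counts[j], n_species)`` array
    per time point, supporting unequal replicate counts N_j.
    """

    def __init__(
        self,
        times,
        values,
        species: tuple[str, ...] = ("x",),
    ) -> None:
        self.times = np.asarray(times, float)
        if self.times.ndim != 1 or np.unique(self.times).size != self.times.size:
            raise ValueError("times must be 1-D with every time appearing once")
        self.species = tuple(species)
        self.values = []
        for j, block in enumerate(values):
            arr = np.asarray(block, float)
            if arr.ndim == 1:
                arr = arr[:, None]
            if arr.shape[1] != len(self.species):
                raise ValueError(
                    f"block {j} has {arr.shape[1]} species columns, expected {len(self.species)}"
                )
            if arr.shape[0] < 1:
                raise ValueError(f"time point {j} must have at least one replicate")
            self.values.append(arr)
        if len(self.values) != self.times.size:
            raise ValueError("one value block required per time point")

    @property
    def counts(self) -> np.ndarray:
        """Replicates per time point, N_j."""
        return np.array([v.shape[0] for v in self.values])

    @property
    def n_total(self) -> int:
        """Total observation count: sum_j N_j x n_species."""
        return int(self.counts.sum() * len(self.species))

    # -- tidy-frame / CSV round trip -------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t, block in zip(self.times, self.values):
            for i, row in enumerate(block):
                for s, val in zip(self.species, row):
                    rows.append((t, s, i, val))
        return pd.DataFrame(rows, columns=["time", "species", "replicate", "value"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ObservationSet":
        required = {"time", "species", "replicate", "value"}
        if not required.issubset(frame.columns):
            raise ValueError(f"frame must have columns {sorted(required)}")
        species = tuple(pd.unique(frame["species"]))
        times = np.array(sorted(pd.unique(frame["time"])))
        blocks = []
        for t in times:
            sub = frame[frame["time"] == t]
            piv = sub.pivot(index="replicate", columns="species", values="value")
            blocks.append(piv[list(species)].to_numpy())
        return cls(times, blocks, species)

    @classmethod
    def from_csv(cls, path) -> "ObservationSet":
        return cls.from_frame(pd.read_csv(path))

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ObservationSet(L={self.times.size}, species={self.species}, "
            f"counts={self.counts.tolist()})"
        )


def log_likelihood(model, theta, data: ObservationSet, noise: NoiseModel) -> float:
    """Log-likelihood of replicated normal observations about the model mean.

    Sums the normal log-density over every replicate, time point and
    observed species, all sharing the constant standard deviation. For
    multi-species data the species are independent coordinates.
    """
    theta = theta.theta if isinstance(theta, ParameterPoint) else np.asarray(theta, float)
    sigma = resolve_sigma(noise, theta)
    mu = model.mean(theta, data.times)  # (L, n_obs_species)
    if mu.shape != (data.times.size, len(data.species)):
        raise ValueError(
            f"model mean shape {mu.shape} does not match data layout "
            f"({data.times.size} times x {len(data.species)} species)"
        )
    ll = 0.0
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    log_norm = -0.5 * _LOG_2PI - np.log(sigma)
    for j, block in enumerate(data.values):
        resid = block - mu[j]
        ll += block.size * log_norm - inv2s2 * float(np.sum(resid * resid))
    return float(ll)


def observation_fisher(
    counts,
    sigma: float,
    n_species: int = 1,
    sigma_inferred: bool = False,
    collapsed: bool = True,
) -> np.ndarray:
    """Fisher information matrix of the observation process.

    For N normal observations of one (mean, sigma) pair the information
    is (N/sigma^2) diag(1, 2). With L time points (and S species) the
    full form is block diagonal over the per-observable blocks. When
    sigma is constant and inferred, the collapsed diagonal form

        diag(N_1/s^2, ..., N_{LS}/s^2, 2 sum(N)/s^2)

    pools all observations into a single sigma row; when sigma is fixed
    only the mean rows remain.
    """
    counts = np.atleast_1d(np.asarray(counts, float))
    if np.any(counts < 1):
        raise ValueError("all replicate counts must be >= 1")
    if not sigma > 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    # one weight per (time, species) mean row, time-major
    w = np.repeat(counts, n_species) / sigma**2
    if not sigma_inferred:
        return np.diag(w)
    if collapsed:
        return np.diag(np.append(w, 2.0 * w.sum()))
    blocks = [np.diag([wj, 2.0 * wj]) for wj in w]
    out = np.zeros((2 * w.size, 2 * w.size))
    for j, b in enumerate(blocks):
        out[2 * j : 2 * j + 2, 2 * j : 2 * j + 2] = b
    return out


def kl_divergence_normal(p, q) -> float:
    """KL divergence D(P || Q) between two univariate normals.

    Each argument is a ``(mean, sigma)`` pair. Non-negative, zero iff
    the distributions coincide, and asymmetric in general.
    """
    (m1, s1), (m2, s2) = p, q
    if not (s1 > 0 and s2 > 0):
        raise ValueError("both standard deviations must be positive")
    return float(np.log(s2 / s1) + (s1**2 + (m1 - m2) ** 2) / (2.0 * s2**2) - 0.5)
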