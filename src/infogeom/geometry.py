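"""Fisher metric and differential geometry on statistical manifolds.

The Fisher information matrix I(theta) = J(theta)^T O J(theta) — model
sensitivities J sandwiching the observation-process information O —
defines a Riemannian metric on parameter space. This module assembles
that metric for any process model + observation design and provides the
machinery built on it: Christoffel symbols, geodesic initial- and
boundary-value problems, metric curve length, Riemann/Ricci tensors and
the scalar curvature.

Conventions
-----------
* Geodesics are parametrized by arc length: initial velocities are
  rescaled to unit metric speed, so the curve parameter *is* the
  Fisher-Rao length.
* Riemann tensor (second kind): R^m_{jkl} = d_k Gamma^m_{lj}
  - d_l Gamma^m_{kj} + Gamma^m_{kr} Gamma^r_{lj} - Gamma^m_{lr}
  Gamma^r_{kj}. Ricci is the contraction R_{jl} = R^m_{jml}, and
  Sc = g^{jl} R_{jl}. This sign convention is pinned by the calibration
  Sc = -1 for the single-observation univariate-normal manifold.
* Metric derivatives use central differences with relative steps
  h1 = 1e-4 max(|theta|, 1) (first derivatives) and h2 = 1e-3
  max(|theta|, 1) (the nested derivatives feeding the Riemann tensor).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root
from scipy.stats import chi2

from .observation_models import NoiseModel, observation_fisher, resolve_sigma

__all__ = [
    "MetricField",
    "GeodesicPath",
    "SingularFisherError",
    "fisher_metric",
    "fisher_metric_field",
    "christoffel",
    "geodesic_ivp",
    "geodesic_spray",
    "geodesic_bvp",
    "fisher_rao_normal_distance",
    "curve_length",
    "riemann_tensor",
    "ricci",
    "scalar_curvature",
    "curvature_map",
    "CurvatureMap",
]

_H1 = 1e-4  # relative step, metric first derivatives
_H2 = 1e-3  # relative step, Christoffel derivatives for Riemann
_BOUNDARY_MARGIN = 1e-6


class SingularFisherError(np.linalg.LinAlgError):
    """The Fisher information is singular or indefinite at a point."""


class MetricField:
    """The Fisher information as a field over parameter space.

    Wraps a callable ``theta -> nu x nu`` symmetric positive-definite
    matrix, with inverse access and an admissible box used to truncate
    geodesics and to fall back to one-sided stencils.
    """

    def __init__(self, g, nu: int, bounds=None, source: str = ""):
        self._g = g
        self.nu = int(nu)
        self.bounds = (
            [tuple(b) for b in bounds] if bounds is not None else [(-np.inf, np.inf)] * self.nu
        )
        self.source = source

    def g(self, theta) -> np.ndarray:
        theta = np.atleast_1d(np.asarray(theta, float))
        G = np.asarray(self._g(theta), float)
        if G.shape != (self.nu, self.nu):
            raise ValueError(f"metric returned shape {G.shape}, expected ({self.nu},{self.nu})")
        G = 0.5 * (G + G.T)
        eig = np.linalg.eigvalsh(G)
        if eig[0] <= 0 or eig[0] / eig[-1] < 1e-12:
            vec = np.linalg.eigh(G)[1][:, 0]
            raise SingularFisherError(
                f"Fisher information singular/indefinite at theta={theta.tolist()}; "
                f"deficient direction {np.round(vec, 6).tolist()}"
            )
        return G

    __call__ = g

    def g_inv(self, theta) -> np.ndarray:
        return np.linalg.inv(self.g(theta))

    def speed(self, theta, v) -> float:
        """Metric norm sqrt(v^T g v) of a tangent vector."""
        v = np.asarray(v, float)
        return float(np.sqrt(v @ self.g(theta) @ v))

    def admissible(self, theta) -> bool:
        return all(lo < t < hi for t, (lo, hi) in zip(np.atleast_1d(theta), self.bounds))

    @classmethod
    def from_function(cls, g, nu, bounds=None, source="custom") -> "MetricField":
        return cls(g, nu, bounds, source)

    @classmethod
    def euclidean(cls, nu: int, scale: float = 1.0) -> "MetricField":
        G = scale * np.eye(nu)
        return cls(lambda _theta: G, nu, source="euclidean")

    @classmethod
    def normal(cls, n_obs: int = 1) -> "MetricField":
        """Univariate-normal manifold (mu, sigma) with N iid observations."""

        def g(theta):
            s = theta[1]
            if not s > 0:
                raise ValueError("sigma must be positive")
            return (n_obs / s**2) * np.diag([1.0, 2.0])

        return cls(g, 2, bounds=[(-np.inf, np.inf), (_BOUNDARY_MARGIN, np.inf)], source="normal")


def fisher_metric(model, times, counts, noise: NoiseModel, theta) -> np.ndarray:
    """Assemble I(theta) = J^T O J for a model and observation design.

    The result is data-independent: it depends on the design (times,
    replicate counts, sigma structure) but not the observed values. The
    replicate counts are folded into the observation information O, so
    no extra N factor is applied.
    """
    theta = np.atleast_1d(np.asarray(theta, float))
    times = np.atleast_1d(np.asarray(times, float))
    counts = np.broadcast_to(np.atleast_1d(counts), times.shape)
    sigma = resolve_sigma(noise, theta)
    O = observation_fisher(
        counts,
        sigma,
        n_species=len(model.observed),
        sigma_inferred=model.sigma_inferred,
        collapsed=True,
    )
    Jmu = model.jacobian(theta, times)  # (L*S, nu_model) mean rows
    if model.sigma_inferred:
        # collapsed layout: mean rows, then the single sigma row e_sigma
        # (d mu / d sigma = 0; d sigma / d theta = e_sigma)
        J = np.zeros((Jmu.shape[0] + 1, model.nu))
        J[:-1, :-1] = Jmu
        J[-1, -1] = 1.0
    else:
        J = Jmu
    G = J.T @ O @ J
    G = 0.5 * (G + G.T)
    eig = np.linalg.eigvalsh(G)
    if eig[0] <= 0 or eig[0] / eig[-1] < 1e-10:
        vec = np.linalg.eigh(G)[1][:, 0]
        labels = dict(zip(model.free, np.round(vec, 6)))
        raise SingularFisherError(
            f"Fisher information singular at theta={theta.tolist()} for model "
            f"{model.name!r}; deficient direction {labels}"
        )
    return G


def fisher_metric_field(model, times, counts, noise: NoiseModel) -> MetricField:
    """A :class:`MetricField` over the model's free coordinates."""
    bounds = []
    for lo, hi in model.free_bounds():
        lo = lo + _BOUNDARY_MARGIN if np.isfinite(lo) and lo == 0 else lo
        bounds.append((lo, hi))
    return MetricField(
        lambda th: fisher_metric(model, times, counts, noise, th),
        model.nu,
        bounds=bounds,
        source=f"fisher({model.name}, L={np.atleast_1d(times).size})",
    )


# ---------------------------------------------------------------------------
# connection and curvature
# ---------------------------------------------------------------------------

def _metric_partials(metric: MetricField, theta, step: float) -> np.ndarray:
    """dg[l, i, j] = d g_ij / d theta_l by central differences."""
    theta = np.asarray(theta, float)
    n = theta.size
    out = np.empty((n, n, n))
    for l in range(n):
        h = step * max(abs(theta[l]), 1.0)
        up, dn = theta.copy(), theta.copy()
        up[l] += h
        dn[l] -= h
        lo, hi = metric.bounds[l]
        if up[l] >= hi or dn[l] <= lo:
            warnings.warn("metric stencil exits admissible region; using one-sided difference")
            if up[l] >= hi:
                up = theta
            else:
                dn = theta
        out[l] = (metric.g(up) - metric.g(dn)) / (up[l] - dn[l])
    return out


def christoffel(metric: MetricField, theta, step: float = _H1) -> np.ndarray:
    """Christoffel symbols of the second kind, Gamma[m, i, j].

    Gamma^m_ij = (1/2) g^{ml} (d_i g_lj + d_j g_li - d_l g_ij),
    symmetric in the lower indices (i, j).
    """
    theta = np.atleast_1d(np.asarray(theta, float))
    ginv = metric.g_inv(theta)
    d = _metric_partials(metric, theta, step)
    # term[l,i,j] = d_i g_lj + d_j g_li - d_l g_ij
    term = np.einsum("ilj->lij", d) + np.einsum("jli->lij", d) - d
    return 0.5 * np.einsum("ml,lij->mij", ginv, term)


def riemann_tensor(metric: MetricField, theta, step1: float = _H1, step2: float = _H2) -> np.ndarray:
    """Riemann tensor of the second kind, R[m, j, k, l].

    Built from the Christoffel symbols and their central-difference
    first derivatives (step ``step2``); the symbols themselves use
    ``step1``.
    """
    theta = np.atleast_1d(np.asarray(theta, float))
    n = theta.size
    Gam = christoffel(metric, theta, step1)
    dGam = np.empty((n, n, n, n))  # dGam[k, m, i, j] = d_k Gamma^m_ij
    for k in range(n):
        h = step2 * max(abs(theta[k]), 1.0)
        up, dn = theta.copy(), theta.copy()
        up[k] += h
        dn[k] -= h
        lo, hi = metric.bounds[k]
        if up[k] >= hi or dn[k] <= lo:
            warnings.warn("Riemann stencil exits admissible region; using one-sided difference")
            if up[k] >= hi:
                up = theta
            else:
                dn = theta
        dGam[k] = (christoffel(metric, up, step1) - christoffel(metric, dn, step1)) / (
            up[k] - dn[k]
        )
    R = (
        np.einsum("kmlj->mjkl", dGam)
        - np.einsum("lmkj->mjkl", dGam)
        + np.einsum("mkr,rlj->mjkl", Gam, Gam)
        - np.einsum("mlr,rkj->mjkl", Gam, Gam)
    )
    return R


def ricci(riemann: np.ndarray) -> np.ndarray:
    """Ricci tensor by contraction, R_jl = R^m_{jml}."""
    return np.einsum("mjml->jl", riemann)


def scalar_curvature(metric: MetricField, theta, step1: float = _H1, step2: float = _H2) -> float:
    """Scalar curvature Sc = g^{jl} R_jl at a point.

    Coordinate-invariant; zero for flat (Gaussian-likelihood)
    manifolds, and -1/N on the univariate-normal manifold with N
    observations.
    """
    R = riemann_tensor(metric, theta, step1, step2)
    return float(np.sum(metric.g_inv(theta) * ricci(R)))


@dataclass
class CurvatureMap:
    """Scalar curvature sampled on a rectangular lattice."""

    axis1: np.ndarray
    axis2: np.ndarray
    values: np.ndarray  # (res1, res2), NaN where evaluation failed
    n_failed: int = 0


def curvature_map(metric: MetricField, box, resolution: int = 100) -> CurvatureMap:
    """Sample Sc on a uniform lattice over a 2-D box.

    ``box = ((lo1, hi1), (lo2, hi2))``. Nodes where the metric is
    singular or evaluation fails are marked NaN, never interpolated.
    """
    (lo1, hi1), (lo2, hi2) = box
    ax1 = np.linspace(lo1, hi1, resolution)
    ax2 = np.linspace(lo2, hi2, resolution)
    vals = np.full((resolution, resolution), np.nan)
    failed = 0
    for i, a in enumerate(ax1):
        for j, b in enumerate(ax2):
            try:
                vals[i, j] = scalar_curvature(metric, np.array([a, b]))
            except (SingularFisherError, ValueError, np.linalg.LinAlgError):
                failed += 1
    return CurvatureMap(ax1, ax2, vals, failed)


# ---------------------------------------------------------------------------
# geodesics
# ---------------------------------------------------------------------------

@dataclass
class GeodesicPath:
    """A geodesic sampled along its curve parameter.

    ``s`` is arc length when produced by :func:`geodesic_ivp` (unit
    metric speed); ``length`` is the accumulated metric length and
    ``truncated`` flags paths stopped at the admissible-region boundary.
    """

    s: np.ndarray
    positions: np.ndarray  # (n, nu)
    velocities: np.ndarray  # (n, nu)
    length: float
    truncated: bool = False

    @property
    def start(self) -> np.ndarray:
        return self.positions[0]

    @property
    def end(self) -> np.ndarray:
        return self.positions[-1]

    def speeds(self, metric: MetricField) -> np.ndarray:
        return np.array(
            [metric.speed(p, v) for p, v in zip(self.positions, self.velocities)]
        )


def _geodesic_rhs(metric: MetricField, chr_step: float):
    def rhs(_s, y):
        n = y.size // 2
        theta, v = y[:n], y[n:]
        Gam = christoffel(metric, theta, chr_step)
        acc = -np.einsum("mij,i,j->m", Gam, v, v)
        return np.concatenate([v, acc])

    return rhs


def _boundary_events(metric: MetricField):
    events = []
    for i, (lo, hi) in enumerate(metric.bounds):
        if np.isfinite(lo):
            def ev_lo(_s, y, i=i, lo=lo):
                return y[i] - (lo + _BOUNDARY_MARGIN)

            ev_lo.terminal = True
            events.append(ev_lo)
        if np.isfinite(hi):
            def ev_hi(_s, y, i=i, hi=hi):
                return (hi - _BOUNDARY_MARGIN) - y[i]

            ev_hi.terminal = True
            events.append(ev_hi)
    return events


def geodesic_ivp(
    metric: MetricField,
    start,
    direction,
    target_length: float,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    chr_step: float = _H1,
    n_samples: int = 101,
) -> GeodesicPath:
    """Integrate a geodesic from a point with a given initial direction.

    The first-order reduction of the geodesic equation
    theta'' + Gamma(theta', theta') = 0 is integrated with an adaptive
    5(4) Runge-Kutta pair. The initial velocity is rescaled to unit
    metric speed, so arc length equals the curve parameter and the
    integration runs to s = ``target_length`` (or to the admissible
    boundary, flagged as truncated).
    """
    start = np.atleast_1d(np.asarray(start, float))
    v0 = np.atleast_1d(np.asarray(direction, float))
    if not np.any(v0):
        raise ValueError("initial direction must be nonzero")
    if not metric.admissible(start):
        raise ValueError(f"start {start.tolist()} outside the admissible region")
    v0 = v0 / metric.speed(start, v0)  # unit metric speed
    y0 = np.concatenate([start, v0])
    sol = solve_ivp(
        _geodesic_rhs(metric, chr_step),
        (0.0, target_length),
        y0,
        method="RK45",
        rtol=rtol,
        atol=atol,
        events=_boundary_events(metric),
        dense_output=True,
    )
    truncated = sol.status != 0  # boundary event or metric failure mid-path
    s_end = float(sol.t[-1])
    s = np.linspace(0.0, s_end, n_samples)
    ys = sol.sol(s).T
    n = start.size
    return GeodesicPath(
        s=s,
        positions=ys[:, :n],
        velocities=ys[:, n:],
        length=s_end,
        truncated=truncated,
    )


def geodesic_spray(
    metric: MetricField,
    mle,
    alpha: float = 0.95,
    count: int = 20,
    seed: int = 0,
    **ivp_kwargs,
) -> list[GeodesicPath]:
    """Geodesics emanating from the MLE out to a confidence distance.

    Each of ``count`` geodesics has metric length sqrt(Delta_{nu,alpha})
    — the chi-square confidence distance — with initial directions at
    equidistant angles on the unit circle (nu = 2) or uniformly on the
    unit sphere (higher nu, seeded).
    """
    mle = np.atleast_1d(np.asarray(mle, float))
    nu = mle.size
    length = float(np.sqrt(chi2.ppf(alpha, df=nu)))
    if nu == 2:
        angles = 2.0 * np.pi * np.arange(count) / count
        dirs = np.column_stack([np.cos(angles), np.sin(angles)])
    else:
        rng = np.random.default_rng(seed)
        dirs = rng.standard_normal((count, nu))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return [geodesic_ivp(metric, mle, d, length, **ivp_kwargs) for d in dirs]


def geodesic_bvp(
    metric: MetricField,
    theta_a,
    theta_b,
    tol: float = 1e-8,
    chr_step: float = _H1,
    rtol: float = 1e-10,
    n_samples: int = 51,
) -> GeodesicPath:
    """Connecting geodesic between two points, by shooting.

    The unknown initial velocity w (affine parameter on [0, 1]) is
    solved so the endpoint miss is below ``tol`` in coordinates; the
    returned path's ``length`` is the Fisher-Rao distance between the
    endpoints. Multi-start on the straight-line guess with several
    scalings; non-convergence raises with the best residual.
    """
    a = np.atleast_1d(np.asarray(theta_a, float))
    b = np.atleast_1d(np.asarray(theta_b, float))
    n = a.size
    if np.allclose(a, b):
        pos = np.tile(a, (2, 1))
        return GeodesicPath(np.array([0.0, 1.0]), pos, np.zeros((2, n)), 0.0)
    rhs = _geodesic_rhs(metric, chr_step)

    def shoot(w, dense=False):
        sol = solve_ivp(
            rhs,
            (0.0, 1.0),
            np.concatenate([a, w]),
            method="RK45",
            rtol=rtol,
            atol=1e-12,
            t_eval=np.linspace(0.0, 1.0, n_samples) if dense else None,
        )
        if not sol.success:
            return None
        return sol

    def residual(w):
        sol = shoot(w)
        if sol is None:
            return np.full(n, 1e3)
        return sol.y[:n, -1] - b

    best = None
    for scale in (1.0, 0.5, 2.0, 0.25, 4.0):
        w0 = scale * (b - a)
        res = root(residual, w0, method="hybr", tol=tol * 1e-2)
        miss = float(np.max(np.abs(residual(res.x))))
        if best is None or miss < best[1]:
            best = (res.x, miss)
        if miss < tol:
            break
    w, miss = best
    if miss >= tol:
        raise RuntimeError(
            f"geodesic shooting did not converge between {a.tolist()} and {b.tolist()}: "
            f"best endpoint miss {miss:.3e}"
        )
    sol = shoot(w, dense=True)
    ys = sol.y.T
    path = GeodesicPath(
        s=sol.t,
        positions=ys[:, :n],
        velocities=ys[:, n:],
        length=0.0,
    )
    # constant metric speed along a geodesic: length = mean speed * span
    path.length = float(np.mean(path.speeds(metric)))
    return path


def fisher_rao_normal_distance(p, q, n_obs: int = 1) -> float:
    """Closed-form Fisher-Rao distance on the univariate-normal manifold.

    For points p = (mu1, sigma1), q = (mu2, sigma2) and N iid
    observations,

        d = sqrt(2 N) arccosh(1 + ((mu1-mu2)^2/2 + (sigma1-sigma2)^2)
                                  / (2 sigma1 sigma2)).

    Serves as the independent oracle for :func:`geodesic_bvp` on this
    manifold.
    """
    (m1, s1), (m2, s2) = p, q
    if not (s1 > 0 and s2 > 0):
        raise ValueError("both standard deviations must be positive")
    arg = 1.0 + ((m1 - m2) ** 2 / 2.0 + (s1 - s2) ** 2) / (2.0 * s1 * s2)
    return float(np.sqrt(2.0 * n_obs) * np.arccosh(arg))


def curve_length(metric: MetricField, positions) -> float:
    """Metric length of a sampled curve by composite midpoint quadrature.

    Second-order accurate in the sample spacing and additive over
    concatenation.
    """
    pos = np.atleast_2d(np.asarray(positions, float))
    if pos.shape[0] < 2:
        raise ValueError("a curve needs at least two samples")
    total = 0.0
    for p0, p1 in zip(pos[:-1], pos[1:]):
        d = p1 - p0
        mid = 0.5 * (p0 + p1)
        total += float(np.sqrt(d @ metric.g(mid) @ d))
    return total
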