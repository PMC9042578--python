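# Methods

## Statistical model and scope

Every analysis in this package assumes replicated observations that are
independent normal draws about a deterministic model mean with
*constant* standard deviation σ: `x_ij ~ N(μ(θ, t_j), σ²)` over
replicates i, time points t_j and (for multi-output models) observed
species, all species sharing the same σ. Multiplicative noise and
time- or state-dependent σ(μ) are out of scope. When σ is unknown it is
inferred as a coordinate of θ and is, by project convention, the *last*
coordinate; the model mean never depends on it, which fixes the σ-row
placement in the model Jacobian deterministically.

The model zoo covers constant-mean univariate/bivariate normal
observation processes, linear (`C(t) = a t + C(0)`) and exponential
(`C(t) = C(0) e^{at}`) growth, logistic growth
(`C(t) = C(0)K / (C(0) + (K − C(0))e^{−rt})`) with analytic partials in
r, C(0) and K, and the SIR epidemic model in population proportions
(`S' = −βSI, I' = βSI − γI, R' = γI`). Default truth values are
parameter estimates published for hard-coral regrowth (logistic,
r = 0.9131 yr⁻¹, C(0) = 0.7237 %, K = 79.74 %, σ = 2.301 %) and for a
boarding-school influenza outbreak (SIR, β = 1.6633 d⁻¹,
γ = 0.44036 d⁻¹, S(0) = 762/763, I(0) = 1/763). Time is unitless in the
code; the registry documents the conventional units (years for growth,
days for SIR).

## Inference

The MLE is found by bound-constrained derivative-free maximization —
scipy's Powell method — restarted from 20 Latin-hypercube starts as a
multimodality guard (ties broken by objective, then lexicographic θ).
Tolerances: objective change 1e-10, parameter change 1e-8. For the
constant-mean normal models the optimum has closed form (sample mean,
biased sample SD); the optimizer reproduces it to better than 1e-6 and
the closed forms double as test oracles.

Confidence regions are sublevel sets of the normalized log-likelihood
ℓ̂ = ℓ − ℓ(θ̂) at threshold −Δ_{ν,α}/2, with ν = dim(θ) always and
α = 0.95 by default (overridable). The boundary is traced as a level
curve: a seed point is bracketed by 1-D root finding along up to 36
rays from the MLE (the ray count is this package's choice); the trace
then follows the unit tangent (perpendicular to ∇ℓ̂, central
differences) with a two-stage second-order Runge–Kutta (Heun)
predictor and a per-step projection back onto the level set (Newton
along the gradient, polished by a bracketed root). The step is 1/400 of
the searched box diagonal. Closure requires returning within two step
lengths of the start *while moving in the starting direction* — the
directional clause matters for contours thinner than the step, where
the trace would otherwise declare closure on meeting the opposite side
of a hairpin. Exiting the box flags the region `closed = False`; no ray
crossing at all raises a region-undefined error. Both outcomes are
practical-non-identifiability verdicts: the logistic (r, C(0)) design
with only mid/late-time observations exhibits exactly this behaviour,
while early/mid and three-time designs of the same total size close.

## Geometry

The Fisher metric is assembled as `I(θ) = Jᵀ O J`. The replicate counts
are folded into the observation information O — per-(time, species)
mean rows weighted `N_j/σ²`, plus, when σ is inferred, one collapsed σ
row `2ΣN_j/σ²` — so no separate N factor appears. The assembly is
data-independent: it uses the observation *design* (times, counts, σ
structure), never the drawn values. Singular or indefinite results
raise immediately, naming the deficient direction (e.g. the growth
rate of a logistic process initialized at carrying capacity).

Derivatives of the metric are central finite differences with relative
steps h₁ = 1e-4·max(|θ|, 1) for first derivatives (Christoffel
symbols) and h₂ = 1e-3·max(|θ|, 1) for the nested derivatives feeding
the Riemann tensor — the larger outer step trades truncation error
against amplified rounding noise in the nested difference; both are
configurable. Stencils that would leave the admissible region fall back
to one-sided differences with a warning.

Curvature conventions: Riemann (second kind)
`R^m_{jkl} = ∂_k Γ^m_{lj} − ∂_l Γ^m_{kj} + Γ^m_{kr}Γ^r_{lj} −
Γ^m_{lr}Γ^r_{kj}`, Ricci by contraction `R_{jl} = R^m_{jml}`, and
`Sc = g^{jl} R_{jl}`. The sign convention is pinned by a calibration
test: the single-observation univariate-normal manifold must give
Sc = −1. With N iid observations the metric scales by N and Sc by 1/N;
here N is the *total* observation count in the likelihood, so a design
with three time points and ten replicates each gives Sc = −1/30
whenever σ is inferred alongside one model parameter (verified
analytically — the metric reduces to diag(f(β)/σ², 2M/σ²), a scaled
hyperbolic half-plane with Sc = −1/M — and numerically to ~1e-5). The
numeric pipeline reproduces the constants to |error| < 1e-3, and Sc is
checked to be invariant under reparametrization (r ↔ log r) to 1e-3
relative.

Geodesics integrate the first-order reduction of the geodesic equation
with an adaptive 5(4) Runge–Kutta pair (rtol 1e-10). Initial
velocities are rescaled to unit metric speed so the curve parameter is
arc length; metric speed is conserved along every path to < 1e-4
relative drift, which is asserted as an invariant. Paths stop 1e-6
inside the admissible boundary and are flagged truncated rather than
reflected. Confidence sprays launch 20 geodesics (default) of length
√Δ_{ν,α} in directions equidistant in Euclidean angle (metric
normalization then makes the lengths metric-true); for ν > 2 directions
are drawn uniformly on the sphere with a seed. Boundary value problems
are solved by shooting on the initial velocity over an affine parameter
in [0, 1] (scipy hybrid root finder, endpoint miss < 1e-8 in
coordinates, multi-start over scalings of the straight-line guess); the
path length is the constant metric speed. On the univariate-normal
manifold the closed form
`d = √(2N)·arccosh(1 + ((Δμ)²/2 + (Δσ)²)/(2σ₁σ₂))` serves as an
independent oracle, and the BVP agrees with it to 1e-3 relative over
random endpoint pairs.

## Hypothesis tests and coverage

λ_LR is computed by direct likelihood evaluation at θ₀ and θ̂; λ_GD is
the squared BVP geodesic length (the closed-form oracle can be routed
explicitly on the normal manifold for speed). p-values are χ²(ν)
survival probabilities. On flat manifolds (multivariate-normal means)
the two statistics coincide identically — asserted to 1e-6 — and
geodesic-spray endpoints land exactly on the likelihood boundary; on
the curved (μ, σ) manifold at N = 10 they differ noticeably, with the
geodesic endpoints biased toward smaller σ, consistent with the
downward bias of the variance MLE. The gap shrinks like the asymptotic
identity 2(ℓ(θ̂) − ℓ(θ)) → d² as N grows (checked at N = 10, 100,
1000).

The coverage study simulates datasets at a fixture's truth, fits the
MLE, tests the truth, and reports the fraction of replicates whose
statistic falls at or below Δ_{ν,α}. Replicates use a counter-based
seed stream (base_seed, index) so each one is individually
reproducible. For the normal designs the statistics have closed forms
through the sufficient statistics; the fast path routes through them
and agrees with the generic simulate→fit→test path to 1e-4, which is
itself exercised in the tests. Per-replicate failures are excluded and
counted; more than 1% exclusions fails the run. Coverage assertions
use ±2 binomial standard errors at the stated replicate count. Note a
limitation of that band when the comparison target is itself a
finite-replicate Monte-Carlo estimate rather than a truth value: two
independent 1000-replicate estimates differ by √2 more than a single
estimate deviates from truth, so an honest rerun of a borderline
setting can fall outside the one-sample band. The univariate-normal
N = 10 geodesic-distance setting is the sensitive case: a 400,000
replicate evaluation of the closed-form statistic places its true
coverage at 89.6%.

## Synthetic data

The generator draws `μ(Θ_truth, t_j) + σ z` with z standard normal,
independently per replicate, time and species, deterministic given its
seed. It emulates the reference designs exactly — sample sizes, time
points, replicate counts and noise levels — but none of the ways real
data depart from the model: no heteroscedasticity, no correlation
across times or species, no truncation at zero (a reject-and-redraw
flag exists but defaults off; the designs instead keep σ small enough
that negative draws are improbable). Passing tests therefore validate
the estimators and the geometry under the assumed observation process,
not robustness to misspecification. Negative-control designs (mid/late
logistic) are included so the non-identifiability machinery is
exercised, not just the happy path.

## Numerical sizes used in the shipped checks

Curvature maps and likelihood surfaces default to 100×100 lattices;
the test suite samples coarser grids (3×3 to 41×41) where a constant or
a sign is being verified, and the SIR metric — whose every evaluation
integrates the ODE system several times for finite-difference
sensitivities — is probed at a handful of points. Coverage studies run
1000 replicates through the closed-form fast paths and 15–200
replicates through the generic optimizer path. These sizes are the
package's own choices for its continuous checks; all machinery accepts
larger values.

## Known limitations

- Visualization-oriented machinery (surfaces, contour tracing, circle
  sprays) is restricted to two inferred coordinates; the metric,
  geodesic and curvature code is dimension-generic but untested beyond
  small ν.
- Nested finite differences limit achievable Sc accuracy to roughly
  1e-4–1e-5 relative on smooth metrics; near-singular metrics fail
  loudly rather than extrapolate.
- The contour tracer assumes a connected level set reachable from the
  MLE by ray search; disconnected confidence regions (multimodal
  likelihoods) are out of scope.
- SIR sensitivities use repeated ODE solves rather than forward
  sensitivity equations; accurate, but each metric evaluation costs
  several integrations.
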