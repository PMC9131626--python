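# Methods

## Model

`llfrailty` implements a parametric shared frailty survival model for
two-level data: subjects j = 1..n_i nested in clusters i = 1..G (women
within regions), with observed time t_ij (age at first marriage, or the
interview age if still unmarried), event indicator δ_ij and categorical
covariates Z_ij.

**Baseline.** Event times follow a log-logistic law,

    S0(t) = 1 / (1 + λ t^k),    h0(t) = λ k t^(k-1) / (1 + λ t^k),
    H0(t) = −log S0(t) = log(1 + λ t^k),

with scale λ > 0 and shape k > 0. The hazard is unimodal (rises then
falls) exactly when k > 1, the pattern expected for age at first marriage.
Survival software usually prints the AFT log-time scale γ = 1/k instead of
k; the fitter reports both. One published table of this model family
prints H(t) with (t/λ)^γ where its own S(t) uses λt^γ; the two are
mutually inconsistent, and we define H = −log S, which is the only choice
for which S = e^(−H) holds.

**Covariates.** The linear predictor η = β′Z enters in one of two metrics:

* AFT (default, the reporting metric of the motivating analysis):
  H(t|Z) = H0(t·e^(−η)), so e^β multiplies the median event time and
  φ = exp(coef) > 1 reads "delayed marriage";
* PH: H(t|Z) = e^η·H0(t).

The AFT intercept μ is the log baseline median, tied to the scale by
λ = exp(−kμ). Rescaling time by c shifts μ by log c and leaves (β, k, θ)
unchanged (verified by test).

**Frailty.** Each cluster carries an unobserved multiplicative frailty u_i
acting on all its members' hazards, u_i ~ Gamma(shape 1/θ, scale θ): mean
1, variance θ. Its Laplace transform LP(s) = (1+θs)^(−1/θ) marginalises
the frailty analytically. With d_i events and A_i = Σ_j H(t_ij|Z_ij), the
cluster's marginal log-likelihood is

    Σ_{j: δ=1} log h(t_ij|Z_ij)
      + Σ_{m=0}^{d_i−1} log(1 + mθ)
      − (1/θ + d_i) log(1 + θ A_i).

The log(1+mθ) sum is the numerically stable form of
Γ(1/θ+d)/[Γ(1/θ)θ^(−d)] as θ → 0. Below θ = 1e−8 the code switches to the
exact independence limit Σ δ log h − Σ H, so the boundary is reachable and
continuous (tested to 1e−5). Within-cluster dependence is summarised by
Kendall's τ = θ/(θ+2); the posterior mean frailty of a cluster is
(1/θ + d_i)/(1/θ + A_i) by gamma conjugacy.

## Estimation

Free parameters: (μ, β, log k, log θ). Maximisation is L-BFGS-B with an
analytic gradient (derived per mode; validated against central
differences). Fitting is two-stage and deterministic:

1. no-frailty fit from μ0 = log median observed event time, β = 0, k = 1;
2. frailty fit started from stage 1 plus θ0 = 0.1.

Stage 1 supplies the nested log-likelihood for the boundary LR test of
θ = 0, whose null reference is the 50:50 mixture ½χ²₀ + ½χ²₁ (θ = 0 lies
on the parameter boundary): p = ½·P(χ²₁ ≥ X) for X > 0, p = 1 at X = 0.
Convergence: relative log-likelihood change < 1e−9, projected-gradient
norm < 1e−5, max 500 iterations; non-convergence is flagged on the result,
never raised. θ is optimised on the log scale with box bound
log θ ≥ log(1e−10), which together with the independence branch makes the
boundary numerically attainable.

Standard errors are from the inverse observed information, computed by
central finite differences of the log-likelihood on the *reported* scale
(μ, β, k, θ) with relative step 1e−4 (the differencing utility is exact on
quadratics by construction). γ = 1/k gets a delta-method SE, se(γ) =
se(k)/k². When θ̂ sits at the boundary, the information matrix is computed
over the remaining parameters and the θ SE is reported absent. P-values
are two-sided Wald normal; the text writer floors tiny values at
"≤ 0.001", matching the reporting convention of the motivating tables
(whose borderline middle-wealth row, p = 0.056, is consistent with Wald
normal).

## Synthetic cohort generator

The generator emulates the structure of a DHS-style women's survey
(~12,000 women aged 15–49 in 11 regions) without any access-restricted
microdata:

* **clusters** — 11 regions with fixed unequal sizes 741–1630 (total
  12,066);
* **covariates** — eight categorical covariates (residence, education,
  religion, wealth quintile, head education, work status, media access,
  head occupation) sampled independently of cluster with marginals equal
  to the survey's published sample fractions; an optional Dirichlet
  "cluster mixing" knob induces regional composition differences
  (default off, since no covariate–cluster model is published);
* **event times** — inverse-CDF draws from the frailty-conditional model,
  solving exp(−u·H(t|Z)) = v with v ~ U(0,1); defaults are the published
  fit itself: intercept 2.757132 (baseline median 15.75 y), k = 1/0.131,
  θ = 0.088, and the published AFT coefficient vector;
* **censoring** — a retrospective interview age C, with event iff
  T ≤ min(C, 50); the cap at 50 encodes the working assumption that all
  women marry before age 50. Times are continuous years (published
  medians like 17.2 imply sub-year resolution); no minimum marriage age
  is imposed by default (a floor option exists).

**Interview-age law.** The default is a young-skewed piecewise-uniform
pyramid over 5-year bands [15,20), …, [45,49] with weights (0.45, 0.18,
0.11, 0.08, 0.07, 0.06, 0.05); a flat Uniform(15, 49) alternative is
available. The pyramid weights were calibrated once so that the default
cohort's event fraction (~0.77) sits in the 0.70–0.85 band around the
~78% ever-married share such surveys report: under a flat age law the
published generating parameters imply an event fraction near 0.91,
because the published fitted baseline median (15.75 y) is well below the
survey's raw median marriage age (17.2 y). The weights are deliberately
more youth-heavy than a real survey pyramid for the same reason; they are
a property of the synthetic study design, fixed once, not a tuning dial.

**What the generator does not emulate:** survey weights and stratified
sampling; the joint covariate distribution across regions (marginals
only, unless mixing is enabled); age-cohort trends in marriage timing;
reporting heaping at whole or half years. Passing recovery tests on this
generator therefore demonstrates correctness of the estimator under the
model's own assumptions, not robustness to the ways real survey data
violate them.

## Descriptive summaries

Group tables report counts, percentages against the *full-sample*
denominator (so group married-percentages sum to the overall married
percentage), and mean/median/min/max of observed event ages only — not
Kaplan–Meier: published regional medians (e.g. 14 with heavy censoring)
are only reproducible as observed-case summaries. A KM-median column is
available via an option. Display rounding is 2 dp for percentages and
1 dp for ages; exact values are kept internally.

## Numerical choices and degenerate inputs

* logaddexp/log1p forms keep λt^k and (1+θA) from overflowing for large k;
  event-time inversion runs in log space with log(expm1(H)) = H for
  H > 30 (error < e^(−30)).
* t = 0: S = 1 and H = 0 exactly; the hazard at 0 is 0 for k > 1, λ for
  k = 1, and a domain error for k < 1 (divergent).
* θ = 0 frailty draws are exactly 1; the gamma density is refused at
  θ = 0 (point mass); the posterior mean frailty returns exactly 1.
* Single-cluster data with frailty on, zero events, and collinear dummy
  designs raise immediately with explanatory messages; empty covariate
  categories are dropped from the design with a warning.
* Likelihood accumulation uses integer cluster codes and bincount, making
  every fit invariant to row order by construction.

## Problem sizes used in the verification suite

Chosen to keep the full suite fast while leaving Monte-Carlo error well
inside the asserted bands: oracle agreement on 200 random clusters of
size ≤ 6 with θ ∈ [0.05, 2]; parameter recovery on 50 cohorts of 60
clusters × 200 women at θ = 0.5 (mean relative bias of θ̂ under 10%,
Wald coverage for both effects within [0.90, 0.99]); τ closure on 10⁴
simulated pairs at θ = 1; LR-test size on 500 null cohorts of 40
clusters × 15 women. The θ̂ MLE carries the usual O(1/G) downward
finite-sample bias (about −6% at G = 60, −1% at G = 120), comfortably
inside the asserted band once averaged over replicates.

## Known limitations

* Only the log-logistic baseline is implemented (the architecture keeps
  the baseline behind `LogLogisticParams`, leaving a seam for other
  families, but none are in scope).
* Only gamma (shared) frailty; no inverse-Gaussian, log-normal,
  positive-stable, or correlated frailty.
* No survey weights, left truncation, interval censoring, time-varying
  covariates, or robust/sandwich variances.
* Wald inference near the θ boundary is unreliable by nature; the LR
  mixture test is the supported test for θ = 0.
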