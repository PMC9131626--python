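# llfrailty

Log-logistic accelerated failure time (AFT) survival analysis with a
**gamma shared frailty**, for clustered time-to-event data. The package is
built around a concrete application: modelling age at first marriage among
women nested in regions, where a survey observes each woman
retrospectively at her interview age (right censoring) and women in the
same region share unmeasured influences on marriage timing.

It is organised as an analysis project: the library under `src/llfrailty/`
holds all computation; the numbered scripts under `analysis/` run the
study pipeline (simulate → describe → fit → diagnostics); `tests/` and
`scripts/acceptance.py` verify everything.

## The model

For woman *j* in region *i*, with covariates Z_ij and a region-level
frailty u_i,

    h_ij(t) = u_i · h(t | Z_ij),        u_i ~ Gamma(1/θ, θ)  (mean 1, variance θ),

with a log-logistic baseline S0(t) = 1/(1 + λt^k) and AFT covariate
action H(t|Z) = H0(t·e^(−β′Z)). The gamma Laplace transform
LP(s) = (1+θs)^(−1/θ) integrates the frailty out in closed form, giving a
marginal likelihood per region with sufficient pieces d_i (events) and
A_i = Σ_j H(t_ij|Z_ij):

    ℓ_i = Σ_{δ=1} log h(t_ij|Z_ij) + Σ_{m=0}^{d_i−1} log(1+mθ) − (1/θ+d_i)·log(1+θA_i).

Reported quantities follow the field's conventions: φ = exp(coef) (a time
ratio; φ > 1 means delayed marriage), the AFT shape γ = 1/k, Kendall's
τ = θ/(θ+2) for within-region dependence, and a boundary likelihood-ratio
test of θ = 0 against the ½χ²₀ + ½χ²₁ mixture. Details, assumptions and
numerical choices: [docs/methods.md](docs/methods.md).

Because the motivating survey microdata are access-restricted, the package
ships a first-class synthetic generator (`llfrailty.simulate`) that
emulates the survey's structure — 11 regions of 741–1630 women
(n = 12,066), eight categorical covariates at published marginals, the
published fit as generating truth, interview-age censoring, and an
administrative cap at age 50.

## Worked example

```python
from llfrailty import SyntheticConfig, generate_population, ModelSpec, fit_model

df, truth = generate_population(SyntheticConfig())   # 12,066 women, 11 regions
fit = fit_model(df, ModelSpec())                     # AFT + gamma frailty
print(f"theta = {fit.theta:.4f}, tau = {100*fit.tau:.2f}%, "
      f"gamma = {fit.gamma_reported:.3f}, LR p = {fit.lr_pvalue:.3g}")
```

prints (seeded default cohort):

```
theta = 0.0658, tau = 3.18%, gamma = 0.132, LR p = 1.68e-109
```

i.e. the fitter recovers the generating heterogeneity θ = 0.088 up to the
sampling noise of 11 region-level frailty draws (SD ≈ 0.04 at G = 11),
reproduces the generating AFT shape γ = 0.131, and the LR test
overwhelmingly rejects "no regional heterogeneity". Running the same via
the pipeline:

```bash
python analysis/01_simulate_cohort.py     # cohort -> scratch/, truth -> results/
python analysis/02_descriptive_tables.py  # Table-style group summaries -> results/
python analysis/03_fit_frailty_model.py   # regression table + frailty footer -> results/
python analysis/04_dependence_checks.py   # tau closure + LR null calibration -> results/
```

`analysis/03` prints the full regression table; its footer reads

```
Random effects: gamma = 0.132, theta = 0.066, tau = 3.2%
LR test of theta = 0: X = 492.884, p = <= 0.001 (0.5*chi2_0 + 0.5*chi2_1 reference)
```

The same stages are available as a CLI (`llfrailty simulate|fit|describe|pipeline`),
e.g. `llfrailty pipeline --config cfg.json --seed 7 --out results/run1`.

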