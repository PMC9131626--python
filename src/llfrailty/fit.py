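"""Maximum-likelihood fitting of the log-logistic gamma shared frailty model.

Free parameters are the AFT intercept (log baseline median; log baseline
rate in PH mode), one coefficient per non-reference covariate category, the
log shape log(k) and, with frailty on, the log frailty variance log(theta).
The frailty is integrated out of the likelihood analytically per cluster
(see :mod:`llfrailty.frailty`), so the objective is an ordinary smooth
log-likelihood maximised by L-BFGS-B with an analytic gradient.

Fitting is two-stage and deterministic: a no-frailty fit started from
(intercept = log median observed event time, beta = 0, k = 1) provides both
the nested-model log-likelihood for the boundary LR test of theta = 0 and
the starting point (with theta = 0.1) for the frailty fit.

Standard errors are square roots of the diagonal of the inverse observed
information, computed by central finite differences of the log-likelihood
on the reported parameter scale (intercept, beta, k, theta); the AFT
log-time scale gamma = 1/k gets a delta-method SE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .baseline import _check_mode
from .frailty import THETA_FLOOR, kendalls_tau, lr_test_theta
from .numdiff import numeric_hessian

__all__ = [
    "Covariate",
    "ModelSpec",
    "FitOptions",
    "FitResult",
    "fit_model",
    "time_ratio",
    "wald_pvalue",
    "standard_errors",
    "summary_table",
]


@dataclass(frozen=True)
class Covariate:
    name: str
    categories: tuple
    reference: str

    def __post_init__(self) -> None:
        if len(self.categories) < 2:
            raise ValueError(f"covariate {self.name!r} needs >= 2 categories")
        if self.reference not in self.categories:
            raise ValueError(
                f"reference {self.reference!r} not among categories of "
                f"{self.name!r}"
            )


# reference categories follow the DHS analysis convention: urban,
# no-education, orthodox, poorest, head no-education, not working,
# no media access, agriculturalist head
SURVEY_COVARIATES = (
    Covariate("residence", ("urban", "rural"), "urban"),
    Covariate(
        "education", ("no_education", "primary", "secondary", "higher"),
        "no_education",
    ),
    Covariate(
        "religion",
        ("orthodox", "catholic", "protestant", "muslim", "other"),
        "orthodox",
    ),
    Covariate(
        "wealth", ("poorest", "poorer", "middle", "richer", "richest"),
        "poorest",
    ),
    Covariate(
        "head_education",
        ("no_education", "primary", "secondary", "higher"),
        "no_education",
    ),
    Covariate("work", ("no", "yes"), "no"),
    Covariate("media", ("no", "yes"), "no"),
    Covariate(
        "head_occupation",
        ("agriculturalist", "professional", "laborers", "business", "other"),
        "agriculturalist",
    ),
)


@dataclass(frozen=True)
class ModelSpec:
    """Covariate coding, covariate mode (PH/AFT) and frailty switch."""

    covariates: tuple = SURVEY_COVARIATES
    mode: str = "aft"
    frailty: bool = True
    cluster_field: str = "cluster"
    time_field: str = "time"
    event_field: str = "event"

    def __post_init__(self) -> None:
        _check_mode(self.mode)
        names = [c.name for c in self.covariates]
        if len(set(names)) != len(names):
            raise ValueError("duplicate covariate names")


@dataclass(frozen=True)
class FitOptions:
    max_iter: int = 500
    ftol: float = 1e-9
    gtol: float = 1e-5
    theta_start: float = 0.1
    compute_se: bool = True
    hessian_rel_step: float = 1e-4


@dataclass
class FitResult:
    intercept: float
    beta: dict
    shape_k: float
    gamma_reported: float
    theta: float
    tau: float
    loglik: float
    loglik_nofrailty: float
    lr_stat: float
    lr_pvalue: float
    param_names: list
    vcov: np.ndarray
    se: dict
    converged: bool
    n_iter: int
    mode: str
    frailty: bool
    n_obs: int
    n_clusters: int
    n_events: int
    message: str = ""

    @property
    def coef(self) -> dict:
        out = {"intercept": self.intercept}
        out.update(self.beta)
        return out


def time_ratio(coef: float) -> float:
    """phi = exp(coef): the factor by which event time is delayed (AFT).

    The source tables label this an odds ratio; either way it is exp(coef),
    with values above 1 meaning a delayed event relative to the reference.
    """
    if not np.isfinite(coef):
        raise ValueError(f"coef must be finite, got {coef}")
    return float(np.exp(coef))


def wald_pvalue(coef: float, se: float) -> float:
    """Two-sided normal p-value, p = 2*(1 - Phi(|coef/se|))."""
    if not (np.isfinite(se) and se > 0):
        raise ValueError(f"se must be finite and > 0, got {se}")
    return float(2.0 * stats.norm.sf(abs(coef / se)))


# ---------------------------------------------------------------------------
# design matrix


def build_design(data: pd.DataFrame, spec: ModelSpec):
    """Treatment-coded dummy matrix against each covariate's reference.

    Column order follows the schema's category order, not the data.
    Categories declared in the schema but absent from the data are dropped
    with a warning; values in the data but not in the schema are an error.
    """
    cols, names = [], []
    for cov in spec.covariates:
        if cov.name not in data.columns:
            raise ValueError(f"covariate column {cov.name!r} missing from data")
        vals = data[cov.name].astype(str)
        unknown = sorted(set(vals) - set(map(str, cov.categories)))
        if unknown:
            raise ValueError(
                f"column {cov.name!r} contains categories outside the "
                f"schema: {unknown}"
            )
        for cat in cov.categories:
            if cat == cov.reference:
                continue
            col = (vals == str(cat)).to_numpy(dtype=float)
            if col.sum() == 0:
                warnings.warn(
                    f"category {cov.name}={cat!r} has zero rows; "
                    "dropped from the design",
                    stacklevel=2,
                )
                continue
            cols.append(col)
            names.append(f"{cov.name}:{cat}")
    X = np.column_stack(cols) if cols else np.empty((len(data), 0))
    full = np.column_stack([np.ones(len(data)), X])
    if np.linalg.matrix_rank(full) < full.shape[1]:
        raise ValueError(
            "singular design: some dummy columns are collinear "
            f"(columns: {names})"
        )
    return X, names


# ---------------------------------------------------------------------------
# vectorised marginal log-likelihood


class LoglikEngine:
    """Marginal log-likelihood (and gradient) over all clusters, vectorised.

    The per-cluster sufficient pieces are d_i (event count) and
    A_i = sum of conditional cumulative hazards, accumulated with bincount
    over integer cluster codes; the objective is therefore invariant to
    row order by construction.
    """

    def __init__(self, times, events, cluster_codes, X, mode: str):
        self.t = np.asarray(times, dtype=float)
        if np.any(self.t <= 0) or not np.all(np.isfinite(self.t)):
            raise ValueError("times must be finite and > 0")
        self.logt = np.log(self.t)
        self.events = np.asarray(events).astype(bool)
        self.codes = np.asarray(cluster_codes, dtype=int)
        self.X = np.asarray(X, dtype=float)
        self.mode = _check_mode(mode)
        self.n = self.t.size
        self.n_clusters = int(self.codes.max()) + 1 if self.n else 0
        self.d = np.bincount(
            self.codes, weights=self.events, minlength=self.n_clusters
        ).astype(int)
        self.n_events = int(self.events.sum())
        self.p = self.X.shape[1]

    # -- shared frailty pieces ---------------------------------------------
    def _cluster_terms(self, A, theta):
        """(loglik cluster terms, per-subject weight g, d-series derivative)."""
        if theta < THETA_FLOOR:
            return -A.sum(), np.ones(self.n), 0.0
        maxd = self.d.max() if self.d.size else 0
        m = np.arange(maxd)
        cs_log = np.concatenate([[0.0], np.cumsum(np.log1p(theta * m))])
        cs_der = np.concatenate([[0.0], np.cumsum(m / (1.0 + theta * m))])
        log1pA = np.log1p(theta * A)
        ll = cs_log[self.d].sum() - ((1.0 / theta + self.d) * log1pA).sum()
        B = (1.0 + theta * self.d) / (1.0 + theta * A)  # -d ll / d A_i
        dtheta = (
            cs_der[self.d].sum()
            + log1pA.sum() / theta**2
            - ((1.0 / theta + self.d) * A / (1.0 + theta * A)).sum()
        )
        return ll, B[self.codes], dtheta

    def loglik_grad(self, intercept, beta, k, theta):
        """Log-likelihood and gradient wrt (intercept, beta, k, theta)."""
        ev = self.events
        if self.mode == "aft":
            s = intercept + (self.X @ beta if self.p else 0.0)
            logw = self.logt - s
            a = k * logw
            H = np.logaddexp(0.0, a)
            sig = np.exp(a - H)
            logh = np.log(k) + (k - 1.0) * logw - H - s
        else:
            eta = self.X @ beta if self.p else np.zeros(self.n)
            a = intercept + k * self.logt
            H0 = np.logaddexp(0.0, a)
            sig = np.exp(a - H0)
            eeta = np.exp(eta)
            H = eeta * H0
            logh = eta + intercept + np.log(k) + (k - 1.0) * self.logt - H0
        A = np.bincount(self.codes, weights=H, minlength=self.n_clusters)
        sum_logh = logh[ev].sum()
        clust_ll, g, dtheta = self._cluster_terms(A, theta)
        ll = sum_logh + clust_ll

        grad = np.empty(self.p + 3)
        if self.mode == "aft":
            c = ev * k * (sig - 1.0) + g * k * sig
            grad[0] = c.sum()
            if self.p:
                grad[1 : 1 + self.p] = self.X.T @ c
            dk = (
                (1.0 / k + (1.0 - sig[ev]) * logw[ev]).sum()
                - (g * sig * logw).sum()
            )
        else:
            grad[0] = (1.0 - sig[ev]).sum() - (g * eeta * sig).sum()
            if self.p:
                grad[1 : 1 + self.p] = self.X.T @ (
                    ev.astype(float) - g * eeta * H0
                )
            dk = (
                (1.0 / k + (1.0 - sig[ev]) * self.logt[ev]).sum()
                - (g * eeta * sig * self.logt).sum()
            )
        grad[self.p + 1] = dk
        grad[self.p + 2] = dtheta
        return ll, grad

    def loglik(self, intercept, beta, k, theta):
        return self.loglik_grad(intercept, beta, k, theta)[0]


def _pack_obj(engine: LoglikEngine, frailty: bool):
    """Objective for L-BFGS-B: x = [intercept, beta..., log k (, log theta)]."""
    p = engine.p

    def nll(x):
        k = np.exp(x[p + 1])
        theta = np.exp(x[p + 2]) if frailty else 0.0
        ll, grad = engine.loglik_grad(x[0], x[1 : 1 + p], k, theta)
        if not np.isfinite(ll):
            return np.inf, np.zeros(x.size)
        out = np.empty(x.size)
        out[: p + 1] = -grad[: p + 1]
        out[p + 1] = -grad[p + 1] * k  # chain rule to log k
        if frailty:
            out[p + 2] = -grad[p + 2] * theta
        return -ll, out

    return nll


def _run_lbfgsb(nll, x0, bounds, opts: FitOptions):
    return optimize.minimize(
        nll,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={
            "maxiter": opts.max_iter,
            "ftol": opts.ftol,
            "gtol": opts.gtol,
        },
    )


def fit_model(
    data: pd.DataFrame,
    spec: ModelSpec,
    options: FitOptions | None = None,
) -> FitResult:
    """Fit the model by maximum likelihood.

    Raises for unidentifiable setups (single cluster with frailty on, no
    events, singular design); non-convergence is flagged on the result,
    not raised.
    """
    opts = options or FitOptions()
    for col in (spec.time_field, spec.event_field, spec.cluster_field):
        if col not in data.columns:
            raise ValueError(f"required column {col!r} missing from data")
    times = data[spec.time_field].to_numpy(dtype=float)
    events = data[spec.event_field].to_numpy()
    if not np.isin(events, (0, 1)).all():
        raise ValueError("event column must be 0/1")
    events = events.astype(int)
    if events.sum() == 0:
        raise ValueError("no events in the data: model not identifiable")
    clusters, codes = np.unique(data[spec.cluster_field].to_numpy(), return_inverse=True)
    if spec.frailty and len(clusters) < 2:
        raise ValueError(
            "frailty variance is unidentifiable with a single cluster; "
            "use frailty=False or supply >= 2 clusters"
        )
    X, coef_names = build_design(data, spec)
    engine = LoglikEngine(times, events, codes, X, spec.mode)
    p = engine.p

    med = float(np.median(times[events == 1]))
    inter0 = np.log(med) if spec.mode == "aft" else -np.log(med)
    x0 = np.zeros(p + 2)
    x0[0] = inter0
    bounds = (
        [(-300.0, 50.0)]
        + [(-20.0, 20.0)] * p
        + [(-4.0, 4.0)]  # log k
    )

    res0 = _run_lbfgsb(_pack_obj(engine, frailty=False), x0, bounds, opts)
    loglik_nofrailty = -float(res0.fun)
    n_iter = int(res0.nit)

    if spec.frailty:
        x1 = np.concatenate([res0.x, [np.log(opts.theta_start)]])
        bounds1 = bounds + [(np.log(1e-10), np.log(50.0))]
        res = _run_lbfgsb(_pack_obj(engine, frailty=True), x1, bounds1, opts)
        n_iter += int(res.nit)
        theta = float(np.exp(res.x[p + 2]))
        if theta < THETA_FLOOR:
            theta = 0.0
    else:
        res = res0
        theta = 0.0

    intercept = float(res.x[0])
    beta_vec = np.asarray(res.x[1 : 1 + p], dtype=float)
    k = float(np.exp(res.x[p + 1]))
    loglik = -float(res.fun)
    lr_stat, lr_p = lr_test_theta(max(loglik, loglik_nofrailty), loglik_nofrailty)

    param_names = ["intercept"] + coef_names + ["shape_k"]
    free_theta = spec.frailty and theta > THETA_FLOOR
    if free_theta:
        param_names.append("theta")

    vcov = np.full((len(param_names), len(param_names)), np.nan)
    se = {name: np.nan for name in param_names}
    if opts.compute_se:
        vcov, se = _observed_info_se(
            engine, intercept, beta_vec, k, theta, coef_names,
            free_theta, opts.hessian_rel_step,
        )
    se["gamma_reported"] = (
        se.get("shape_k", np.nan) / k**2
        if np.isfinite(se.get("shape_k", np.nan))
        else np.nan
    )

    return FitResult(
        intercept=intercept,
        beta=dict(zip(coef_names, beta_vec.tolist())),
        shape_k=k,
        gamma_reported=1.0 / k,
        theta=theta,
        tau=kendalls_tau(theta),
        loglik=loglik,
        loglik_nofrailty=loglik_nofrailty,
        lr_stat=lr_stat,
        lr_pvalue=lr_p,
        param_names=param_names,
        vcov=vcov,
        se=se,
        converged=bool(res.success),
        n_iter=n_iter,
        mode=spec.mode,
        frailty=spec.frailty,
        n_obs=engine.n,
        n_clusters=engine.n_clusters,
        n_events=engine.n_events,
        message=str(res.message),
    )


def _observed_info_se(
    engine, intercept, beta, k, theta, coef_names, free_theta, rel_step
):
    """Inverse observed information on the reported scale
    (intercept, beta, k and, when estimated off the boundary, theta)."""
    p = engine.p

    def negll(y):
        th = y[p + 2] if free_theta else theta
        if y[p + 1] <= 0 or (free_theta and th < 0):
            return np.inf
        return -engine.loglik(y[0], y[1 : 1 + p], y[p + 1], th)

    y0 = np.concatenate([[intercept], beta, [k], [theta] if free_theta else []])
    names = ["intercept"] + list(coef_names) + ["shape_k"] + (
        ["theta"] if free_theta else []
    )
    try:
        info = numeric_hessian(negll, y0, rel_step=rel_step)
        vcov = np.linalg.inv(info)
        diag = np.diag(vcov)
        if np.any(diag < 0):
            raise np.linalg.LinAlgError("negative variance")
        se = {n: float(np.sqrt(v)) for n, v in zip(names, diag)}
    except np.linalg.LinAlgError:
        vcov = np.full((len(names), len(names)), np.nan)
        se = {n: np.nan for n in names}
    if not free_theta:
        se.setdefault("theta", np.nan)
    return vcov, se


def standard_errors(fit: FitResult) -> dict:
    """Per-parameter standard errors of a converged fit (NaN where absent)."""
    return dict(fit.se)


def summary_table(fit: FitResult, spec: ModelSpec) -> pd.DataFrame:
    """Regression table: one row per non-reference category plus the constant.

    Columns: coef, se, p_value (Wald normal), phi = exp(coef).  Model-level
    quantities (gamma, theta, tau, LR-test p of theta = 0, log-likelihood)
    ride along in ``DataFrame.attrs["footer"]``.
    """
    rows = [
        {
            "covariate": "constant",
            "category": "",
            "coef": fit.intercept,
            "se": fit.se.get("intercept", np.nan),
        }
    ]
    for cov in spec.covariates:
        for cat in cov.categories:
            if cat == cov.reference:
                continue
            name = f"{cov.name}:{cat}"
            if name not in fit.beta:
                continue  # dropped empty category
            rows.append(
                {
                    "covariate": cov.name,
                    "category": cat,
                    "coef": fit.beta[name],
                    "se": fit.se.get(name, np.nan),
                }
            )
    df = pd.DataFrame(rows)
    df["p_value"] = [
        wald_pvalue(c, s) if np.isfinite(s) and s > 0 else np.nan
        for c, s in zip(df["coef"], df["se"])
    ]
    df["phi"] = [time_ratio(c) for c in df["coef"]]
    footer = {
        "gamma": fit.gamma_reported,
        "shape_k": fit.shape_k,
        "loglik": fit.loglik,
        "converged": fit.converged,
    }
    if fit.frailty:
        footer.update(
            theta=fit.theta,
            tau=fit.tau,
            lr_stat=fit.lr_stat,
            lr_pvalue=fit.lr_pvalue,
            loglik_nofrailty=fit.loglik_nofrailty,
        )
    df.attrs["footer"] = footer
    return df
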