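"""Gamma shared frailty: density, Laplace transform, marginal likelihood.

Each cluster (region) i carries one unobserved multiplicative frailty u_i
acting on every member's hazard.  The frailty is gamma with mean 1 and
variance theta (shape 1/theta, scale theta), whose Laplace transform

    LP(s) = E[exp(-u s)] = (1 + theta*s)**(-1/theta)

lets the frailty be integrated out of the likelihood in closed form.  With
d = number of events in the cluster and A = sum of conditional cumulative
hazards over its members, the marginal cluster log-likelihood is

    sum_{events} log h_cond(t_j)
      + sum_{m=0}^{d-1} log(1 + m*theta)
      - (1/theta + d) * log(1 + theta*A).

The product Gamma(1/theta+d) / [Gamma(1/theta) * theta**(-d)] is computed
as the log(1+m*theta) sum for stability as theta -> 0; below THETA_FLOOR
the independence formulas are used (the continuous theta -> 0 limit).

Within-cluster dependence is summarised by Kendall's tau = theta/(theta+2),
and the presence of heterogeneity is tested with a boundary likelihood-ratio
test whose null reference is the 50:50 mixture of chi-square with 0 and 1
degrees of freedom (theta = 0 sits on the boundary of the parameter space).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .baseline import LinearPredictor, LogLogisticParams, _check_mode, conditional_cumhaz, conditional_hazard

__all__ = [
    "THETA_FLOOR",
    "FrailtySpec",
    "ClusterData",
    "gamma_frailty_logdensity",
    "laplace_transform",
    "kendalls_tau",
    "cluster_loglik",
    "total_loglik",
    "frailty_posterior_mean",
    "lr_test_theta",
]

#: below this frailty variance the marginal likelihood switches to the
#: exact independence (theta -> 0) limit
THETA_FLOOR = 1e-8


@dataclass(frozen=True)
class FrailtySpec:
    """Frailty variance theta >= 0; theta = 0 means independence."""

    theta: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.theta) and self.theta >= 0):
            raise ValueError(f"theta must be finite and >= 0, got {self.theta}")


@dataclass
class ClusterData:
    """Observed data for one cluster: times, event flags, linear predictors."""

    cluster_id: object
    times: np.ndarray
    events: np.ndarray
    etas: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events)
        if self.etas is None:
            self.etas = np.zeros_like(self.times)
        self.etas = np.asarray(self.etas, dtype=float)
        n = len(self.times)
        if len(self.events) != n or len(self.etas) != n:
            raise ValueError("times, events and etas must have equal length")
        if np.any(self.times <= 0) or not np.all(np.isfinite(self.times)):
            raise ValueError("times must be finite and > 0")
        if not np.isin(self.events, (0, 1)).all():
            raise ValueError("events must be 0/1")
        self.events = self.events.astype(int)

    @property
    def d(self) -> int:
        """Number of events in the cluster."""
        return int(self.events.sum())


def gamma_frailty_logdensity(u, fs: FrailtySpec):
    """Log-density of the mean-1 gamma frailty (shape 1/theta, scale theta)."""
    if fs.theta <= 0:
        raise ValueError(
            "theta = 0 is a point mass at u = 1 and has no density"
        )
    arr = np.asarray(u, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("frailty u must be > 0")
    shape = 1.0 / fs.theta
    out = stats.gamma.logpdf(arr, a=shape, scale=fs.theta)
    return float(out) if np.isscalar(u) or arr.ndim == 0 else out


def laplace_transform(s, fs: FrailtySpec):
    """LP(s) = (1 + theta*s)**(-1/theta); exp(-s) in the theta -> 0 limit."""
    arr = np.asarray(s, dtype=float)
    if np.any(arr < 0):
        raise ValueError("s must be >= 0")
    if fs.theta < THETA_FLOOR:
        out = np.exp(-arr)
    else:
        out = np.exp(-np.log1p(fs.theta * arr) / fs.theta)
    return float(out) if np.isscalar(s) or arr.ndim == 0 else out


def kendalls_tau(fs: FrailtySpec | float) -> float:
    """Kendall's tau between two event times sharing a gamma frailty:
    tau = theta / (theta + 2)."""
    theta = fs.theta if isinstance(fs, FrailtySpec) else float(fs)
    if not (np.isfinite(theta) and theta >= 0):
        raise ValueError(f"theta must be finite and >= 0, got {theta}")
    return theta / (theta + 2.0)


def _event_series_sum(d: np.ndarray, theta: float) -> float:
    """sum over clusters of sum_{m=0}^{d_i - 1} log(1 + m*theta)."""
    d = np.asarray(d, dtype=int)
    if d.size == 0 or d.max() == 0:
        return 0.0
    cs = np.concatenate(
        [[0.0], np.cumsum(np.log1p(theta * np.arange(d.max())))]
    )
    return float(cs[d].sum())


def marginal_loglik_terms(
    logh_events: float, A: float, d: int, theta: float
) -> float:
    """Marginal log-likelihood of one cluster from its sufficient pieces."""
    if theta < THETA_FLOOR:
        return logh_events - A
    return (
        logh_events
        + _event_series_sum(np.array([d]), theta)
        - (1.0 / theta + d) * np.log1p(theta * A)
    )


def cluster_loglik(
    cd: ClusterData,
    p: LogLogisticParams,
    fs: FrailtySpec,
    mode: str = "aft",
) -> float:
    """Marginal log-likelihood contribution of one cluster (frailty integrated
    out analytically via the gamma Laplace transform)."""
    mode = _check_mode(mode)
    H = np.array(
        [
            conditional_cumhaz(t, p, LinearPredictor(e, mode))
            for t, e in zip(cd.times, cd.etas)
        ]
    )
    logh = 0.0
    for t, e, ev in zip(cd.times, cd.etas, cd.events):
        if ev:
            logh += np.log(conditional_hazard(t, p, LinearPredictor(e, mode)))
    A = float(H.sum())
    out = marginal_loglik_terms(logh, A, cd.d, fs.theta)
    if not np.isfinite(out):
        raise FloatingPointError(
            f"non-finite cluster log-likelihood (theta={fs.theta}, A={A})"
        )
    return float(out)


def total_loglik(
    clusters,
    p: LogLogisticParams,
    fs: FrailtySpec,
    mode: str = "aft",
) -> float:
    """Sum of cluster log-likelihood contributions over all clusters."""
    clusters = list(clusters)
    if not clusters:
        raise ValueError("need at least one cluster")
    return float(sum(cluster_loglik(cd, p, fs, mode) for cd in clusters))


def frailty_posterior_mean(
    cd: ClusterData,
    p: LogLogisticParams,
    fs: FrailtySpec,
    mode: str = "aft",
) -> float:
    """E[u_i | data]: by gamma conjugacy (1/theta + d) / (1/theta + A).

    Clusters with more events than expected (d > A) have posterior-mean
    frailty above 1: they experience the event earlier than average.
    """
    if fs.theta == 0:
        return 1.0
    mode = _check_mode(mode)
    A = float(
        sum(
            conditional_cumhaz(t, p, LinearPredictor(e, mode))
            for t, e in zip(cd.times, cd.etas)
        )
    )
    inv = 1.0 / fs.theta
    return (inv + cd.d) / (inv + A)


def lr_test_theta(
    loglik_frailty: float, loglik_nofrailty: float
) -> tuple[float, float]:
    """Boundary likelihood-ratio test of theta = 0.

    The statistic X = 2*(l_frailty - l_nofrailty) is referred to the
    50:50 mixture chi2_0 : chi2_1, so p = 0.5*P(chi2_1 >= X) for X > 0
    and p = 1 at X = 0.
    """
    x = 2.0 * (loglik_frailty - loglik_nofrailty)
    if x < -1e-6:
        raise ValueError(
            "frailty log-likelihood below no-frailty log-likelihood: "
            "models are not nested fits of the same data"
        )
    x = max(x, 0.0)
    p = 1.0 if x == 0.0 else 0.5 * float(stats.chi2.sf(x, df=1))
    return x, p
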