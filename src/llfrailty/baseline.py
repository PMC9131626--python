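"""Log-logistic baseline survival distribution and conditional forms.

The baseline law is parameterised as

    S0(t) = 1 / (1 + lam * t**k),   lam > 0, k > 0,

with hazard h0(t) = lam*k*t**(k-1) / (1 + lam*t**k) and cumulative hazard
H0(t) = -log S0(t) = log(1 + lam*t**k).  The hazard is unimodal (rises then
falls) exactly when k > 1, the non-monotone shape reported for age at first
marriage.

Covariates enter through a linear predictor eta = beta'Z in one of two modes:

* ``"aft"`` (accelerated failure time, the default reporting metric):
  time is rescaled, H(t) = H0(t * exp(-eta)); exp(eta) multiplies the
  median, so exp(coef) > 1 means a delayed event.
* ``"ph"`` (proportional hazards): the hazard is scaled,
  H(t) = exp(eta) * H0(t).

In survival-software convention the log-logistic AFT shape is often printed
as the log-time scale gamma = 1/k; :meth:`LogLogisticParams.reported_gamma`
exposes that metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LogLogisticParams",
    "LinearPredictor",
    "loglogistic_survival",
    "loglogistic_hazard",
    "loglogistic_pdf",
    "loglogistic_cumhaz",
    "loglogistic_quantile",
    "conditional_cumhaz",
    "conditional_hazard",
]

MODES = ("ph", "aft")


@dataclass(frozen=True)
class LogLogisticParams:
    """Baseline scale/shape pair.

    ``lam`` is the rate-like scale (dimension time**-k); ``k`` the
    dimensionless shape.  The baseline median is ``lam**(-1/k)``.
    """

    lam: float
    k: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lam) and self.lam > 0):
            raise ValueError(f"lam must be finite and > 0, got {self.lam}")
        if not (np.isfinite(self.k) and self.k > 0):
            raise ValueError(f"k must be finite and > 0, got {self.k}")

    def reported_gamma(self) -> float:
        """AFT log-time scale metric, gamma = 1/k."""
        return 1.0 / self.k

    def median(self) -> float:
        return float(self.lam ** (-1.0 / self.k))

    @classmethod
    def from_aft(cls, intercept: float, k: float) -> "LogLogisticParams":
        """Baseline whose median is exp(intercept): lam = exp(-k*intercept)."""
        return cls(lam=float(np.exp(-k * intercept)), k=k)


@dataclass(frozen=True)
class LinearPredictor:
    """The value beta'Z for one subject plus the covariate mode."""

    eta: float
    mode: str = "aft"

    def __post_init__(self) -> None:
        if not np.isfinite(self.eta):
            raise ValueError(f"eta must be finite, got {self.eta}")
        _check_mode(self.mode)


def _check_mode(mode: str) -> str:
    m = str(mode).lower()
    if m not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    return m


def _check_time(t, allow_zero: bool = True):
    arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("t must be finite")
    if allow_zero:
        if np.any(arr < 0):
            raise ValueError("t must be >= 0")
    else:
        if np.any(arr <= 0):
            raise ValueError("t must be > 0")
    return arr, np.isscalar(t) or arr.ndim == 0


def _ret(x, scalar: bool):
    return float(x) if scalar else x


def loglogistic_survival(t, p: LogLogisticParams):
    """S(t) = 1 / (1 + lam * t**k); S(0) = 1."""
    arr, scalar = _check_time(t, allow_zero=True)
    with np.errstate(over="ignore"):
        s = np.exp(-loglogistic_cumhaz(arr, p))
    return _ret(s, scalar)


def loglogistic_cumhaz(t, p: LogLogisticParams):
    """H(t) = -log S(t) = log(1 + lam * t**k); H(0) = 0."""
    arr, scalar = _check_time(t, allow_zero=True)
    out = np.zeros_like(arr, dtype=float)
    pos = arr > 0
    # logaddexp keeps lam*t**k from overflowing for large k
    out[pos] = np.logaddexp(0.0, np.log(p.lam) + p.k * np.log(arr[pos]))
    return _ret(out, scalar)


def loglogistic_hazard(t, p: LogLogisticParams):
    """h(t) = lam*k*t**(k-1) / (1 + lam*t**k).

    At t = 0 the hazard is 0 for k > 1, lam for k = 1, and divergent for
    k < 1 (a domain error).
    """
    arr, scalar = _check_time(t, allow_zero=True)
    if np.any(arr == 0) and p.k < 1:
        raise ValueError("hazard diverges at t = 0 for shape k < 1")
    out = np.empty_like(arr, dtype=float)
    zero = arr == 0
    out[zero] = p.lam if p.k == 1 else 0.0
    pos = ~zero
    tp = arr[pos]
    logh = (
        np.log(p.lam)
        + np.log(p.k)
        + (p.k - 1.0) * np.log(tp)
        - loglogistic_cumhaz(tp, p)
    )
    out[pos] = np.exp(logh)
    return _ret(out, scalar)


def loglogistic_pdf(t, p: LogLogisticParams):
    """f(t) = h(t) * S(t) = lam*k*t**(k-1) / (1 + lam*t**k)**2."""
    arr, scalar = _check_time(t, allow_zero=True)
    out = loglogistic_hazard(arr, p) * loglogistic_survival(arr, p)
    return _ret(out, scalar)


def loglogistic_quantile(s, p: LogLogisticParams):
    """Inverse of the survival function: t with S(t) = s, for s in (0, 1)."""
    arr = np.asarray(s, dtype=float)
    scalar = np.isscalar(s) or arr.ndim == 0
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0) or np.any(arr >= 1):
        raise ValueError("survival probability s must lie strictly in (0, 1)")
    t = ((1.0 - arr) / (arr * p.lam)) ** (1.0 / p.k)
    return _ret(t, scalar)


def _eta_mode(lp) -> tuple[float, str]:
    if isinstance(lp, LinearPredictor):
        return lp.eta, _check_mode(lp.mode)
    raise TypeError("lp must be a LinearPredictor")


def conditional_cumhaz(t, p: LogLogisticParams, lp: LinearPredictor):
    """Covariate-conditional cumulative hazard at frailty u = 1.

    PH: exp(eta)*H0(t).  AFT: H0(t*exp(-eta)).  Both equal H0(t) at eta=0.
    """
    eta, mode = _eta_mode(lp)
    arr, scalar = _check_time(t, allow_zero=True)
    if mode == "ph":
        out = np.exp(eta) * loglogistic_cumhaz(arr, p)
    else:
        out = loglogistic_cumhaz(arr * np.exp(-eta), p)
    return _ret(out, scalar)


def conditional_hazard(t, p: LogLogisticParams, lp: LinearPredictor):
    """Covariate-conditional hazard at frailty u = 1 (d/dt of conditional_cumhaz)."""
    eta, mode = _eta_mode(lp)
    arr, scalar = _check_time(t, allow_zero=True)
    if mode == "ph":
        out = np.exp(eta) * loglogistic_hazard(arr, p)
    else:
        out = np.exp(-eta) * loglogistic_hazard(arr * np.exp(-eta), p)
    return _ret(out, scalar)
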