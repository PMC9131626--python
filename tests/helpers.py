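"""Shared test oracles: brute-force numerical integration of the frailty
marginal likelihood, independent of the closed-form implementation."""

import numpy as np
from scipy.integrate import quad

from llfrailty.baseline import (
    LinearPredictor,
    conditional_cumhaz,
    conditional_hazard,
)


def quad_cluster_loglik(times, events, etas, p, theta, mode="aft"):
    """log of the frailty-conditional likelihood integrated numerically
    against the mean-1 gamma density (shape 1/theta, scale theta)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    etas = np.asarray(etas, dtype=float)
    H = np.array(
        [conditional_cumhaz(t, p, LinearPredictor(e, mode)) for t, e in zip(times, etas)]
    )
    logh = sum(
        np.log(conditional_hazard(t, p, LinearPredictor(e, mode)))
        for t, e, ev in zip(times, etas, events)
        if ev
    )
    d = int(events.sum())
    A = float(H.sum())
    shape = 1.0 / theta

    from scipy.stats import gamma as gamma_dist

    def integrand(u):
        return u**d * np.exp(-u * A) * gamma_dist.pdf(u, a=shape, scale=theta)

    val, err = quad(integrand, 0, np.inf, limit=400, epsabs=0.0, epsrel=1e-11)
    assert val > 0 and err < 1e-8 * val
    return float(logh + np.log(val))


def simulated_clusters(seed, G, n_i, theta=0.5, mode="aft"):
    """Clusters drawn exactly from the frailty model (no censoring)."""
    from llfrailty.frailty import ClusterData
    from llfrailty.simulate import sample_event_time

    rng = np.random.default_rng(seed)
    from llfrailty.baseline import LogLogisticParams

    p = LogLogisticParams(0.05, 3.0)
    u = rng.gamma(1.0 / theta, theta, size=G)
    clusters = []
    for i in range(G):
        t = sample_event_time(
            u[i], np.zeros(n_i), p, mode, v=rng.uniform(size=n_i)
        )
        clusters.append(ClusterData(i, t, np.ones(n_i, dtype=int), np.zeros(n_i)))
    return p, theta, clusters, np.full(G, n_i, dtype=float)


def random_small_cluster(rng, p, mode="aft", max_n=6):
    """A random cluster: n <= max_n subjects, random censoring, modest etas."""
    n = int(rng.integers(1, max_n + 1))
    etas = rng.normal(0.0, 0.4, size=n)
    # draw times near the conditional median so hazards are well-scaled
    from llfrailty.simulate import sample_event_time

    u = rng.gamma(2.0, 0.5)
    t = sample_event_time(u, etas, p, mode, v=rng.uniform(0.05, 0.95, size=n))
    t = np.maximum(t, 1e-3)
    events = rng.integers(0, 2, size=n)
    return t, events, etas
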