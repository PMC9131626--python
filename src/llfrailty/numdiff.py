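"""Central finite-difference derivatives for standard-error computation."""

from __future__ import annotations

import numpy as np

__all__ = ["numeric_gradient", "numeric_hessian"]


def _steps(x: np.ndarray, rel_step: float) -> np.ndarray:
    return rel_step * np.maximum(1.0, np.abs(x))


def numeric_gradient(f, x, rel_step: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of a scalar function."""
    x = np.asarray(x, dtype=float)
    h = _steps(x, rel_step)
    g = np.empty_like(x)
    for i in range(x.size):
        e = np.zeros_like(x)
        e[i] = h[i]
        g[i] = (f(x + e) - f(x - e)) / (2.0 * h[i])
    return g


def numeric_hessian(f, x, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of a scalar function.

    Exact (to round-off) on quadratics.  ``rel_step`` trades truncation
    against round-off; 1e-4 suits log-likelihoods of magnitude ~1e4.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    h = _steps(x, rel_step)
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = h[i]
        fpp = f(x + 2 * ei)
        fmm = f(x - 2 * ei)
        H[i, i] = (fpp - 2.0 * f0 + fmm) / (4.0 * h[i] ** 2)
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = h[j]
            fab = f(x + ei + ej)
            fa_b = f(x + ei - ej)
            f_ab = f(x - ei + ej)
            f_a_b = f(x - ei - ej)
            H[i, j] = H[j, i] = (fab - fa_b - f_ab + f_a_b) / (
                4.0 * h[i] * h[j]
            )
    return H
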