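"""Central-difference derivatives used for Hessians and as test oracles."""

from __future__ import annotations

import numpy as np

__all__ = ["gradient", "jacobian", "hessian_from_grad", "hessian"]


def gradient(f, x, h: float = 1e-6) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    g = np.empty_like(x)
    for i in range(x.size):
        step = h * max(1.0, abs(x[i]))
        e = np.zeros_like(x)
        e[i] = step
        g[i] = (f(x + e) - f(x - e)) / (2 * step)
    return g


def jacobian(f, x, h: float = 1e-6) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    f0 = np.asarray(f(x), dtype=float)
    J = np.empty((f0.size, x.size))
    for i in range(x.size):
        step = h * max(1.0, abs(x[i]))
        e = np.zeros_like(x)
        e[i] = step
        J[:, i] = (np.asarray(f(x + e)) - np.asarray(f(x - e))) / (2 * step)
    return J


def hessian_from_grad(grad, x, h: float = 1e-5) -> np.ndarray:
    """Hessian as the symmetrised Jacobian of an (analytic) gradient."""
    H = jacobian(grad, x, h=h)
    return 0.5 * (H + H.T)


def hessian(f, x, h: float = 1e-4) -> np.ndarray:
    """Plain central-difference Hessian of a scalar function."""
    x = np.asarray(x, dtype=float)
    n = x.size
    H = np.empty((n, n))
    steps = h * np.maximum(1.0, np.abs(x))
    f0 = f(x)
    for i in range(n):
        ei = np.zeros(n); ei[i] = steps[i]
        H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / steps[i] ** 2
        for j in range(i):
            ej = np.zeros(n); ej[j] = steps[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * steps[i] * steps[j])
    return H
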