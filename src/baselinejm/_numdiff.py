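"""Central-difference derivatives for observed-information matrices."""

from __future__ import annotations

import numpy as np


def numeric_hessian(f, x, rel_step: float = 1e-4) -> np.ndarray:
    """Symmetric central-difference Hessian of a scalar function.

    Steps scale with |x_i| (floor at ``rel_step``); cost is 2p^2 + O(p)
    function evaluations for p parameters.
    """
    x = np.asarray(x, dtype=float)
    p = x.size
    h = rel_step * np.maximum(np.abs(x), 1.0)
    H = np.empty((p, p))
    f0 = f(x)
    # diagonal
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
    # off-diagonal
    for i in range(p):
        for j in range(i):
            ei = np.zeros(p)
            ej = np.zeros(p)
            ei[i] = h[i]
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H
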