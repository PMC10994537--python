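"""Independent brute-force oracles shared across test modules."""

import itertools

import numpy as np


def brute_force_nnls(A, y):
    """Exhaustive-support NNLS oracle: unconstrained least squares on every
    support subset, keeping the best feasible (non-negative) solution. Valid
    because the NNLS optimum satisfies the normal equations restricted to its
    own support."""
    n = A.shape[1]
    best_w, best_r = np.zeros(n), np.linalg.norm(y)
    for k in range(1, n + 1):
        for support in itertools.combinations(range(n), k):
            sub = A[:, support]
            w_sub, *_ = np.linalg.lstsq(sub, y, rcond=None)
            if np.any(w_sub < -1e-12):
                continue
            w = np.zeros(n)
            w[list(support)] = np.clip(w_sub, 0, None)
            r = np.linalg.norm(y - A @ w)
            if r < best_r - 1e-15:
                best_w, best_r = w, r
    return best_w, best_r
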