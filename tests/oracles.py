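"""Independent reference computations used by several test modules."""

import numpy as np
from scipy.optimize import minimize


def qp_dual_optimum(X, y, C, q):
    """Dense QP oracle for the polynomial-kernel SVM dual (SLSQP, 3 starts)."""
    K = (X @ X.T + 1.0) ** q
    n = len(y)
    Q = (y[:, None] * y[None, :]) * K
    cons = [{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}]
    best = None
    for trial in range(3):
        a0 = (np.full(n, min(C, 1.0) * 0.5) if trial == 0
              else np.random.default_rng(trial).uniform(0, C, n))
        a0 = np.clip(a0 - y * (a0 @ y) / n, 0, C)
        r = minimize(lambda a: -(a.sum() - 0.5 * a @ Q @ a), a0,
                     jac=lambda a: -(np.ones(n) - Q @ a),
                     bounds=[(0, C)] * n, constraints=cons, method="SLSQP",
                     options={"maxiter": 500, "ftol": 1e-12})
        if best is None or r.fun < best.fun:
            best = r
    return -best.fun


def full_alphas(model, X):
    """Scatter a model's support multipliers back onto the training rows."""
    a = np.zeros(len(X))
    for sv, al in zip(model.support_vectors, model.alphas):
        a[np.argmin(np.abs(X - sv).sum(axis=1))] += al
    return a
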