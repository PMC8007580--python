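"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written naively (explicit loops, no shared code with the
package) so it can serve as a trustworthy reference on tiny inputs.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def brute_force_relieff(
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    queries,
    ordinal: bool,
) -> np.ndarray:
    """Naive (O)ReliefF: explicit loops over queries, classes and attributes."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    N, S = X.shape
    L = int(y.max()) + 1
    priors = [float(np.sum(y == l)) / N for l in range(L)]
    Q = np.zeros(S)
    for i in queries:
        i = int(i)
        # Manhattan distances; ties broken by lower index via sort key
        others = [(sum(abs(X[i][a] - X[j][a]) for a in range(S)), j) for j in range(N) if j != i]
        others.sort()
        hits = [j for _, j in others if y[j] == y[i]][:k]
        if hits:
            for a in range(S):
                Q[a] -= sum(abs(X[i][a] - X[j][a]) for j in hits) / len(hits)
        for l in range(L):
            if l == y[i]:
                continue
            misses = [j for _, j in others if y[j] == l][:k]
            if not misses:
                continue
            w = priors[l] / (1.0 - priors[y[i]])
            if ordinal:
                denom = sum(abs(y[i] - lp) for lp in range(L) if lp != y[i])
                w *= abs(y[i] - l) / denom
            for a in range(S):
                Q[a] += w * sum(abs(X[i][a] - X[j][a]) for j in misses) / len(misses)
    return Q


def independent_threshold_fit(
    X: np.ndarray, y: np.ndarray, L: int, lam: float
) -> tuple[np.ndarray, np.ndarray]:
    """Minimise the immediate-threshold objective with a separately written
    loss (loops) and a derivative-free optimiser; returns (weights, thresholds)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    S = X.shape[1]

    def loss(theta):
        w, b = theta[:S], theta[S:]
        total = lam * float(np.sum(w * w))
        for i in range(X.shape[0]):
            f = float(np.dot(X[i], w))
            if y[i] >= 1:
                total += float(np.logaddexp(0.0, -(f - b[y[i] - 1])))
            if y[i] <= L - 2:
                total += float(np.logaddexp(0.0, -(b[y[i]] - f)))
        return total

    theta0 = np.concatenate([np.zeros(S), np.linspace(-1, 1, L - 1)])
    res = minimize(loss, theta0, method="Nelder-Mead",
                   options={"maxiter": 20000, "xatol": 1e-8, "fatol": 1e-10})
    return res.x[:S], np.sort(res.x[S:])


def predict_thresholds(X, w, b) -> np.ndarray:
    f = np.asarray(X, dtype=float) @ np.asarray(w, dtype=float)
    return (f[:, None] > np.asarray(b)[None, :]).sum(axis=1)
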