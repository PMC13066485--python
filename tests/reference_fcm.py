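"""Independent loop-based fuzzy C-means oracle for cross-checking.

Deliberately naive: per-element Python loops, center initialization by
sampling data points (a different scheme from the package's random-membership
initialization), and its own convergence loop.  Shares no code with
``assaydiff.fcm``.
"""

import math

import numpy as np


def _objective(X, centers, u, m):
    total = 0.0
    for i in range(len(X)):
        for j in range(len(centers)):
            d2 = sum((X[i][k] - centers[j][k]) ** 2 for k in range(len(X[i])))
            total += (u[i][j] ** m) * d2
    return total


def _update_memberships(X, centers, m):
    D, N = len(X), len(centers)
    u = [[0.0] * N for _ in range(D)]
    for i in range(D):
        d = [
            math.sqrt(sum((X[i][k] - centers[j][k]) ** 2
                          for k in range(len(X[i]))))
            for j in range(N)
        ]
        if any(dj == 0.0 for dj in d):
            hits = [j for j in range(N) if d[j] == 0.0]
            for j in hits:
                u[i][j] = 1.0 / len(hits)
            continue
        for j in range(N):
            u[i][j] = 1.0 / sum(
                (d[j] / d[k]) ** (2.0 / (m - 1.0)) for k in range(N)
            )
    return u


def _update_centers(X, u, m, N):
    d = len(X[0])
    centers = [[0.0] * d for _ in range(N)]
    for j in range(N):
        wsum = sum(u[i][j] ** m for i in range(len(X)))
        for k in range(d):
            centers[j][k] = sum(
                (u[i][j] ** m) * X[i][k] for i in range(len(X))
            ) / wsum
    return centers


def reference_fcm_best_objective(X, n_clusters, m=2.0, seed=99,
                                 n_restarts=20, tol=1e-10, max_iter=500):
    """Best final objective over restarts initialized from random data points."""
    X = [list(map(float, row)) for row in np.atleast_2d(X)]
    rng = np.random.default_rng(seed)
    best = math.inf
    for _ in range(n_restarts):
        idx = rng.choice(len(X), size=n_clusters, replace=False)
        centers = [list(X[i]) for i in idx]
        prev = math.inf
        for _ in range(max_iter):
            u = _update_memberships(X, centers, m)
            centers = _update_centers(X, u, m, n_clusters)
            u = _update_memberships(X, centers, m)
            obj = _objective(X, centers, u, m)
            if abs(prev - obj) < tol:
                break
            prev = obj
        best = min(best, obj)
    return best
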