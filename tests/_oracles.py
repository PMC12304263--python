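"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the production code paths: dense linear algebra for
the AsLS baseline, an O(n²) feasibility search for the lower convex hull, and
an O(n²) pairwise count for the rank AUC.
"""

import numpy as np


def asls_dense(y, lam=1000.0, p=0.05, max_iter=10):
    """AsLS baseline via a dense direct solve of the same iteration."""
    y = np.asarray(y, dtype=float)
    n = y.size
    D = np.diff(np.eye(n), 2, axis=0)  # (n-2, n) second-difference operator
    P = lam * (D.T @ D)
    w = np.ones(n)
    for _ in range(max_iter):
        z = np.linalg.solve(np.diag(w) + P, w * y)
        w_new = np.where(y > z, p, 1.0 - p)
        if np.array_equal(w_new, w):
            break
        w = w_new
    return z


def lower_hull_brute(x, y):
    """Lower-hull vertex indices: k is a vertex iff no chord (i<k<j) lies below it."""
    n = len(x)
    verts = []
    for k in range(n):
        on_hull = True
        for i in range(k):
            for j in range(k + 1, n):
                line = y[i] + (y[j] - y[i]) * (x[k] - x[i]) / (x[j] - x[i])
                if line < y[k]:
                    on_hull = False
                    break
            if not on_hull:
                break
        if on_hull:
            verts.append(k)
    return verts


def rubberband_brute(y, grid):
    """Baseline from the brute-force hull, same interpolation as production."""
    idx = lower_hull_brute(grid, y)
    return np.interp(grid, grid[idx], y[idx])


def auc_pairwise(scores, y, positive="cancer"):
    """AUC as the average over all positive–negative pairs, ties count ½."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    pos = scores[y == positive]
    neg = scores[y != positive]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))
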