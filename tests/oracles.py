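"""Independent brute-force oracles used by the test suite.

The dip oracle minimizes, over piecewise-linear unimodal CDFs with knots
at the distinct sample values (and an optional jump at the mode, which
the unimodal class permits), the sup-norm distance to the empirical CDF.
It solves one small linear program per candidate mode knot and is
completely independent of the package's hull-based computation.
"""

import numpy as np
from scipy.optimize import linprog


def dip_bruteforce(sample) -> float:
    xs = np.sort(np.asarray(sample, dtype=float))
    n = len(xs)
    x, counts = np.unique(xs, return_counts=True)
    cum = np.cumsum(counts) / n          # F(x_k)
    clo = cum - counts / n               # F(x_k^-)
    m = len(x)
    if m == 1:
        return 0.0
    dx = np.diff(x)
    best = np.inf
    for k in range(m):
        # variables: G_0..G_{m-1} (right-continuous values at the knots),
        # Gm (left limit at the mode knot), d
        nv = m + 2
        iGm, id_ = m, m + 1
        c = np.zeros(nv)
        c[id_] = 1.0
        A, b = [], []

        def row():
            return np.zeros(nv)

        for j in range(m):
            if j == k:
                continue
            r = row(); r[j] = 1.0; r[id_] = -1.0; A.append(r); b.append(clo[j])
            r = row(); r[j] = -1.0; r[id_] = -1.0; A.append(r); b.append(-cum[j])
        # mode knot: left limit vs F(x_k^-), value vs F(x_k)
        r = row(); r[iGm] = 1.0; r[id_] = -1.0; A.append(r); b.append(clo[k])
        r = row(); r[iGm] = -1.0; r[id_] = -1.0; A.append(r); b.append(-clo[k])
        r = row(); r[k] = 1.0; r[id_] = -1.0; A.append(r); b.append(cum[k])
        r = row(); r[k] = -1.0; r[id_] = -1.0; A.append(r); b.append(-cum[k])
        # monotone, with the jump Gm <= G_k at the mode
        for j in range(m - 1):
            r = row(); r[j] = 1.0; r[j + 1 if j + 1 != k else iGm] = -1.0
            A.append(r); b.append(0.0)
        r = row(); r[iGm] = 1.0; r[k] = -1.0; A.append(r); b.append(0.0)

        def val(j):
            return iGm if j == k else j

        # slopes nondecreasing left of the mode
        for j in range(1, k):
            r = row()
            r[val(j - 1)] += -1.0 / dx[j - 1]
            r[val(j)] += 1.0 / dx[j - 1] + 1.0 / dx[j]
            r[val(j + 1)] += -1.0 / dx[j]
            A.append(r); b.append(0.0)
        # slopes nonincreasing right of the mode
        for j in range(k + 1, m - 1):
            r = row()
            r[j - 1] += 1.0 / dx[j - 1]
            r[j] += -1.0 / dx[j - 1] - 1.0 / dx[j]
            r[j + 1] += 1.0 / dx[j]
            A.append(r); b.append(0.0)
        res = linprog(c, A_ub=np.array(A), b_ub=np.array(b),
                      bounds=[(0.0, 1.0)] * (m + 1) + [(0.0, 1.0)],
                      method="highs")
        assert res.success, res.message
        best = min(best, res.fun)
    return float(best)


def relative_effect_enumeration(x, y) -> float:
    """P(X < Y) + 0.5 P(X = Y) by direct pair enumeration."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    wins = sum(1.0 if xi < yj else (0.5 if xi == yj else 0.0)
               for xi in x for yj in y)
    return wins / (len(x) * len(y))
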