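"""Shared brute-force reference implementations for acceptance checks.

Deliberately naive (explicit loops, enumeration) and independent of the
package's optimized code paths.
"""

import itertools

import numpy as np
from scipy import stats


def lz76_oracle(bits) -> int:
    s = "".join(str(int(b)) for b in bits)
    n = len(s)
    phrases = 0
    pos = 0
    while pos < n:
        length = 1
        while pos + length <= n and s[pos : pos + length] in s[: pos + length - 1]:
            length += 1
        phrases += 1
        pos += length
    return phrases


def sampen_oracle(x, m, r) -> float:
    n = len(x)
    t = n - m
    a = b = 0
    for i in range(t):
        for j in range(i + 1, t):
            if max(abs(x[i + o] - x[j + o]) for o in range(m)) <= r:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    return -np.log(a / b)


def ctm_oracle(x, radius) -> float:
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd > 0:
        x = x / sd
    pts = [(x[i + 1] - x[i], x[i + 2] - x[i + 1]) for i in range(len(x) - 2)]
    return sum(1 for u, v in pts if np.hypot(u, v) < radius) / len(pts)


def rank_regression_oracle(x, y, covariates) -> float:
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rc = np.column_stack(
        [np.ones(len(x))] + [stats.rankdata(c) for c in np.atleast_2d(covariates.T)]
    )
    bx = np.linalg.solve(rc.T @ rc, rc.T @ rx)
    by = np.linalg.solve(rc.T @ rc, rc.T @ ry)
    ex, ey = rx - rc @ bx, ry - rc @ by
    return float(np.corrcoef(ex, ey)[0, 1])


def enumeration_wilcoxon_p(d, alternative) -> float:
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ge = le = 0
    for signs in itertools.product([0, 1], repeat=d.size):
        w = sum(r for s, r in zip(signs, ranks) if s)
        ge += w >= w_obs - 1e-9
        le += w <= w_obs + 1e-9
    total = 2**d.size
    if alternative == "greater":
        return ge / total
    if alternative == "less":
        return le / total
    return min(1.0, 2 * min(ge, le) / total)
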