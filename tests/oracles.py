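"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plain double loops straight from the
definitions, deliberately sharing no code with the package.
"""

from __future__ import annotations

import math

import numpy as np


def sampen_bruteforce(x, m: int, r: float) -> float:
    """Sample entropy by direct template-pair counting (Chebyshev distance).

    Counts pairs i < j over the first n - m template start indices at
    lengths m and m + 1; returns -ln(A/B), +inf when A or B is zero.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    n_templates = n - m
    b = a = 0
    for i in range(n_templates):
        for j in range(i + 1, n_templates):
            d_m = max(abs(x[i + k] - x[j + k]) for k in range(m))
            if d_m <= r:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    if a == 0 or b == 0:
        return math.inf
    return -math.log(a / b)


def recurrence_rate_bruteforce(x, m: int, tau: int, eps: float, theiler: int) -> float:
    """Recurrence rate by O(N^2) Euclidean pair scanning of the embedding."""
    x = np.asarray(x, dtype=float)
    n_e = len(x) - (m - 1) * tau
    total = rec = 0
    for i in range(n_e):
        for j in range(i + 1, n_e):
            if j - i <= theiler:
                continue
            total += 1
            d2 = 0.0
            for k in range(m):
                diff = x[i + k * tau] - x[j + k * tau]
                d2 += diff * diff
            if math.sqrt(d2) <= eps:
                rec += 1
    return rec / total if total else 0.0


def lz76_bruteforce(bits) -> int:
    """LZ76 complete-phrase count via explicit start-position scanning.

    Reproducibility of block s[p:p+l] is checked by trying every copy
    start q <= p - 1 with overlap allowed; the trailing block that is
    still reproducible when the sequence ends is not counted.
    """
    s = [int(bool(b)) for b in bits]
    n = len(s)

    def reproducible(p: int, l: int) -> bool:
        # can s[p:p+l] be copied symbol-by-symbol starting from some q < p
        # (overlap with the block itself allowed)?
        for q in range(p):
            if all(s[q + t] == s[p + t] for t in range(l)):
                return True
        return False

    c = 0
    p = 0
    while p < n:
        l = 1
        while p + l <= n and reproducible(p, l):
            l += 1
        if p + l <= n:
            c += 1
        p += l
    return max(c, 1)


def katz_bruteforce(x) -> float:
    """Katz dimension from the definition, per-point loops."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    length = 0.0
    for i in range(1, n):
        length += math.sqrt(1.0 + (x[i] - x[i - 1]) ** 2)
    d = 0.0
    for i in range(1, n):
        d = max(d, math.sqrt(i**2 + (x[i] - x[0]) ** 2))
    return math.log10(length) / math.log10(d)


def logistic_lyapunov_oracle(orbit, r: float) -> float:
    """lambda of the logistic map as the orbit mean of log|f'(x)| = log|r - 2rx|."""
    x = np.asarray(orbit, dtype=float)
    deriv = np.abs(r - 2.0 * r * x)
    deriv = deriv[deriv > 0]
    return float(np.mean(np.log(deriv)))


def fisher_bruteforce(w, m0, m1) -> float:
    """Direct evaluation of the Fisher separability ratio."""
    y0 = np.asarray(m0) @ np.asarray(w)
    y1 = np.asarray(m1) @ np.asarray(w)
    denom = float(np.var(y0) + np.var(y1))
    if denom <= 0:
        return 0.0
    return float((y1.mean() - y0.mean()) ** 2) / denom


def cca_eig_oracle(x, y, ridge: float = 1e-9) -> float:
    """First canonical correlation via the eigenvalue route
    (eig of Sxx^-1 Sxy Syy^-1 Syx), independent of the SVD formulation."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape[0] == 1:
        x = x.T
    if y.shape[0] == 1:
        y = y.T
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    n = x.shape[0]
    sxx = xc.T @ xc / (n - 1) + ridge * np.eye(x.shape[1])
    syy = yc.T @ yc / (n - 1) + ridge * np.eye(y.shape[1])
    sxy = xc.T @ yc / (n - 1)
    m = np.linalg.solve(sxx, sxy) @ np.linalg.solve(syy, sxy.T)
    eigvals = np.linalg.eigvals(m)
    lam = float(np.max(eigvals.real))
    return math.sqrt(max(lam, 0.0))
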