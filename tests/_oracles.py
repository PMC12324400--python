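"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: the step-fit
oracle enumerates every breakpoint and computes SSEs directly, the AUC
oracle counts concordant pairs exhaustively, and the Welch oracle
evaluates the closed-form statistic from first principles.
"""

import math

import numpy as np


def step_oracle(values):
    """(k, left_mean, right_mean, sse) by exhaustive breakpoint search."""
    x = [float(v) for v in values]
    n = len(x)
    best = None
    for k in range(1, n):
        left, right = x[:k], x[k:]
        lm = sum(left) / k
        rm = sum(right) / (n - k)
        sse = sum((v - lm) ** 2 for v in left) + sum((v - rm) ** 2 for v in right)
        if best is None or sse < best[3] - 1e-12:
            best = (k, lm, rm, sse)
    return best


def fstat_oracle(values, m=3):
    """Direct evaluation of the step-regression F statistic.

    Uses the oracle fit; returns None for a perfect (zero-residual) fit.
    """
    x = [float(v) for v in values]
    n = len(x)
    k, lm, rm, _ = step_oracle(x)
    fitted = [lm] * k + [rm] * (n - k)
    xbar = sum(x) / n
    num = sum((f - xbar) ** 2 for f in fitted) / (m - 1)
    den = sum((v - f) ** 2 for v, f in zip(x, fitted))
    if den == 0:
        return None
    return num / (den / (n - m))


def auc_oracle(pos, neg):
    """Concordant-pair AUC with ties counted 1/2."""
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def welch_oracle(a, b):
    """Closed-form Welch t, Welch-Satterthwaite df, two-sided p."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * tdist.sf(abs(t), df)
    return t, df, p
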