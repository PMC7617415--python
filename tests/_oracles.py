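"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the Fisher oracle uses
exact rational arithmetic over an explicit enumeration of tables, and the
logistic oracle is a direct iteratively-reweighted-least-squares solver.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Minimum-likelihood two-sided Fisher p by exact rational enumeration."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    denom = comb(n, c1)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    probs = {k: Fraction(comb(r1, k) * comb(n - r1, c1 - k), denom) for k in range(lo, hi + 1)}
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs)


def irls_logistic(X: np.ndarray, y: np.ndarray, tol: float = 1e-12, max_iter: int = 200):
    """Logistic MLE via Newton/IRLS; returns (beta, standard errors)."""
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1.0 - mu)
        z = eta + (y - mu) / W
        XtW = X.T * W
        beta_new = np.linalg.solve(XtW @ X, XtW @ z)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
    W = mu * (1.0 - mu)
    cov = np.linalg.inv((X.T * W) @ X)
    return beta, np.sqrt(np.diag(cov))
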