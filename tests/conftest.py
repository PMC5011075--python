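"""Shared fixtures and independent brute-force oracles.

The oracles here intentionally avoid the code paths they check: plain
normal-equations linear algebra, double loops, and literal formula
transcriptions.
"""

from __future__ import annotations

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)


def ols_oracle(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normal-equations OLS: coefficients and standard errors."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(XtX)))
    return beta, se


def ivw_oracle(betas, ses) -> tuple[float, float]:
    """Weighted-mean fixed-effects combination, written out longhand."""
    num = 0.0
    den = 0.0
    for b, s in zip(betas, ses):
        w = 1.0 / (s * s)
        num += w * b
        den += w
    return num / den, (1.0 / den) ** 0.5


def cochran_q_oracle(betas, ses) -> float:
    bhat, _ = ivw_oracle(betas, ses)
    q = 0.0
    for b, s in zip(betas, ses):
        q += (b - bhat) ** 2 / (s * s)
    return q


def overlap_oracle(positions, intervals) -> np.ndarray:
    """Literal per-variant, per-interval scan (1-based pos, 0-based half-open)."""
    out = np.zeros(len(positions), dtype=int)
    for i, p in enumerate(positions):
        for iv in intervals:
            start, end = iv[-2], iv[-1]
            if start <= p - 1 < end:
                out[i] = 1
                break
    return out
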