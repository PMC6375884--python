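"""Shared exact-test and multiple-testing primitives.

These are the statistical building blocks used by the expression screen and
the methylome window tests: Benjamini-Hochberg step-up FDR control and a
two-sided Fisher exact test on 2x2 contingency tables.  Both are implemented
directly (summation of hypergeometric point probabilities; the step-up
recursion) so they can be verified against brute-force enumeration.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

# Relative tolerance for "probability <= observed" ties in two-sided exact
# tests; point probabilities equal up to floating error count as ties.
REL_TIE = 1.0 + 1e-7


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * n / j for sorted p-values, clipped at 1,
    returned in the input order.  NaNs and values outside [0, 1] are rejected.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("p-values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValueError("NaN p-values are not allowed")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(n, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _validate_table(table) -> tuple[int, int, int, int]:
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(t < 0):
        raise ValueError("table entries must be non-negative")
    flat = t.ravel()
    if not np.allclose(flat, np.round(flat)):
        raise ValueError("table entries must be integers")
    a, b, c, d = (int(round(x)) for x in flat)
    return a, b, c, d


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table of non-negative counts.

    The p-value is the sum of hypergeometric point probabilities (over all
    tables with the observed margins) that do not exceed the probability of
    the observed table.  A zero row or column margin makes the table
    untestable and returns p = 1.
    """
    a, b, c, d = _validate_table(table)
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c2 == 0:
        return 1.0
    kmin = max(0, r1 + c1 - n)
    kmax = min(r1, c1)
    k = np.arange(kmin, kmax + 1)
    # P(a = k) = C(c1, k) C(c2, r1 - k) / C(n, r1)
    logp = (
        _log_comb(c1, k)
        + _log_comb(c2, r1 - k)
        - _log_comb(n, r1)
    )
    pmf = np.exp(logp - logp.max())
    pmf /= pmf.sum()
    obs = pmf[a - kmin]
    return float(min(1.0, pmf[pmf <= obs * REL_TIE].sum()))


def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
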