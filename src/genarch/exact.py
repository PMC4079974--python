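"""Two-sided Fisher's exact test for 2x2 tables, computed in log space.

The two-sided p-value is the sum of the probabilities of all tables with
the observed margins whose hypergeometric probability does not exceed the
observed table's (the usual "probability-based" two-sided rule). Working
with log-probabilities keeps the test exact far into the tail (p ~ 1e-81
on the panel-scale tables this package produces), where a naive product
of factorials underflows.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp
from scipy.stats import hypergeom

_REL_EPS = 1e-7


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 count table.

    Parameters
    ----------
    table : array-like, shape (2, 2)
        Nonnegative integer counts ``[[a, b], [c, d]]``.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.all(np.equal(np.mod(t, 1), 0)):
        raise ValueError("counts must be nonnegative integers")
    a, b, c, d = (int(x) for x in t.ravel())
    n = a + b + c + d
    if n == 0:
        return 1.0
    r1, c1 = a + b, a + c
    k_min = max(0, c1 - (c + d))
    k_max = min(r1, c1)
    ks = np.arange(k_min, k_max + 1)
    logp = hypergeom.logpmf(ks, n, r1, c1)
    log_obs = hypergeom.logpmf(a, n, r1, c1)
    mask = logp <= log_obs + _REL_EPS
    p = float(np.exp(logsumexp(logp[mask])))
    return min(p, 1.0)


def log10_fisher_exact_2x2(table) -> float:
    """log10 of the two-sided p (useful when p underflows to 0)."""
    t = np.asarray(table)
    a, b, c, d = (int(x) for x in t.ravel())
    n = a + b + c + d
    if n == 0:
        return 0.0
    r1, c1 = a + b, a + c
    ks = np.arange(max(0, c1 - (c + d)), min(r1, c1) + 1)
    logp = hypergeom.logpmf(ks, n, r1, c1)
    log_obs = hypergeom.logpmf(a, n, r1, c1)
    mask = logp <= log_obs + _REL_EPS
    return float(logsumexp(logp[mask]) / np.log(10.0))
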