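"""Exact-test primitives shared across the pipeline.

The central statistic is a two-tailed hypergeometric test built by the
minimum-likelihood construction: the two-sided P-value of an observed
overlap ``k`` is the total probability of every outcome that is no more
probable than ``k`` itself. This is the same convention scipy uses for
``fisher_exact(alternative="two-sided")``, exposed here directly on
hypergeometric parameters so that marker-panel scoring and gene-set
enrichment share one engine.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as _st

# relative slack when comparing point probabilities: outcomes whose pmf is
# equal to pmf(k) up to floating-point noise belong in the tail sum
_REL_TOL = 1e-12

P_FLOOR = 1e-300


def hypergeom_support(N: int, K: int, n: int) -> np.ndarray:
    """All achievable overlap counts for a draw of ``n`` from ``N`` with ``K`` successes."""
    lo = max(0, n - (N - K))
    hi = min(n, K)
    return np.arange(lo, hi + 1)


def hypergeom_two_tailed(k: int, N: int, K: int, n: int) -> float:
    """Two-tailed hypergeometric P-value by the minimum-likelihood method.

    Parameters
    ----------
    k : observed number of successes in the draw.
    N : population size.
    K : number of successes in the population.
    n : draw size.

    Returns
    -------
    float
        P = sum of pmf(x) over all achievable x with pmf(x) <= pmf(k),
        clipped to [0, 1].
    """
    if not (0 <= K <= N):
        raise ValueError(f"require 0 <= K <= N, got K={K}, N={N}")
    if not (0 <= n <= N):
        raise ValueError(f"require 0 <= n <= N, got n={n}, N={N}")
    xs = hypergeom_support(N, K, n)
    if k < xs[0] or k > xs[-1]:
        raise ValueError(f"k={k} outside support [{xs[0]}, {xs[-1]}]")
    pmf = _st.hypergeom.pmf(xs, N, K, n)
    pk = pmf[k - xs[0]]
    p = float(pmf[pmf <= pk * (1.0 + _REL_TOL)].sum())
    return min(p, 1.0)


def signed_log10_hypergeom(k: int, N: int, K: int, n: int,
                           floor: float = P_FLOOR) -> float:
    """Signed -log10 of the two-tailed hypergeometric P-value.

    The sign is the sign of the deviation of ``k`` from its expectation
    ``n*K/N``: positive when the draw is enriched for successes, negative
    when depleted, zero exactly at expectation. The P-value is floored to
    keep the logarithm finite.
    """
    if n == 0:
        return 0.0
    p = max(hypergeom_two_tailed(k, N, K, n), floor)
    dev = k - n * K / N
    return float(np.sign(dev) * (-np.log10(p)))


def fisher_one_sided_greater(a: int, b: int, c: int, d: int) -> float:
    """One-sided Fisher exact P for the 2x2 table [[a, b], [c, d]].

    Tests whether the first row is enriched for the first column
    (alternative: odds ratio > 1).
    """
    table = np.array([[a, b], [c, d]])
    if (table < 0).any():
        raise ValueError("2x2 table entries must be non-negative")
    return float(_st.fisher_exact(table, alternative="greater")[1])


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values (vector, same order as input)."""
    from statsmodels.stats.multitest import multipletests
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
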