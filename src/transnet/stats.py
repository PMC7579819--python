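"""Over-representation (hypergeometric) enrichment and FDR adjustment.

The enrichment p-value is the exact upper tail of the hypergeometric
distribution: with N background genes, M of them annotated to a term, a
query list of n genes of which k are annotated,

    p = 1 - sum_{i=0}^{k-1} C(N-M, n-i) C(M, i) / C(N, n)
      = sum_{i=k}^{min(n,M)} C(M, i) C(N-M, n-i) / C(N, n).

The second form is what is computed (term-by-term in log space via gammaln),
avoiding the cancellation of 1 - cdf while remaining the identical exact
quantity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

__all__ = ["hypergeom_upper_tail", "hypergeom_enrichment", "bh_adjust"]


def _log_binom(a: float, b: float) -> float:
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def hypergeom_upper_tail(N: int, M: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, M, n), exact, stable in log space."""
    if not (0 <= M <= N and 0 <= n <= N):
        raise ValueError("require 0 <= M <= N and 0 <= n <= N")
    if not (max(0, n + M - N) <= k <= min(n, M) + 1):
        # k may exceed the support's max by convention only when p = 0
        if k > min(n, M):
            return 0.0
        raise ValueError("k outside the hypergeometric support")
    if k <= max(0, n + M - N):
        return 1.0
    denom = _log_binom(N, n)
    terms = [
        _log_binom(M, i) + _log_binom(N - M, n - i) - denom
        for i in range(k, min(n, M) + 1)
    ]
    if not terms:
        return 0.0
    m = max(terms)
    p = float(np.exp(m) * np.sum(np.exp(np.array(terms) - m)))
    return min(p, 1.0)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving,
    clipped at 1, running-minimum monotone)."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_enrichment(
    query: set[str],
    term_sets: dict[str, set[str]],
    background: set[str],
) -> pd.DataFrame:
    """Per-term over-representation test with BH adjustment across terms.

    Term gene sets are intersected with the background before counting; the
    query must be a subset of the background. Returns a DataFrame with
    columns term, N, M, n, k, p, q sorted by p (ties by term id).
    """
    if not query or not background:
        raise ValueError("query and background must be nonempty")
    query = set(query)
    background = set(background)
    if not query <= background:
        raise ValueError("query must be a subset of the background")
    N, n = len(background), len(query)
    rows = []
    for term in sorted(term_sets):
        annotated = term_sets[term] & background
        M = len(annotated)
        k = len(annotated & query)
        p = hypergeom_upper_tail(N, M, n, k) if k > 0 else 1.0
        rows.append({"term": term, "N": N, "M": M, "n": n, "k": k, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values(["p", "term"]).reset_index(drop=True)
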