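"""Hypergeometric GO-term over-representation with dependency-robust FDR.

For a gene list of size n drawn from a universe of size N, a term annotating
K universe genes and k list genes has upper-tail probability
P(X >= k) for X ~ Hypergeometric(N, K, n).  Because GO terms overlap and are
hierarchically dependent, p-values are adjusted with the Benjamini-Yekutieli
procedure by default (valid under arbitrary dependency); Benjamini-Hochberg
is available as an option.  The annotation map is flat (gene -> set of term
ids): any DAG ancestor propagation must be applied to the map beforehand.
Genes of the universe without annotation still count toward N.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError

_FDR_METHODS = {"BY": "fdr_by", "BH": "fdr_bh"}


def hypergeom_upper(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), exact upper tail.

    ``N`` universe size, ``K`` annotated in universe, ``n`` list size,
    ``k`` annotated in list.
    """
    for name, v in (("N", N), ("K", K), ("n", n), ("k", k)):
        if v < 0 or v != int(v):
            raise ParameterError(f"{name} must be a non-negative integer, got {v}")
    if k > n or n > N or K > N:
        raise ParameterError(
            f"inconsistent counts: need k <= n <= N and K <= N, got "
            f"N={N}, K={K}, n={n}, k={k}"
        )
    if k == 0:
        return 1.0
    # survival function at k-1; scipy computes the tail in log space internally
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    gene_list: Iterable[str],
    universe: Iterable[str],
    go_map: Mapping[str, Iterable[str]],
    fdr: str = "BY",
    min_hits: int = 1,
) -> pd.DataFrame:
    """Test every GO term with >= ``min_hits`` list hits for over-representation.

    Returns a DataFrame sorted by raw p (ties broken by term id) with columns
    term, list_hits, list_size, universe_hits, universe_size, p, p_adjusted
    and ratio = (k/n)/(K/N).  Terms with zero list hits are excluded from the
    FDR family.
    """
    if fdr not in _FDR_METHODS:
        raise ParameterError(f"fdr must be one of {sorted(_FDR_METHODS)}, got {fdr!r}")
    if min_hits < 1:
        raise ParameterError(f"min_hits must be >= 1, got {min_hits}")
    universe = list(dict.fromkeys(universe))
    gene_list = list(dict.fromkeys(gene_list))
    if not universe:
        raise ParameterError("universe is empty")
    if not gene_list:
        raise ParameterError("gene list is empty")
    uset = set(universe)
    outside = [g for g in gene_list if g not in uset]
    if outside:
        raise ParameterError(
            f"gene list contains genes outside the universe: {outside[:5]}"
        )
    N = len(universe)
    n = len(gene_list)
    lset = set(gene_list)
    universe_hits: dict[str, int] = {}
    list_hits: dict[str, int] = {}
    for gene in universe:
        for term in go_map.get(gene, ()):
            universe_hits[term] = universe_hits.get(term, 0) + 1
            if gene in lset:
                list_hits[term] = list_hits.get(term, 0) + 1
    terms = sorted(t for t, k in list_hits.items() if k >= min_hits)
    if not terms:
        return pd.DataFrame(
            columns=[
                "term",
                "list_hits",
                "list_size",
                "universe_hits",
                "universe_size",
                "p",
                "p_adjusted",
                "ratio",
            ]
        )
    k_arr = np.array([list_hits[t] for t in terms])
    K_arr = np.array([universe_hits[t] for t in terms])
    p = np.array(
        [hypergeom_upper(N, K, n, k) for K, k in zip(K_arr, k_arr)], dtype=float
    )
    p_adj = multipletests(p, method=_FDR_METHODS[fdr])[1]
    out = pd.DataFrame(
        {
            "term": terms,
            "list_hits": k_arr,
            "list_size": n,
            "universe_hits": K_arr,
            "universe_size": N,
            "p": p,
            "p_adjusted": np.minimum(p_adj, 1.0),
            "ratio": (k_arr / n) / (K_arr / N),
        }
    )
    out = out.sort_values(["p", "term"], kind="stable").reset_index(drop=True)
    return out
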