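"""Hypergeometric term enrichment and GO secondary-category frequencies.

Enrichment of a differentially-expressed (DE) gene set against a finite
universe uses the upper-tail hypergeometric probability
P(X >= k) with k DE genes annotated to a term, K background genes in the
term, n DE genes and N universe genes. Raw p-values are reported (and
-log10 p for plotting); no ontology propagation is performed — term->gene
maps are taken as given.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import pandas as pd
from scipy import stats

from .errors import ConsistencyError, DataError

_NAMESPACE_ORDER = {"biological_process": 0, "BP": 0,
                    "cellular_component": 1, "CC": 1,
                    "molecular_function": 2, "MF": 2}


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int
    K: int
    n: int
    N: int
    p_value: float
    neg_log10_p: float


def hypergeometric_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail (at-least-k) hypergeometric probability.

    p = sum_{i=k}^{min(K,n)} C(K,i) C(N-K, n-i) / C(N,n)
    """
    if not (0 <= k <= min(K, n) and k <= K <= N and 0 <= n <= N):
        raise ValueError(
            f"hypergeometric bounds violated: k={k}, K={K}, n={n}, N={N}"
        )
    # sf(k-1) = P(X >= k)
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich_terms(
    de_genes: set[str],
    background: set[str],
    term_map: Mapping[str, set[str]],
    term_names: Mapping[str, str] | None = None,
    min_term_size: int = 0,
) -> list[EnrichmentResult]:
    """One hypergeometric result per term overlapping the DE set, sorted by p.

    Term gene sets are intersected with the background before counting; ties
    in p are broken by term id.
    """
    offenders = sorted(de_genes - background)
    if offenders:
        raise ConsistencyError(
            f"DE genes absent from the background universe: {offenders}"
        )
    N = len(background)
    n = len(de_genes)
    results = []
    for term_id, genes in term_map.items():
        in_bg = genes & background
        K = len(in_bg)
        if K < min_term_size or K == 0:
            continue
        k = len(in_bg & de_genes)
        if k == 0:
            continue
        p = hypergeometric_tail(k, K, n, N)
        results.append(
            EnrichmentResult(
                term_id=term_id,
                term_name=(term_names or {}).get(term_id, term_id),
                k=k, K=K, n=n, N=N,
                p_value=p,
                neg_log10_p=-math.log10(p) if p > 0 else math.inf,
            )
        )
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def top_terms(results, limit: int = 10) -> list[EnrichmentResult]:
    """The ``limit`` most enriched terms (input is already p-sorted)."""
    return list(results)[:limit]


def secondary_id_frequency(
    de_genes: set[str],
    background: set[str],
    category_map: Mapping[str, set[str]],
    namespace_of: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-category DE vs background annotation fractions (GO level-2 bars).

    Rows are ordered by GO namespace (biological process, cellular component,
    molecular function — resolved through ``namespace_of`` or a
    ``"NS:name"`` category-id prefix) and then by category name.
    """
    if not de_genes:
        raise DataError("empty DE gene set: nothing to profile")
    offenders = sorted(de_genes - background)
    if offenders:
        raise ConsistencyError(
            f"DE genes absent from the background universe: {offenders}"
        )

    def ns_rank(cat: str) -> int:
        ns = (namespace_of or {}).get(cat)
        if ns is None and ":" in cat:
            ns = cat.split(":", 1)[0]
        return _NAMESPACE_ORDER.get(ns, 3)

    rows = []
    for cat in sorted(category_map, key=lambda c: (ns_rank(c), c)):
        genes = category_map[cat] & background
        de_count = len(genes & de_genes)
        bg_count = len(genes)
        rows.append(
            (
                cat,
                de_count / len(de_genes),
                bg_count / len(background),
                de_count,
                bg_count,
            )
        )
    return pd.DataFrame(
        rows, columns=["category", "de_fraction", "bg_fraction", "de_count", "bg_count"]
    )


def results_to_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.term_id, r.term_name, r.k, r.K, r.n, r.N, r.p_value, r.neg_log10_p)
            for r in results
        ],
        columns=["term_id", "term_name", "k", "K", "n", "N", "p_value", "neg_log10_p"],
    )
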