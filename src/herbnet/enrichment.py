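"""Hypergeometric over-representation analysis with BH control and
kappa-based term grouping.

For a query set of n targets drawn from a universe of N, a term with K
members and k overlapping query members is scored with the upper tail
P(X >= k), X ~ Hypergeometric(N, K, n) — over-representation only, never
depletion. Raw p-values are Benjamini-Hochberg adjusted across the tested
terms (those with k >= 1). Terms can then be condensed into functional
groups by single-linkage clustering on pairwise Cohen's kappa of their
query-membership indicator vectors, each group led by its most significant
term.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import DomainError, InputError
from .io import AnnotationSet

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "hypergeom_pvalue",
    "bh_adjust",
    "enrich",
    "cohen_kappa_binary",
    "kappa_group_terms",
]


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    K: int
    n: int
    k: int
    N: int
    p_raw: float
    p_adj: float
    members_hit: frozenset[str]
    retained: bool


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail probability P(X >= k) for X ~ Hypergeometric(N, K, n).

    N is the universe size, K the term size, n the query size, k the overlap.
    Computed via the survival function, which works in log space internally
    and is stable for large N. P(X >= 0) is exactly 1.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise DomainError(f"need 0 <= K <= N and 0 <= n <= N, got K={K}, n={n}, N={N}")
    if k < 0 or k > K or k > n:
        raise DomainError(f"overlap k={k} inconsistent with K={K}, n={n}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment; output order matches input."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise DomainError("p-values must all lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def enrich(
    query: Iterable[str],
    annotations: AnnotationSet,
    alpha: float = 0.05,
    filter_on: str = "raw",
) -> list[EnrichmentResult]:
    """Over-representation analysis of a target set against annotation terms.

    The query is silently restricted to the universe (restriction logged);
    one result is produced per term with overlap >= 1, sorted by ascending
    raw p then term_id. ``retained`` marks results whose selected p-value
    (raw or BH-adjusted per ``filter_on``) is <= alpha.
    """
    if filter_on not in ("raw", "adjusted"):
        raise InputError("filter_on must be 'raw' or 'adjusted'")
    if len(annotations) == 0:
        raise InputError("empty annotation set")
    q = set(query)
    q_in = q & annotations.universe
    if len(q_in) < len(q):
        logger.info("query restricted to universe: %d of %d kept", len(q_in), len(q))
    if not q_in:
        warnings.warn("query does not intersect the annotation universe; empty result")
        return []
    N = len(annotations.universe)
    n = len(q_in)
    rows = []
    for tid, (name, members) in annotations.terms.items():
        hit = members & q_in
        if not hit:
            continue
        K = len(members)
        k = len(hit)
        rows.append((tid, name, K, k, frozenset(hit), hypergeom_pvalue(k, K, n, N)))
    rows.sort(key=lambda r: (r[5], r[0]))
    adj = bh_adjust([r[5] for r in rows])
    out = []
    for (tid, name, K, k, hit, p_raw), p_adj in zip(rows, adj):
        selected = p_raw if filter_on == "raw" else p_adj
        out.append(EnrichmentResult(
            term_id=tid, term_name=name, K=K, n=n, k=k, N=N,
            p_raw=p_raw, p_adj=p_adj, members_hit=hit, retained=selected <= alpha,
        ))
    return out


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "term_id": r.term_id, "term_name": r.term_name,
            "K": r.K, "n": r.n, "k": r.k, "N": r.N,
            "p_raw": r.p_raw, "p_adj": r.p_adj,
            "retained": r.retained,
            "members_hit": "|".join(sorted(r.members_hit)),
        }
        for r in results
    ], columns=["term_id", "term_name", "K", "n", "k", "N", "p_raw", "p_adj",
                "retained", "members_hit"])


def cohen_kappa_binary(set_a: frozenset[str] | set[str], set_b: frozenset[str] | set[str],
                       domain: Sequence[str]) -> float:
    """Cohen's kappa between two membership indicators over a common domain.

    Degenerate case: when chance agreement is 1 (both indicators constant),
    kappa is 1 for identical indicators and 0 otherwise.
    """
    m = len(domain)
    if m == 0:
        raise InputError("empty kappa domain")
    a = sum(1 for x in domain if x in set_a and x in set_b)
    b = sum(1 for x in domain if x in set_a and x not in set_b)
    c = sum(1 for x in domain if x not in set_a and x in set_b)
    d = m - a - b - c
    po = (a + d) / m
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / (m * m)
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return (po - pe) / (1 - pe)


def kappa_group_terms(
    results: Sequence[EnrichmentResult],
    kappa_min: float = 0.4,
    domain: Sequence[str] | None = None,
) -> list[dict]:
    """Group enriched terms whose hit sets agree at Cohen's kappa >= kappa_min.

    Single-linkage grouping (connected components of the kappa-threshold
    graph) over the terms' ``members_hit`` indicator vectors; the indicator
    domain defaults to the union of all hit sets. Each group's leading term
    is its lowest raw p, ties broken by term_id.
    """
    import networkx as nx

    if not results:
        return []
    if domain is None:
        dom = sorted(frozenset().union(*(r.members_hit for r in results)))
    else:
        dom = sorted(set(domain))
    g = nx.Graph()
    g.add_nodes_from(r.term_id for r in results)
    by_id = {r.term_id: r for r in results}
    ids = sorted(by_id)
    for i, t1 in enumerate(ids):
        for t2 in ids[i + 1:]:
            kap = cohen_kappa_binary(by_id[t1].members_hit, by_id[t2].members_hit, dom)
            if kap >= kappa_min:
                g.add_edge(t1, t2)
    groups = []
    for comp in nx.connected_components(g):
        terms = sorted(comp)
        leader = min(terms, key=lambda t: (by_id[t].p_raw, t))
        groups.append({"leading_term": leader, "terms": terms,
                       "p_raw": by_id[leader].p_raw})
    groups.sort(key=lambda grp: (grp["p_raw"], grp["leading_term"]))
    return groups
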