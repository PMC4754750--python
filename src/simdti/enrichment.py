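"""Hypergeometric enrichment of target sets, Benjamini-Hochberg
correction, and the reverse (term -> formulas) index."""

from __future__ import annotations

import json
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .datatypes import EnrichmentResult, GeneSetCollection

__all__ = [
    "hypergeom_upper_tail",
    "bh_adjust",
    "enrich",
    "function2tcm_index",
    "results_to_table",
    "write_results_json",
    "read_results_json",
]


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability ``P(X >= k)`` for ``k``
    successes when drawing ``n`` items from a universe of ``N`` containing
    ``K`` marked items.  Computed via the survival function (log-space
    internals), exact for k = 0."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(n, K)):
        raise ValueError(
            f"invalid hypergeometric parameters: k={k}, K={K}, n={n}, N={N}"
        )
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k)
    return float(min(1.0, hypergeom.sf(k - 1, N, K, n)))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, returned in input
    order: ``adj_(i) = min_{j>=i} p_(j) * m / j``, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.isnan(p).any() or (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def enrich(
    targets: Iterable[str],
    collection: GeneSetCollection,
    p_adj_cutoff: float = 0.05,
) -> list[EnrichmentResult]:
    """Test every term with at least one mapped target for
    over-representation of ``targets`` (de-duplicated, intersected with
    the background universe); BH-correct across the tested terms of this
    category; sort by (adjusted p, term id)."""
    target_set = set(targets) & set(collection.universe)
    if not target_set:
        raise ValueError(
            "no targets map into the collection universe "
            f"(category {collection.category!r}); id spaces likely differ"
        )
    n = len(target_set)
    N = len(collection.universe)
    rows = []
    for term_id in sorted(collection.terms):
        term = collection.terms[term_id]
        mapped = sorted(target_set & term.members)
        if not mapped:
            continue  # untested; does not inflate m
        k, K = len(mapped), len(term.members)
        rows.append((term, mapped, hypergeom_upper_tail(k, K, n, N)))
    if not rows:
        return []
    p_adj = bh_adjust([r[2] for r in rows])
    results = [
        EnrichmentResult(
            term_id=term.term_id,
            term_name=term.name,
            category=collection.category,
            k=len(mapped),
            K=len(term.members),
            n=n,
            N=N,
            p_raw=p_raw,
            p_adjusted=float(adj),
            mapped_targets=tuple(mapped),
            significant=bool(adj <= p_adj_cutoff),
        )
        for (term, mapped, p_raw), adj in zip(rows, p_adj)
    ]
    results.sort(key=lambda r: (r.p_adjusted, r.term_id))
    return results


def function2tcm_index(
    analyses: Mapping[str, Sequence[EnrichmentResult]],
) -> dict[str, list[tuple[str, float]]]:
    """Invert named enrichment outputs into a term -> [(name, p_adj)]
    index, keeping only significant entries, best p first.

    Analysis names are keys (e.g. formula or herb names); duplicates are
    rejected upstream by the mapping type, and an empty mapping is an
    error.
    """
    if not analyses:
        raise ValueError("at least one named analysis is required")
    index: dict[str, list[tuple[str, float]]] = {}
    for name in analyses:
        for res in analyses[name]:
            if not res.significant:
                continue
            index.setdefault(res.term_id, []).append((name, res.p_adjusted))
    for term_id in index:
        index[term_id].sort(key=lambda e: (e[1], e[0]))
    return dict(sorted(index.items()))


def results_to_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Tabular view matching the result-page columns."""
    return pd.DataFrame(
        {
            "term_id": [r.term_id for r in results],
            "term_name": [r.term_name for r in results],
            "category": [r.category for r in results],
            "k": [r.k for r in results],
            "K": [r.K for r in results],
            "n": [r.n for r in results],
            "N": [r.N for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
            "significant": [r.significant for r in results],
            "mapped_targets": ["|".join(r.mapped_targets) for r in results],
        }
    )


def write_results_json(results: Sequence[EnrichmentResult], path) -> None:
    payload = [
        {
            "term_id": r.term_id,
            "term_name": r.term_name,
            "category": r.category,
            "k": r.k,
            "K": r.K,
            "n": r.n,
            "N": r.N,
            "p_raw": r.p_raw,
            "p_adjusted": r.p_adjusted,
            "mapped_targets": list(r.mapped_targets),
            "significant": r.significant,
        }
        for r in results
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_results_json(path) -> list[EnrichmentResult]:
    with open(path) as fh:
        payload = json.load(fh)
    return [
        EnrichmentResult(
            term_id=d["term_id"],
            term_name=d["term_name"],
            category=d["category"],
            k=d["k"],
            K=d["K"],
            n=d["n"],
            N=d["N"],
            p_raw=d["p_raw"],
            p_adjusted=d["p_adjusted"],
            mapped_targets=tuple(d["mapped_targets"]),
            significant=d["significant"],
        )
        for d in payload
    ]
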