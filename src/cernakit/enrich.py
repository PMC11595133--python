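"""Hypergeometric over-representation analysis with BH-FDR correction.

Each functional term (a GO term or KEGG pathway, supplied as a
term -> gene map) is tested for over-representation of a query gene set
against a background universe with the upper-tail hypergeometric
probability; p-values are corrected across all tested terms by the
Benjamini-Hochberg step-up procedure. The reported enrichment score is
-log10(p), the quantity conventionally plotted on enrichment bar charts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EnrichmentResult",
    "hypergeom_upper",
    "hypergeom_pmf",
    "bh_adjust",
    "enrich",
    "read_term_map",
]


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # query genes in the term
    K: int  # background genes in the term
    n: int  # query size
    N: int  # background size
    p: float
    fdr: float
    enrichment_score: float  # -log10(p)


def _check_bounds(k: int, K: int, n: int, N: int) -> None:
    if not (0 <= k <= min(K, n) and k <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid hypergeometric bounds k={k} K={K} n={n} N={N}")


def hypergeom_pmf(k: int, K: int, n: int, N: int) -> float:
    """P(X = k) for X ~ Hypergeom(N, K, n)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid hypergeometric bounds K={K} n={n} N={N}")
    return float(stats.hypergeom.pmf(k, N, K, n))


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail probability P(X >= k) for X ~ Hypergeom(N, K, n).

    Drawing n genes from a universe of N containing K term members, the
    probability of seeing k or more members in the draw.
    """
    _check_bounds(k, K, n, N)
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (FDR).

    fdr for the i-th smallest p is min over j >= i of p_(j) * m / j,
    clipped to 1; returned in the input order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out.tolist()


def read_term_map(path) -> dict[str, tuple[str, set[str]]]:
    """Read a term map TSV (term_id, term_name, gene_id; one row per
    membership) into term_id -> (term_name, gene set)."""
    df = pd.read_csv(path, sep="\t")
    need = {"term_id", "term_name", "gene_id"}
    if not need.issubset(df.columns):
        raise ValueError(f"term map needs columns {sorted(need)}")
    out: dict[str, tuple[str, set[str]]] = {}
    for row in df.itertuples():
        name, genes = out.setdefault(str(row.term_id), (str(row.term_name), set()))
        genes.add(str(row.gene_id))
    return out


def enrich(
    query: Iterable[str],
    background: Iterable[str],
    term_map: Mapping[str, tuple[str, set[str]] | set[str]],
) -> list[EnrichmentResult]:
    """Over-representation of ``query`` within each term, BH-corrected.

    ``query`` must be a subset of ``background``; term gene sets are
    intersected with the background before counting, and terms left empty
    (K = 0) are dropped before correction. Results are sorted by p
    ascending (ties by term_id).
    """
    query_set = set(query)
    bg = set(background)
    stray = sorted(query_set - bg)
    if stray:
        raise ValueError(f"query genes absent from background: {stray[:10]}")
    N, n = len(bg), len(query_set)

    tested: list[tuple[str, str, int, int]] = []
    for term_id in sorted(term_map):
        entry = term_map[term_id]
        if isinstance(entry, tuple):
            name, genes = entry
        else:
            name, genes = term_id, entry
        members = set(genes) & bg
        K = len(members)
        if K == 0:
            continue
        k = len(members & query_set)
        tested.append((term_id, name, k, K))

    pvals = [hypergeom_upper(k, K, n, N) for _, _, k, K in tested]
    fdrs = bh_adjust(pvals)
    results = [
        EnrichmentResult(
            term_id=tid,
            term_name=name,
            k=k,
            K=K,
            n=n,
            N=N,
            p=p,
            fdr=fdr,
            enrichment_score=float(-np.log10(p)) if p > 0 else float("inf"),
        )
        for (tid, name, k, K), p, fdr in zip(tested, pvals, fdrs)
    ]
    results.sort(key=lambda r: (r.p, r.term_id))
    return results


def write_enrichment(results: Sequence[EnrichmentResult], path) -> None:
    rows = [
        {
            "term_id": r.term_id,
            "term_name": r.term_name,
            "k": r.k,
            "K": r.K,
            "n": r.n,
            "N": r.N,
            "p": r.p,
            "fdr": r.fdr,
            "enrichment_score": r.enrichment_score,
        }
        for r in results
    ]
    pd.DataFrame(
        rows,
        columns=["term_id", "term_name", "k", "K", "n", "N", "p", "fdr", "enrichment_score"],
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")
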