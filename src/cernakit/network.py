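"""Sign-constrained co-expression networks and ceRNA triplet assembly.

Pairwise Pearson correlations across all samples (both groups pooled)
define candidate interactions: an edge requires |r| > 0.8 and p < 0.05
(both strict) plus the sign dictated by the ceRNA model — miRNA vs
mRNA and miRNA vs lncRNA must be negative (repression), mRNA vs lncRNA
positive (competition for the same miRNA). Sequence evidence then
filters expression edges: a miRNA edge needs at least one predicted
binding site; a trans lncRNA-mRNA pair needs a duplex hit; a cis pair
needs the genes within a genomic window (default 100 kb, inclusive).
A ceRNA triplet (mRNA, miRNA, lncRNA) is emitted when all three of its
pairwise edges survive, and is scored by its mRNA-lncRNA correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .binding import BindingSite, DuplexHit
from .io_formats import TranscriptRecord

__all__ = [
    "CorrelationEdge",
    "CeRNATriplet",
    "pearson",
    "coexpression_edges",
    "cis_pairs",
    "trans_pairs",
    "mirna_target_edges",
    "assemble_triplets",
]

CLASS_PAIRS = ("miRNA-mRNA", "miRNA-lncRNA", "mRNA-lncRNA")


@dataclass(frozen=True)
class CorrelationEdge:
    id_a: str
    id_b: str
    class_pair: str
    r: float
    p: float
    required_sign: str  # "positive" | "negative"

    @property
    def pair(self) -> tuple[str, str]:
        return (self.id_a, self.id_b)


@dataclass(frozen=True)
class CeRNATriplet:
    mrna_id: str
    mirna_id: str
    lncrna_id: str
    r_mrna_lncrna: float
    r_mirna_mrna: float
    r_mirna_lncrna: float
    mrna_site: BindingSite | None
    lncrna_site: BindingSite | None
    cerna_score: float


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r and its two-sided p-value.

    p comes from t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of
    freedom; |r| = 1 gives p = 0 exactly. Zero variance in either vector
    raises (correlation undefined) rather than propagating NaN.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = xa.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    xc = xa - xa.mean()
    yc = ya - ya.mean()
    sx = float(np.sqrt((xc**2).sum()))
    sy = float(np.sqrt((yc**2).sum()))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("undefined correlation: zero variance")
    r = float((xc * yc).sum() / (sx * sy))
    r = max(-1.0, min(1.0, r))
    # exact collinearity can land within rounding error of +/-1; snap so
    # perfect linear relationships report r = +/-1, p = 0 exactly
    if 1.0 - abs(r) < 1e-14:
        r = math.copysign(1.0, r)
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return r, min(p, 1.0)


def _corr_matrix(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-by-row r and two-sided p between two feature x sample arrays.

    Rows with zero variance yield NaN (callers treat them as edgeless).
    """
    n = A.shape[1]
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    sa = np.sqrt((Ac**2).sum(axis=1))
    sb = np.sqrt((Bc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Ac @ Bc.T) / np.outer(sa, sb)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.abs(r) == 1.0, 0.0, p)
    return r, p


def coexpression_edges(
    matA: pd.DataFrame,
    matB: pd.DataFrame,
    class_pair: str,
    required_sign: str,
    r_threshold: float = 0.8,
    p_threshold: float = 0.05,
) -> list[CorrelationEdge]:
    """All cross-class pairs passing |r| > r_threshold, p < p_threshold
    (strict) with the required correlation sign.

    ``matA``/``matB`` are feature x sample expression frames and must
    share identical sample order (no silent realignment). Features with
    zero variance yield no edges. Edges are sorted by (id_a, id_b).
    """
    if list(matA.columns) != list(matB.columns):
        raise ValueError("sample order mismatch between matrices")
    if required_sign not in {"positive", "negative", "any"}:
        raise ValueError("required_sign must be 'positive', 'negative' or 'any'")
    if matA.shape[1] < 3:
        raise ValueError("need at least 3 samples for Pearson p-values")
    r, p = _corr_matrix(
        matA.to_numpy(dtype=float), matB.to_numpy(dtype=float)
    )
    edges: list[CorrelationEdge] = []
    ids_a = list(matA.index)
    ids_b = list(matB.index)
    mask = (np.abs(r) > r_threshold) & (p < p_threshold)
    if required_sign == "positive":
        mask &= r > 0
    elif required_sign == "negative":
        mask &= r < 0
    mask &= ~np.isnan(r)
    for i, j in zip(*np.nonzero(mask)):
        edges.append(
            CorrelationEdge(
                ids_a[i], ids_b[j], class_pair, float(r[i, j]), float(p[i, j]), required_sign
            )
        )
    edges.sort(key=lambda e: (e.id_a, e.id_b))
    return edges


def _interval_distance(a: TranscriptRecord, b: TranscriptRecord) -> int:
    """0 if the intervals overlap, else the gap between their ends (bp)."""
    if a.end < b.start:
        return b.start - a.end
    if b.end < a.start:
        return a.start - b.end
    return 0


def cis_pairs(
    lncrnas: Sequence[TranscriptRecord],
    genes: Sequence[TranscriptRecord],
    expr_edges: Iterable[CorrelationEdge],
    window_bp: int = 100_000,
) -> list[tuple[str, str, int, int]]:
    """lncRNA-gene pairs within the cis window that are co-expressed.

    A pair is kept iff both features lie on the same chromosome at most
    ``window_bp`` apart (inclusive; 0 when overlapping) and a qualifying
    co-expression edge links them. Returns (lncRNA id, gene id,
    distance, signed display distance); the sign is + when the lncRNA
    starts downstream of the gene start, - when upstream.
    """
    edge_pairs = {frozenset(e.pair) for e in expr_edges}
    out: list[tuple[str, str, int, int]] = []
    for lnc in lncrnas:
        for gene in genes:
            if lnc.chrom != gene.chrom:
                continue
            d = _interval_distance(lnc, gene)
            if d > window_bp:
                continue
            if frozenset((lnc.transcript_id, gene.transcript_id)) not in edge_pairs:
                continue
            signed = d if lnc.start >= gene.start else -d
            out.append((lnc.transcript_id, gene.transcript_id, d, signed))
    out.sort(key=lambda t: (t[0], t[1]))
    return out


def trans_pairs(
    duplex_hits: Iterable[DuplexHit],
    expr_edges: Iterable[CorrelationEdge],
) -> list[tuple[str, str]]:
    """lncRNA-mRNA pairs with both a duplex hit and a co-expression edge."""
    hit_pairs = {(h.lncrna_id, h.mrna_id) for h in duplex_hits}
    edge_pairs = {frozenset(e.pair) for e in expr_edges}
    kept = sorted(
        (lnc, m) for lnc, m in hit_pairs if frozenset((lnc, m)) in edge_pairs
    )
    return kept


def mirna_target_edges(
    expr_edges: Iterable[CorrelationEdge],
    sites: Iterable[BindingSite],
) -> list[CorrelationEdge]:
    """Keep negative miRNA-target edges backed by >= 1 binding site."""
    site_pairs = {(s.mirna_id, s.target_id) for s in sites}
    kept = [
        e
        for e in expr_edges
        if e.required_sign == "negative" and _mirna_pair(e) in site_pairs
    ]
    kept.sort(key=lambda e: (e.id_a, e.id_b))
    return kept


def _mirna_pair(edge: CorrelationEdge) -> tuple[str, str]:
    """(miRNA id, target id) for an edge whose class pair starts with miRNA."""
    if not edge.class_pair.startswith("miRNA"):
        raise ValueError(f"not a miRNA edge: {edge.class_pair}")
    return (edge.id_a, edge.id_b)


def assemble_triplets(
    mirna_mrna_edges: Sequence[CorrelationEdge],
    mirna_lncrna_edges: Sequence[CorrelationEdge],
    mrna_lncrna_edges: Sequence[CorrelationEdge],
    sites: Sequence[BindingSite] = (),
    score_min: float | None = None,
) -> list[CeRNATriplet]:
    """Join the three edge sets into (mRNA, miRNA, lncRNA) triplets.

    A triplet is emitted iff the miRNA represses both the mRNA and the
    lncRNA (edges in the two negative sets) and the mRNA and lncRNA are
    positively co-expressed. The ceRNA score is the mRNA-lncRNA r;
    ``score_min`` optionally floors it. Output is sorted by score
    descending, ties by (mrna_id, mirna_id, lncrna_id).
    """
    mm = {(e.id_a, e.id_b): e for e in mirna_mrna_edges}  # (miRNA, mRNA)
    ml = {(e.id_a, e.id_b): e for e in mirna_lncrna_edges}  # (miRNA, lncRNA)
    pl: dict[tuple[str, str], CorrelationEdge] = {}  # (mRNA, lncRNA)
    for e in mrna_lncrna_edges:
        pl[(e.id_a, e.id_b)] = e

    best_site: dict[tuple[str, str], BindingSite] = {}
    for s in sites:
        key = (s.mirna_id, s.target_id)
        cur = best_site.get(key)
        if cur is None or (s.align_score, -s.delta_g) > (cur.align_score, -cur.delta_g):
            best_site[key] = s

    mrnas_of: dict[str, list[str]] = {}
    for mi, m in mm:
        mrnas_of.setdefault(mi, []).append(m)
    lncs_of: dict[str, list[str]] = {}
    for mi, l in ml:
        lncs_of.setdefault(mi, []).append(l)

    triplets: list[CeRNATriplet] = []
    for mi in sorted(set(mrnas_of) & set(lncs_of)):
        for m in mrnas_of[mi]:
            for l in lncs_of[mi]:
                edge_pl = pl.get((m, l))
                if edge_pl is None:
                    continue
                score = edge_pl.r
                if score_min is not None and score < score_min:
                    continue
                triplets.append(
                    CeRNATriplet(
                        mrna_id=m,
                        mirna_id=mi,
                        lncrna_id=l,
                        r_mrna_lncrna=edge_pl.r,
                        r_mirna_mrna=mm[(mi, m)].r,
                        r_mirna_lncrna=ml[(mi, l)].r,
                        mrna_site=best_site.get((mi, m)),
                        lncrna_site=best_site.get((mi, l)),
                        cerna_score=score,
                    )
                )
    triplets.sort(
        key=lambda t: (-t.cerna_score, t.mrna_id, t.mirna_id, t.lncrna_id)
    )
    return triplets
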