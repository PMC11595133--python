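"""Sequence-level interaction prediction.

Two scanners share the nearest-neighbor energy model from
:mod:`cernakit.energy`:

``mirna_scan``
    miRNA target-site prediction in the miranda family: a local
    complementarity alignment of the miRNA (5'->3') against the target,
    with the 5' seed region up-weighted, an alignment-score threshold S,
    a duplex free-energy threshold DeltaG, and optionally a *strict seed*
    requirement (miRNA positions 2-8 all Watson-Crick paired, no wobbles,
    no gaps). Defaults S >= 150 and DeltaG <= -30 kcal/mol.

``trans_duplex_scan``
    lncRNA-mRNA trans interaction prediction: maximal exactly
    complementary stretches between the two transcripts, kept when they
    reach a minimum length (default 10 bp) and a free-energy cutoff
    (default -100, configurable — see the methods note on units).

Coordinates in reported sites are 1-based closed positions on the target
(sense strand). All sequences are DNA-spelled internally (T == U).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .energy import DEFAULT_MODEL, NNEnergyModel, duplex_energy

__all__ = [
    "BindingSite",
    "DuplexHit",
    "ScanParams",
    "mirna_scan",
    "trans_duplex_scan",
    "revcomp",
    "perfect_site_score",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# Seed region: miRNA position 1 is the 5' nucleotide; seed = positions 2-8.
SEED_START = 2
SEED_END = 8


def _norm(seq: str) -> str:
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    return _norm(seq).translate(_COMPLEMENT)[::-1]


def _is_wc(a: str, b: str) -> bool:
    """True if a (query base) pairs Watson-Crick with target base b."""
    return a == b.translate(_COMPLEMENT)


def _is_gu(a: str, b: str) -> bool:
    """True if a.b is a G.U (wobble) pair, DNA spelling."""
    return (a == "G" and b == "T") or (a == "T" and b == "G")


@dataclass(frozen=True)
class ScanParams:
    """Alignment scoring constants for ``mirna_scan`` (miranda family).

    Substitution scores at miRNA positions ``seed_start``..``seed_end``
    are multiplied by ``seed_scale`` (the 5' end dominates targeting).
    """

    match: float = 5.0
    gu_wobble: float = 1.0
    mismatch: float = -3.0
    gap_open: float = -9.0
    gap_extend: float = -4.0
    seed_scale: float = 4.0
    seed_start: int = SEED_START
    seed_end: int = SEED_END


DEFAULT_SCAN_PARAMS = ScanParams()


@dataclass(frozen=True)
class BindingSite:
    """A predicted miRNA binding site on a target transcript."""

    mirna_id: str
    target_id: str
    target_start: int  # 1-based closed, on the target sense strand
    target_end: int
    align_score: float
    delta_g: float
    seed_perfect: bool

    def __post_init__(self) -> None:
        if self.target_start > self.target_end:
            raise ValueError("site start > end")


@dataclass(frozen=True)
class DuplexHit:
    """A maximal complementary stretch between a lncRNA and an mRNA."""

    lncrna_id: str
    mrna_id: str
    lnc_start: int
    lnc_end: int
    mrna_start: int
    mrna_end: int
    stretch_len: int
    energy: float


def perfect_site_score(
    mirna_seq: str, params: ScanParams = DEFAULT_SCAN_PARAMS
) -> float:
    """Alignment score of a site that pairs every miRNA base Watson-Crick.

    Closed form: match * L plus the extra seed weighting; the maximum
    attainable score for a given miRNA.
    """
    m = len(_norm(mirna_seq))
    n_seed = min(params.seed_end, m) - params.seed_start + 1
    return params.match * m + params.match * (params.seed_scale - 1.0) * n_seed


# ---------------------------------------------------------------------------
# miRNA site scanning


def _smith_waterman(
    q: str, w: str, params: ScanParams
) -> tuple[float, list[tuple[int | None, int | None]]]:
    """Local alignment of miRNA ``q`` against target window ``w``.

    ``w`` is in *reverse-complement orientation* relative to the target
    sense strand, so that complementary pairing becomes literal base
    equality and the antiparallel geometry becomes a plain left-to-right
    alignment. Returns (best score, alignment columns); each column is
    (query index, window index) with ``None`` marking a gap, both 0-based.
    Affine gaps (Gotoh); substitution scores at seed positions are scaled.
    """
    m, n = len(q), len(w)
    NEG = float("-inf")
    # H: best ending in match/mismatch; E: gap in query (w advances);
    # F: gap in window (q advances).
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best, best_pos = 0.0, (0, 0)
    for i in range(1, m + 1):
        weight = (
            params.seed_scale
            if params.seed_start <= i <= params.seed_end
            else 1.0
        )
        qi = q[i - 1]
        for j in range(1, n + 1):
            wj = w[j - 1]
            if qi == wj:
                sub = params.match * weight
            elif (qi == "G" and wj == "A") or (qi == "T" and wj == "C"):
                # In revcomp orientation a G.U wobble reads as G/A or T/C.
                sub = params.gu_wobble * weight
            else:
                sub = params.mismatch * weight
            E[i][j] = max(H[i][j - 1] + params.gap_open, E[i][j - 1] + params.gap_extend)
            F[i][j] = max(H[i - 1][j] + params.gap_open, F[i - 1][j] + params.gap_extend)
            H[i][j] = max(0.0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            if H[i][j] > best:
                best, best_pos = H[i][j], (i, j)
    # Traceback.
    cols: list[tuple[int | None, int | None]] = []
    i, j = best_pos
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            if H[i][j] == 0.0:
                break
            weight = (
                params.seed_scale
                if params.seed_start <= i <= params.seed_end
                else 1.0
            )
            qi, wj = q[i - 1], w[j - 1]
            if qi == wj:
                sub = params.match * weight
            elif (qi == "G" and wj == "A") or (qi == "T" and wj == "C"):
                sub = params.gu_wobble * weight
            else:
                sub = params.mismatch * weight
            if H[i][j] == H[i - 1][j - 1] + sub:
                cols.append((i - 1, j - 1))
                i, j = i - 1, j - 1
            elif H[i][j] == E[i][j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            cols.append((None, j - 1))
            if E[i][j] == H[i][j - 1] + params.gap_open:
                state = "H"
            j -= 1
        else:
            cols.append((i - 1, None))
            if F[i][j] == H[i - 1][j] + params.gap_open:
                state = "H"
            i -= 1
    cols.reverse()
    return best, cols


def _alignment_pairs_and_energy(
    q: str,
    w: str,
    cols: Sequence[tuple[int | None, int | None]],
    model: NNEnergyModel,
) -> tuple[float, list[tuple[int, int]]]:
    """Duplex energy of an alignment, plus its paired (qi, wj) columns.

    Stacking applies only between columns adjacent in both sequences; a
    gap or a non-pairing column breaks the helix into segments, each of
    which pays its own initiation penalty minus all-but-one shared term.
    The total reported is init_penalty + sum of stack terms over intact
    steps (a single initiation for the site).
    """
    paired = [
        (qi, wj)
        for qi, wj in cols
        if qi is not None and wj is not None and (q[qi] == w[wj] or _gu_rc(q[qi], w[wj]))
    ]
    if not paired:
        return float("inf"), []
    energy = model.init_penalty
    for (qa, wa), (qb, wb) in zip(paired, paired[1:]):
        if qb == qa + 1 and wb == wa + 1:
            p1 = _pair_string(q[qa], w[wa])
            p2 = _pair_string(q[qb], w[wb])
            energy += model.stack_energy[(p1, p2)]
    return energy, paired


def _gu_rc(a: str, b: str) -> bool:
    """G.U wobble test in revcomp orientation (see _smith_waterman)."""
    return (a == "G" and b == "A") or (a == "T" and b == "C")


def _pair_string(qbase: str, wbase: str) -> str:
    """Map a (query, revcomp-window) column to an RNA pair string.

    The window base is in reverse-complement orientation, so the actual
    target base is its complement.
    """
    t = wbase.translate(_COMPLEMENT)
    return (qbase + t).replace("T", "U")


def _seed_perfect(
    q: str, w: str, cols: Sequence[tuple[int | None, int | None]], params: ScanParams
) -> bool:
    """True iff seed positions are all present, WC-paired, and ungapped."""
    by_q = {qi: wj for qi, wj in cols if qi is not None}
    prev_w = None
    for pos in range(params.seed_start, params.seed_end + 1):
        qi = pos - 1
        wj = by_q.get(qi)
        if wj is None or q[qi] != w[wj]:
            return False
        if prev_w is not None and wj != prev_w + 1:
            return False
        prev_w = wj
    return True


def mirna_scan(
    mirna_seq: str,
    target_seq: str,
    model: NNEnergyModel = DEFAULT_MODEL,
    s_min: float = 150.0,
    dg_max: float = -30.0,
    strict_seed: bool = True,
    params: ScanParams = DEFAULT_SCAN_PARAMS,
    mirna_id: str = "miRNA",
    target_id: str = "target",
) -> list[BindingSite]:
    """Scan a target transcript for binding sites of one miRNA.

    Reported sites satisfy ``align_score >= s_min`` and
    ``delta_g <= dg_max``; with ``strict_seed`` the seed (miRNA positions
    2-8) must be contiguously Watson-Crick paired. Overlapping candidates
    are resolved by keeping the higher-scoring site (ties: lower energy,
    then leftmost).

    With ``strict_seed`` the scan is seed-anchored: exact seed
    complements are located by string search and the full alignment is
    computed in a window around each anchor — exact for strict-seed
    semantics, since every valid site contains the exact seed match.
    Without it, a full local alignment of the whole target is used.
    """
    q = _norm(mirna_seq)
    t = _norm(target_seq)
    if len(q) < params.seed_end:
        raise ValueError(f"miRNA shorter than the seed span ({params.seed_end} nt)")
    if not (18 <= len(q) <= 26):
        raise ValueError(f"miRNA length {len(q)} outside 18-26 nt")
    if not t:
        raise ValueError("empty target sequence")
    rc = revcomp(t)
    L = len(t)
    m = len(q)

    candidates: list[BindingSite] = []
    seen_spans: set[tuple[int, int]] = set()

    def _evaluate_window(w_start: int, w_end: int) -> None:
        """Align q against rc[w_start:w_end] and record a passing site."""
        w = rc[w_start:w_end]
        score, cols = _smith_waterman(q, w, params)
        if score < s_min or not cols:
            return
        if strict_seed and not _seed_perfect(q, w, cols, params):
            return
        dg, paired = _alignment_pairs_and_energy(q, w, cols, model)
        if not paired or dg > dg_max:
            return
        w_idx = [wj for _, wj in cols if wj is not None]
        k1 = w_start + min(w_idx) + 1  # 1-based on rc
        k2 = w_start + max(w_idx) + 1
        start, end = L - k2 + 1, L - k1 + 1  # back to target sense coords
        if (start, end) in seen_spans:
            return
        seen_spans.add((start, end))
        candidates.append(
            BindingSite(
                mirna_id=mirna_id,
                target_id=target_id,
                target_start=start,
                target_end=end,
                align_score=score,
                delta_g=dg,
                seed_perfect=_seed_perfect(q, w, cols, params),
            )
        )

    if strict_seed:
        seed = q[params.seed_start - 1 : params.seed_end]
        pad = m + 8  # room for the non-seed arms plus a few gaps
        pos = rc.find(seed)
        while pos != -1:
            w_start = max(0, pos - (params.seed_start - 1) - pad // 2)
            w_end = min(len(rc), pos + len(seed) + pad)
            _evaluate_window(w_start, w_end)
            pos = rc.find(seed, pos + 1)
    else:
        # Full-length local alignment; re-scan with the best hit masked
        # until nothing reaches the score threshold.
        masked = rc
        for _ in range(64):
            score, cols = _smith_waterman(q, masked, params)
            if score < s_min or not cols:
                break
            w_idx = [wj for _, wj in cols if wj is not None]
            lo, hi = min(w_idx), max(w_idx)
            w = masked
            dg, paired = _alignment_pairs_and_energy(q, w, cols, model)
            if paired and dg <= dg_max:
                k1, k2 = lo + 1, hi + 1
                start, end = L - k2 + 1, L - k1 + 1
                if (start, end) not in seen_spans:
                    seen_spans.add((start, end))
                    candidates.append(
                        BindingSite(
                            mirna_id=mirna_id,
                            target_id=target_id,
                            target_start=start,
                            target_end=end,
                            align_score=score,
                            delta_g=dg,
                            seed_perfect=_seed_perfect(q, w, cols, params),
                        )
                    )
            masked = masked[:lo] + "N" * (hi - lo + 1) + masked[hi + 1 :]

    # Overlap resolution: higher S wins; ties by lower energy, then leftmost.
    candidates.sort(key=lambda s: (-s.align_score, s.delta_g, s.target_start))
    kept: list[BindingSite] = []
    for site in candidates:
        if all(
            site.target_end < k.target_start or site.target_start > k.target_end
            for k in kept
        ):
            kept.append(site)
    kept.sort(key=lambda s: s.target_start)
    return kept


def scan_many(
    mirna_seqs: dict[str, str],
    target_seqs: dict[str, str],
    model: NNEnergyModel = DEFAULT_MODEL,
    s_min: float = 150.0,
    dg_max: float = -30.0,
    strict_seed: bool = True,
    params: ScanParams = DEFAULT_SCAN_PARAMS,
) -> list[BindingSite]:
    """All-vs-all miRNA site scan; sites sorted by (miRNA, target, start)."""
    sites: list[BindingSite] = []
    for mid in sorted(mirna_seqs):
        for tid in sorted(target_seqs):
            sites.extend(
                mirna_scan(
                    mirna_seqs[mid],
                    target_seqs[tid],
                    model=model,
                    s_min=s_min,
                    dg_max=dg_max,
                    strict_seed=strict_seed,
                    params=params,
                    mirna_id=mid,
                    target_id=tid,
                )
            )
    return sites


# ---------------------------------------------------------------------------
# lncRNA-mRNA trans duplex scanning


def trans_duplex_scan(
    lnc_seq: str,
    mrna_seq: str,
    model: NNEnergyModel = DEFAULT_MODEL,
    min_stretch: int = 10,
    energy_cutoff: float = -100.0,
    allow_gu: bool = False,
    lncrna_id: str = "lncRNA",
    mrna_id: str = "mRNA",
) -> list[DuplexHit]:
    """Find maximal complementary stretches between two transcripts.

    A stretch is a run of consecutive positions where the lncRNA pairs
    the mRNA antiparallel (Watson-Crick; G.U too if ``allow_gu``).
    Stretches shorter than ``min_stretch`` or with nearest-neighbor
    energy above ``energy_cutoff`` are discarded. Hits are sorted by
    energy ascending (most stable first).

    Without wobbles the search runs by hashing ``min_stretch``-mers of
    the reverse-complemented mRNA; with wobbles it falls back to a dense
    O(n*m) diagonal sweep.
    """
    a = _norm(lnc_seq)
    b = _norm(mrna_seq)
    if not a or not b:
        raise ValueError("empty sequence")
    n, m = len(a), len(b)
    rcb = revcomp(b)

    # Collect maximal matching runs as (lnc 0-based start, rcb 0-based
    # start, length); the diagonal (i - j) identifies each run uniquely.
    runs: dict[tuple[int, int], int] = {}

    def _pairs_ok(x: str, y: str) -> bool:
        return x == y or (allow_gu and _gu_rc(x, y))

    if allow_gu:
        for diag in range(-(len(rcb) - 1), n):
            i = max(0, diag)
            j = i - diag
            run = 0
            while i < n and j < len(rcb):
                if _pairs_ok(a[i], rcb[j]):
                    run += 1
                else:
                    if run >= min_stretch:
                        runs[(i - run, j - run)] = run
                    run = 0
                i += 1
                j += 1
            if run >= min_stretch:
                runs[(i - run, j - run)] = run
    else:
        k = min_stretch
        if len(rcb) >= k and n >= k:
            kmer_pos: dict[str, list[int]] = {}
            for j in range(len(rcb) - k + 1):
                kmer_pos.setdefault(rcb[j : j + k], []).append(j)
            for i in range(n - k + 1):
                for j in kmer_pos.get(a[i : i + k], ()):
                    # extend to the maximal run containing this k-mer
                    s_i, s_j = i, j
                    while s_i > 0 and s_j > 0 and a[s_i - 1] == rcb[s_j - 1]:
                        s_i -= 1
                        s_j -= 1
                    e_i, e_j = i + k, j + k
                    while e_i < n and e_j < len(rcb) and a[e_i] == rcb[e_j]:
                        e_i += 1
                        e_j += 1
                    runs[(s_i, s_j)] = e_i - s_i

    hits: list[DuplexHit] = []
    for (i0, j0), length in runs.items():
        if length < min_stretch:
            continue
        pairs = [_pair_string(a[i0 + off], rcb[j0 + off]) for off in range(length)]
        energy = duplex_energy(pairs, model)
        if energy > energy_cutoff:
            continue
        # map rcb coords back to mRNA sense coords (1-based closed)
        m_start = m - (j0 + length - 1)
        m_end = m - j0
        hits.append(
            DuplexHit(
                lncrna_id=lncrna_id,
                mrna_id=mrna_id,
                lnc_start=i0 + 1,
                lnc_end=i0 + length,
                mrna_start=m_start,
                mrna_end=m_end,
                stretch_len=length,
                energy=energy,
            )
        )
    hits.sort(key=lambda h: (h.energy, h.lnc_start, h.mrna_start))
    return hits
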