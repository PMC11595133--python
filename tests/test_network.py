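import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cernakit.binding import BindingSite, DuplexHit
from cernakit.io_formats import TranscriptRecord
from cernakit.network import (
    CorrelationEdge,
    assemble_triplets,
    cis_pairs,
    coexpression_edges,
    mirna_target_edges,
    pearson,
    trans_pairs,
)


def oracle_pearson(x, y):
    """Brute-force covariance/variance oracle with independent p."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    cov = ((x - x.mean()) * (y - y.mean())).sum() / n
    r = cov / (x.std() * y.std())
    if abs(r) >= 1:
        return float(np.sign(r)), 0.0
    t = r * np.sqrt((n - 2) / (1 - r * r))
    return r, 2 * stats.t.sf(abs(t), n - 2)


class TestPearson:
    def test_perfect_linearity(self):
        r, p = pearson([1, 2, 3], [2, 4, 6])
        assert r == 1.0 and p == 0.0

    def test_perfect_anticorrelation(self):
        r, p = pearson([1, 2, 3], [3, 2, 1])
        assert r == -1.0 and p == 0.0

    def test_r_08_n6_p_from_t_distribution(self):
        # integer construction with exact r = 0.8 on n = 6
        x = [2, 0, 0, 2, 1, 1]
        y = [14, 0, 6, 8, 7, 7]
        r, p = pearson(x, y)
        assert r == 0.8
        # oracle: two-sided tail of t = 0.8 * sqrt(4 / 0.36) on 4 df
        assert p == pytest.approx(2 * stats.t.sf(0.8 * np.sqrt(4 / 0.36), 4), abs=1e-12)
        assert p == pytest.approx(0.056, abs=5e-4)

    def test_matches_oracle_on_random_vectors(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n = int(rng.integers(3, 40))
            x = rng.normal(size=n)
            y = rng.normal(size=n) + 0.5 * x
            r, p = pearson(x, y)
            ro, po = oracle_pearson(x, y)
            assert r == pytest.approx(ro, abs=1e-10)
            assert p == pytest.approx(po, abs=1e-10)

    def test_symmetry_and_positive_affine_invariance(self):
        rng = np.random.default_rng(18)
        x, y = rng.normal(size=8), rng.normal(size=8)
        assert pearson(x, y)[0] == pytest.approx(pearson(y, x)[0], abs=1e-12)
        r0 = pearson(x, y)[0]
        r1 = pearson(3.0 * x + 7.0, y)[0]
        assert r1 == pytest.approx(r0, abs=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="variance"):
            pearson([1, 1, 1], [1, 2, 3])

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            pearson([1, 2], [3, 4])


def _frame(rows, ids=None):
    rows = np.atleast_2d(np.asarray(rows, float))
    ids = ids or [f"x{i}" for i in range(rows.shape[0])]
    return pd.DataFrame(rows, index=ids, columns=[f"s{j}" for j in range(rows.shape[1])])


class TestCoexpressionEdges:
    def test_self_pairs_have_r_one(self):
        mat = _frame([[1, 2, 3, 4, 5, 6], [6, 1, 3, 2, 4, 5]])
        edges = coexpression_edges(mat, mat, "mRNA-lncRNA", "positive")
        self_edges = [e for e in edges if e.id_a == e.id_b]
        assert len(self_edges) == 2
        assert all(e.r == 1.0 and e.p == 0.0 for e in self_edges)

    def test_r_exactly_08_rejected(self):
        a = _frame([[2, 0, 0, 2, 1, 1]], ids=["a"])
        b = _frame([[14, 0, 6, 8, 7, 7]], ids=["b"])
        assert coexpression_edges(a, b, "mRNA-lncRNA", "positive") == []

    def test_sign_constraint(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        a = _frame([x], ids=["a"])
        b = _frame([-x + 0.01 * np.array([1, -1, 0, 1, -1, 0])], ids=["b"])
        assert coexpression_edges(a, b, "miRNA-mRNA", "negative") != []
        assert coexpression_edges(a, b, "mRNA-lncRNA", "positive") == []

    def test_sample_order_mismatch_rejected(self):
        a = _frame([[1, 2, 3, 4]])
        b = _frame([[1, 2, 3, 4]])
        b.columns = ["s1", "s0", "s2", "s3"]
        with pytest.raises(ValueError, match="sample order"):
            coexpression_edges(a, b, "mRNA-lncRNA", "positive")

    def test_edge_sets_shrink_as_thresholds_tighten(self):
        rng = np.random.default_rng(19)
        a = _frame(rng.normal(size=(15, 6)))
        b = _frame(rng.normal(size=(15, 6)), ids=[f"y{i}" for i in range(15)])
        loose = coexpression_edges(a, b, "mRNA-lncRNA", "any", 0.5, 0.2)
        tight_r = coexpression_edges(a, b, "mRNA-lncRNA", "any", 0.7, 0.2)
        tight_p = coexpression_edges(a, b, "mRNA-lncRNA", "any", 0.5, 0.05)
        as_set = lambda es: {(e.id_a, e.id_b) for e in es}
        assert as_set(tight_r) <= as_set(loose)
        assert as_set(tight_p) <= as_set(loose)


def _gene(tid, chrom, start, end, biotype="mRNA"):
    return TranscriptRecord(
        transcript_id=tid, gene_id=f"G{tid}", biotype=biotype, chrom=chrom,
        strand="+", start=start, end=end, exons=((start, end),),
    )


def _edge(a, b, r=0.95, sign="positive", cls="mRNA-lncRNA"):
    return CorrelationEdge(a, b, cls, r, 0.001, sign)


class TestCisPairs:
    def test_overlap_distance_zero_kept(self):
        lnc = _gene("L1", "chr1", 500, 900, "lncRNA")
        gene = _gene("M1", "chr1", 100, 600)
        out = cis_pairs([lnc], [gene], [_edge("L1", "M1")])
        assert out == [("L1", "M1", 0, 0)]

    def test_window_boundary_inclusive(self):
        gene = _gene("M1", "chr1", 100, 600)
        lnc_at = _gene("L1", "chr1", 600 + 100_000, 600 + 100_500, "lncRNA")
        lnc_past = _gene("L2", "chr1", 600 + 100_001, 600 + 100_501, "lncRNA")
        edges = [_edge("L1", "M1"), _edge("L2", "M1")]
        out = cis_pairs([lnc_at, lnc_past], [gene], edges)
        assert [(l, g, d) for l, g, d, _ in out] == [("L1", "M1", 100_000)]

    def test_requires_coexpression_edge(self):
        lnc = _gene("L1", "chr1", 1000, 1400, "lncRNA")
        gene = _gene("M1", "chr1", 100, 600)
        assert cis_pairs([lnc], [gene], []) == []

    def test_different_chromosome_skipped(self):
        lnc = _gene("L1", "chr2", 1000, 1400, "lncRNA")
        gene = _gene("M1", "chr1", 100, 600)
        assert cis_pairs([lnc], [gene], [_edge("L1", "M1")]) == []

    def test_upstream_distance_signed_negative(self):
        gene = _gene("M1", "chr1", 50_000, 51_000)
        lnc = _gene("L1", "chr1", 10_000, 11_000, "lncRNA")
        ((_, _, d, signed),) = cis_pairs([lnc], [gene], [_edge("L1", "M1")])
        assert d == 39_000 and signed == -39_000


class TestTransAndTargetEdges:
    def _hit(self, l="L1", m="M1"):
        return DuplexHit(l, m, 1, 20, 1, 20, 20, -45.0)

    def _site(self, mi="R1", t="M1"):
        return BindingSite(mi, t, 10, 31, 200.0, -40.0, True)

    def test_trans_needs_both_evidence_types(self):
        edge = _edge("L1", "M1")
        assert trans_pairs([self._hit()], [edge]) == [("L1", "M1")]
        assert trans_pairs([self._hit()], []) == []
        assert trans_pairs([], [edge]) == []

    def test_mirna_edges_need_binding_site(self):
        neg = _edge("R1", "M1", r=-0.9, sign="negative", cls="miRNA-mRNA")
        assert mirna_target_edges([neg], [self._site()]) == [neg]
        assert mirna_target_edges([neg], []) == []

    def test_positive_mirna_edge_never_kept(self):
        pos = _edge("R1", "M1", r=0.9, sign="positive", cls="miRNA-mRNA")
        assert mirna_target_edges([pos], [self._site()]) == []


class TestAssembleTriplets:
    def _toy(self):
        mm = [_edge("R1", "M1", -0.9, "negative", "miRNA-mRNA")]
        ml = [_edge("R1", "L1", -0.85, "negative", "miRNA-lncRNA")]
        pl = [_edge("M1", "L1", 0.95, "positive", "mRNA-lncRNA")]
        return mm, ml, pl

    def test_single_qualifying_triplet(self):
        mm, ml, pl = self._toy()
        (t,) = assemble_triplets(mm, ml, pl)
        assert (t.mrna_id, t.mirna_id, t.lncrna_id) == ("M1", "R1", "L1")
        assert t.cerna_score == 0.95

    def test_missing_lncrna_arm_gives_nothing(self):
        mm, _, pl = self._toy()
        assert assemble_triplets(mm, [], pl) == []

    def test_score_floor(self):
        mm, ml, pl = self._toy()
        assert assemble_triplets(mm, ml, pl, score_min=0.99) == []

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(23)
        mis = [f"R{i}" for i in range(12)]
        ms = [f"M{i}" for i in range(15)]
        ls = [f"L{i}" for i in range(10)]
        mm = [
            _edge(mi, m, -0.9, "negative", "miRNA-mRNA")
            for mi in mis for m in ms if rng.random() < 0.2
        ]
        ml = [
            _edge(mi, l, -0.88, "negative", "miRNA-lncRNA")
            for mi in mis for l in ls if rng.random() < 0.2
        ]
        pl = [
            _edge(m, l, float(0.81 + 0.18 * rng.random()), "positive", "mRNA-lncRNA")
            for m in ms for l in ls if rng.random() < 0.3
        ]
        got = {(t.mrna_id, t.mirna_id, t.lncrna_id) for t in assemble_triplets(mm, ml, pl)}
        mm_set = {(e.id_a, e.id_b) for e in mm}
        ml_set = {(e.id_a, e.id_b) for e in ml}
        pl_set = {(e.id_a, e.id_b) for e in pl}
        oracle = {
            (m, mi, l)
            for m, mi, l in itertools.product(ms, mis, ls)
            if (mi, m) in mm_set and (mi, l) in ml_set and (m, l) in pl_set
        }
        assert got == oracle

    def test_sorted_by_score_descending(self):
        mm = [_edge("R1", m, -0.9, "negative", "miRNA-mRNA") for m in ("M1", "M2")]
        ml = [_edge("R1", "L1", -0.9, "negative", "miRNA-lncRNA")]
        pl = [_edge("M1", "L1", 0.85, "positive"), _edge("M2", "L1", 0.99, "positive")]
        out = assemble_triplets(mm, ml, pl)
        assert [t.mrna_id for t in out] == ["M2", "M1"]
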