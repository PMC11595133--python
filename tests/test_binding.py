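import numpy as np
import pytest

from cernakit.binding import (
    DEFAULT_SCAN_PARAMS,
    mirna_scan,
    perfect_site_score,
    revcomp,
    trans_duplex_scan,
)
from conftest import random_seq


def brute_force_stretches(a: str, b: str, min_len: int):
    """O(n*m) oracle: all maximal exactly complementary stretches.

    Returns a set of (lnc 0-based start, mrna-rc 0-based start, length).
    """
    rcb = revcomp(b)
    n, m = len(a), len(rcb)
    out = set()
    for i in range(n):
        for j in range(m):
            if a[i] != rcb[j]:
                continue
            if i > 0 and j > 0 and a[i - 1] == rcb[j - 1]:
                continue  # not a run start
            k = 0
            while i + k < n and j + k < m and a[i + k] == rcb[j + k]:
                k += 1
            if k >= min_len:
                out.add((i, j, k))
    return out


class TestMirnaScan:
    MI = "ACGTACGTACGTACGTACGTAG"  # 22 nt

    def test_perfect_complement_gives_one_maximal_site(self):
        target = random_seq(np.random.default_rng(0), 100) + revcomp(self.MI) + \
            random_seq(np.random.default_rng(1), 100)
        sites = mirna_scan(self.MI, target)
        assert len(sites) == 1
        (site,) = sites
        assert site.target_start == 101
        assert site.target_end == 122
        assert site.seed_perfect
        # oracle: closed-form score of the known full-complement alignment
        assert site.align_score == pytest.approx(perfect_site_score(self.MI))
        assert site.delta_g < -30

    def test_site_coordinates_track_implant_position(self):
        rng = np.random.default_rng(7)
        for pos in (1, 37, 479):  # includes both target boundaries
            target = random_seq(rng, 500)
            implant = revcomp(self.MI)
            target = target[: pos - 1] + implant + target[pos - 1 + len(implant):]
            sites = mirna_scan(self.MI, target)
            spans = [(s.target_start, s.target_end) for s in sites]
            assert (pos, pos + len(self.MI) - 1) in spans

    def test_identical_sequence_is_not_a_site(self):
        # the target equals the miRNA itself (not its complement); a
        # purine-only miRNA rules out accidental self-complementarity
        mi = "AGGAAGAGGAAGAAGGAAGGAG"
        target = mi * 10
        assert mirna_scan(mi, target) == []

    def test_gu_wobble_in_seed_rejected_under_strict_seed(self):
        # force a G.U pair at miRNA position 4 in an otherwise perfect site:
        # miRNA G can wobble-pair target T (instead of WC partner C)
        mi = "AAGGAAGGAAGGAAGGAAGGAA"
        site = list(revcomp(mi))
        # miRNA position 4 (G) pairs target base at site index len-4
        idx = len(site) - 4
        assert site[idx] == "C"
        site[idx] = "T"  # G.T wobble
        target = "A" * 50 + "".join(site) + "A" * 50
        assert mirna_scan(mi, target, strict_seed=True) == []
        relaxed = mirna_scan(mi, target, strict_seed=False, s_min=100, dg_max=-20)
        assert any(not s.seed_perfect for s in relaxed)

    def test_thresholds_are_monotone(self):
        rng = np.random.default_rng(3)
        target = random_seq(rng, 300) + revcomp(self.MI) + random_seq(rng, 300)
        base = {(s.target_start, s.target_end) for s in mirna_scan(self.MI, target)}
        stricter_s = {
            (s.target_start, s.target_end)
            for s in mirna_scan(self.MI, target, s_min=250)
        }
        stricter_g = {
            (s.target_start, s.target_end)
            for s in mirna_scan(self.MI, target, dg_max=-60)
        }
        assert stricter_s <= base
        assert stricter_g <= base

    def test_short_mirna_rejected(self):
        with pytest.raises(ValueError):
            mirna_scan("ACGT", "ACGTACGT" * 10)

    def test_reported_sites_respect_thresholds(self, small_sim):
        truth_pair = small_sim.truth.planted_sites[0]
        mi, target, _ = truth_pair
        sites = mirna_scan(
            small_sim.sequences[mi], small_sim.sequences[target],
            mirna_id=mi, target_id=target,
        )
        assert sites, "planted site must be recovered"
        for s in sites:
            assert s.align_score >= 150
            assert s.delta_g <= -30
            assert s.seed_perfect


class TestTransDuplexScan:
    def test_planted_fifteen_mer_recovered(self):
        rng = np.random.default_rng(5)
        m = random_seq(rng, 120)
        window = m[40:55]  # 15 nt
        lnc = random_seq(rng, 100) + revcomp(window) + random_seq(rng, 80)
        hits = trans_duplex_scan(lnc, m, min_stretch=10, energy_cutoff=0.0)
        assert any(h.stretch_len >= 15 for h in hits)

    def test_nine_bp_stretch_is_no_hit(self):
        # designed sequences: complementary stretch of exactly 9 bp
        m = "AAAAAAAAAAAAAAAAAAAAGGGCCCTTTAAAAAAAAAAAAAAAAAAAA"
        window = m[20:29]  # GGGCCCTTT, 9 nt
        lnc = "C" * 30 + revcomp(window) + "C" * 30
        oracle = brute_force_stretches(lnc, m, 1)
        assert max(k for _, _, k in oracle) == 9
        assert trans_duplex_scan(lnc, m, min_stretch=10, energy_cutoff=0.0) == []

    def test_energy_cutoff_filters(self):
        rng = np.random.default_rng(11)
        m = random_seq(rng, 200)
        window = m[50:130]  # 80 nt
        lnc = random_seq(rng, 50) + revcomp(window) + random_seq(rng, 50)
        hits = trans_duplex_scan(lnc, m, min_stretch=10, energy_cutoff=-100.0)
        assert hits and all(h.energy <= -100.0 for h in hits)
        assert trans_duplex_scan(lnc, m, min_stretch=10, energy_cutoff=-1e6) == []

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(21)
        for trial in range(20):
            n = int(rng.integers(30, 201))
            m_len = int(rng.integers(30, 201))
            lnc = random_seq(rng, n)
            mrna = random_seq(rng, m_len)
            if trial % 2 == 0:  # half the trials carry an implant
                w0 = int(rng.integers(0, m_len - 12))
                window = mrna[w0 : w0 + 12]
                l0 = int(rng.integers(0, n - 12))
                lnc = lnc[:l0] + revcomp(window) + lnc[l0 + 12 :]
            found = {
                (h.lnc_start - 1, h.stretch_len)
                for h in trans_duplex_scan(lnc, mrna, min_stretch=6, energy_cutoff=float('inf'))
            }
            oracle = {(i, k) for i, _, k in brute_force_stretches(lnc, mrna, 6)}
            assert found == oracle

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            trans_duplex_scan("", "ACGT")

    def test_hits_sorted_by_energy(self):
        rng = np.random.default_rng(33)
        m = random_seq(rng, 300)
        lnc = (
            random_seq(rng, 40)
            + revcomp(m[10:25])
            + random_seq(rng, 40)
            + revcomp(m[100:180])
            + random_seq(rng, 40)
        )
        hits = trans_duplex_scan(lnc, m, min_stretch=10, energy_cutoff=0.0)
        energies = [h.energy for h in hits]
        assert energies == sorted(energies)
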