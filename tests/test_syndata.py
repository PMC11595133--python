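import numpy as np
import pytest

from cernakit.binding import mirna_scan, revcomp, trans_duplex_scan
from cernakit.network import pearson
from cernakit.syndata import (
    SimConfig,
    TruthSet,
    generate_annotation,
    generate_counts,
    generate_sequences,
    plan_truth,
    read_truth,
    simulate,
    write_truth,
)


ZERO_NOISE = SimConfig(
    n_mrna=40, n_lncrna=15, n_mirna=10, n_triplets=4, n_trans_pairs=2,
    nb_dispersion=0.0, seed=77,
)


@pytest.fixture(scope="module")
def zero_noise_sim():
    return simulate(ZERO_NOISE)


class TestConfig:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(n_mrna=0),
            dict(reps_per_group=1),
            dict(planted_de_fraction=1.2),
            dict(nb_dispersion=-0.1),
            dict(n_triplets=100, n_mirna=10),
            dict(mean_count_log_range=(3.0, 2.0)),
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            SimConfig(**kw)


class TestAnnotation:
    def test_feature_counts_by_construction(self):
        cfg = SimConfig(n_mrna=5, n_lncrna=3, n_mirna=2, n_triplets=1,
                        n_trans_pairs=1, cis_pair_distances=(1000,), seed=1)
        records = generate_annotation(cfg)
        by_type = {}
        for r in records:
            by_type.setdefault(r.biotype, []).append(r)
        assert len(by_type["mRNA"]) == 5
        assert len(by_type["lncRNA"]) == 3
        assert len(by_type["miRNA"]) == 2

    def test_cis_distances_exact(self):
        cfg = SimConfig(n_mrna=20, n_lncrna=10, n_mirna=5, n_triplets=2,
                        n_trans_pairs=1,
                        cis_pair_distances=(0, 100_000, 100_001), seed=3)
        records = generate_annotation(cfg)
        truth = plan_truth(cfg, records)
        by_id = {r.transcript_id: r for r in records}
        for lnc_id, gene_id, d in truth.cis_pair_truth:
            lnc, gene = by_id[lnc_id], by_id[gene_id]
            assert lnc.chrom == gene.chrom
            if d == 0:
                assert lnc.start <= gene.end and gene.start <= lnc.end
            else:
                assert lnc.start - gene.end == d

    def test_lncrna_records_pass_candidate_rules(self):
        records = generate_annotation(ZERO_NOISE)
        for r in records:
            if r.biotype == "lncRNA":
                assert r.length > 200 and r.n_exons >= 2

    def test_chromosome_sizing_error(self):
        cfg = SimConfig(n_mrna=50, n_lncrna=10, n_mirna=5, n_triplets=2,
                        n_trans_pairs=1, chrom_length_bp=100_000, seed=1)
        with pytest.raises(ValueError, match="too short"):
            generate_annotation(cfg)

    def test_same_seed_identical_gtf(self, tmp_path):
        from cernakit.io_formats import write_gtf

        for name in ("a", "b"):
            write_gtf(generate_annotation(ZERO_NOISE), tmp_path / f"{name}.gtf")
        assert (tmp_path / "a.gtf").read_bytes() == (tmp_path / "b.gtf").read_bytes()


class TestSequences:
    def test_planted_sites_are_exact_reverse_complements(self, zero_noise_sim):
        sim = zero_noise_sim
        for mi, target, pos in sim.truth.planted_sites:
            mi_seq = sim.sequences[mi]
            window = sim.sequences[target][pos - 1 : pos - 1 + len(mi_seq)]
            assert window == revcomp(mi_seq)

    def test_planted_trans_stretch_at_least_requested(self, zero_noise_sim):
        sim = zero_noise_sim
        for lnc, mrna, slen in sim.truth.planted_trans_pairs:
            hits = trans_duplex_scan(
                sim.sequences[lnc], sim.sequences[mrna],
                min_stretch=10, energy_cutoff=0.0,
            )
            assert max(h.stretch_len for h in hits) >= slen

    def test_mature_mirnas_are_21_to_23_nt(self, zero_noise_sim):
        for r in zero_noise_sim.records_by_class("miRNA"):
            assert 21 <= len(zero_noise_sim.sequences[r.transcript_id]) <= 23

    def test_random_mirna_rarely_hits_random_target(self):
        # Monte-Carlo negative control at default thresholds
        rng = np.random.default_rng(55)
        letters = np.array(list("ACGT"))
        n_with_site = 0
        for _ in range(200):
            mi = "".join(letters[rng.integers(0, 4, 22)])
            target = "".join(letters[rng.integers(0, 4, 1000)])
            if mirna_scan(mi, target):
                n_with_site += 1
        assert n_with_site <= 10  # >= 95% of scans site-free


class TestCounts:
    def test_shapes_and_nonnegativity(self, zero_noise_sim):
        cfg = zero_noise_sim.config
        for mat, n in ((zero_noise_sim.mrna, cfg.n_mrna),
                       (zero_noise_sim.mirna, cfg.n_mirna),
                       (zero_noise_sim.lncrna, cfg.n_lncrna)):
            assert mat.counts.shape == (n, 2 * cfg.reps_per_group)
            assert (mat.counts.values >= 0).all()
            assert np.issubdtype(mat.counts.values.dtype, np.integer)

    def test_zero_noise_replicates_identical(self):
        cfg = SimConfig(n_mrna=30, n_lncrna=5, n_mirna=5, n_triplets=0,
                        n_trans_pairs=0, cis_pair_distances=(),
                        planted_de_fraction=0.0, nb_dispersion=0.0, seed=5)
        truth = TruthSet()
        mrna, _, _ = generate_counts(cfg, truth)
        a = mrna.counts[["A1", "A2", "A3"]].to_numpy()
        b = mrna.counts[["B1", "B2", "B3"]].to_numpy()
        assert (a == a[:, :1]).all() and (b == b[:, :1]).all()

    def test_zero_noise_triplet_correlation_signs_are_exact(self, zero_noise_sim):
        sim = zero_noise_sim
        expr = {**{f: sim.mrna.counts.loc[f] for f in sim.mrna.counts.index},
                **{f: sim.mirna.counts.loc[f] for f in sim.mirna.counts.index},
                **{f: sim.lncrna.counts.loc[f] for f in sim.lncrna.counts.index}}
        for m, mi, l in sim.truth.planted_triplets:
            r_ml = pearson(expr[m], expr[l])[0]
            r_mim = pearson(expr[mi], expr[m])[0]
            r_mil = pearson(expr[mi], expr[l])[0]
            assert r_ml == 1.0
            assert r_mim == -1.0
            assert r_mil == -1.0

    def test_same_seed_identical_matrices(self):
        cfg = ZERO_NOISE
        records = generate_annotation(cfg)
        truth = plan_truth(cfg, records)
        a = generate_counts(cfg, truth)
        b = generate_counts(cfg, truth)
        for x, y in zip(a, b):
            assert x.counts.equals(y.counts)


class TestTruthRoundTrip:
    def test_empty_truth(self, tmp_path):
        write_truth(TruthSet(), tmp_path / "t.json")
        assert read_truth(tmp_path / "t.json") == TruthSet()

    def test_round_trip_identity(self, tmp_path, zero_noise_sim):
        truth = zero_noise_sim.truth
        write_truth(truth, tmp_path / "t.json")
        assert read_truth(tmp_path / "t.json") == truth

    def test_triplet_count_matches_config(self, zero_noise_sim):
        assert len(zero_noise_sim.truth.planted_triplets) == ZERO_NOISE.n_triplets

    def test_truth_ids_exist_and_sites_complete(self, zero_noise_sim):
        zero_noise_sim.truth.validate(zero_noise_sim.records)
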