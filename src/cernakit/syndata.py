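"""Synthetic two-group RNA-seq data with planted ceRNA ground truth.

Emulates the statistical structure of a two-breed, three-replicate ovary
transcriptome comparison so that every downstream stage — differential
expression, lncRNA filtering, binding prediction, co-expression networks,
cis/trans assignment, and triplet assembly — can be validated against a
known truth without any external downloads:

* negative-binomial counts (var = mu + alpha * mu^2) with per-sample
  depth factors; alpha = 0 degenerates to deterministic means so exact
  zero-noise tests are possible;
* planted differentially expressed features at a stated |log2FC|;
* planted (mRNA, miRNA, lncRNA) triplets: the miRNA shifted in one
  group, both of its targets shifted the opposite way, plus a shared
  latent factor on the mRNA and lncRNA log-means so that, pooled across
  samples, r(miRNA, target) < 0 and r(mRNA, lncRNA) > 0 in expectation;
* implanted binding sites: each planted target carries the exact
  reverse complement of its full miRNA, which passes any reasonable
  alignment-score/energy threshold by construction;
* planted lncRNA-mRNA trans pairs sharing an exact complementary
  stretch, and lncRNA loci placed at controlled genomic distances from
  genes to exercise the 100-kb cis boundary.

All randomness flows from ``SimConfig.seed`` through per-stage child
generators, so each stage — and the whole simulation — is reproducible
bit for bit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .binding import revcomp
from .energy import DEFAULT_MODEL, duplex_energy
from .io_formats import (
    ExpressionMatrix,
    TranscriptRecord,
    write_counts,
    write_fasta,
    write_gtf,
)

__all__ = [
    "SimConfig",
    "TruthSet",
    "SimResult",
    "generate_annotation",
    "plan_truth",
    "generate_sequences",
    "generate_counts",
    "write_truth",
    "read_truth",
    "simulate",
]

# Chromosome layout: one slot per gene keeps every cis-placed lncRNA well
# clear of the next gene even at the largest tested distance.
_GENE_SLOT_BP = 400_000
_MIN_DG_PLANTED_SITE = -35.0  # kcal/mol; guarantees planted sites clear -30
_LATENT_SD_LOG2 = 0.35  # shared mRNA/lncRNA latent factor, log2 units


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic generator.

    Defaults describe the validation conditions used throughout the test
    suite: 600 mRNAs, 150 lncRNAs, 80 miRNAs, two groups of three
    replicates, 20% planted DE per class at |log2FC| = 3, 30 planted
    ceRNA triplets, NB dispersion 0.05, and cis lncRNA placements
    straddling the 100-kb window boundary.
    """

    n_mrna: int = 600
    n_lncrna: int = 150
    n_mirna: int = 80
    reps_per_group: int = 3
    planted_de_fraction: float = 0.2
    planted_lfc: float = 3.0
    n_triplets: int = 30
    nb_dispersion: float = 0.05
    mean_count_log_range: tuple[float, float] = (1.5, 3.5)  # log10 NB mean
    genome_n_chroms: int = 3
    cis_pair_distances: tuple[int, ...] = (0, 50_000, 100_000, 100_001, 150_000)
    n_trans_pairs: int = 5
    trans_stretch_len: int = 80
    chrom_length_bp: int | None = None  # None = auto-size
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_mrna", "n_lncrna", "n_mirna", "reps_per_group",
                     "genome_n_chroms"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.reps_per_group < 2:
            raise ValueError("reps_per_group must be >= 2 (Pearson p needs n >= 3)")
        if 2 * self.reps_per_group < 4:
            warnings.warn("pooled sample size < 4; correlations will be fragile")
        if not 0.0 <= self.planted_de_fraction <= 1.0:
            raise ValueError("planted_de_fraction must lie in [0, 1]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.n_triplets > min(self.n_mrna, self.n_lncrna, self.n_mirna):
            raise ValueError("n_triplets exceeds the smallest feature class")
        if self.trans_stretch_len < 15:
            raise ValueError("trans_stretch_len must be >= 15")
        lo, hi = self.mean_count_log_range
        if not lo < hi:
            raise ValueError("mean_count_log_range must be an increasing interval")

    # Deterministic feature naming -----------------------------------------
    def mrna_ids(self) -> list[str]:
        return [f"M{i:04d}" for i in range(1, self.n_mrna + 1)]

    def lncrna_ids(self) -> list[str]:
        return [f"L{i:04d}" for i in range(1, self.n_lncrna + 1)]

    def mirna_ids(self) -> list[str]:
        return [f"R{i:04d}" for i in range(1, self.n_mirna + 1)]

    def sample_ids(self) -> list[str]:
        return [f"A{i}" for i in range(1, self.reps_per_group + 1)] + [
            f"B{i}" for i in range(1, self.reps_per_group + 1)
        ]

    def group_of(self) -> dict[str, str]:
        return {s: s[0] for s in self.sample_ids()}

    def _rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stage])


@dataclass
class TruthSet:
    """Planted ground truth for recovery experiments.

    ``de_features`` maps feature id to its signed log2 fold change
    (group A relative to group B); positive = higher in A.
    """

    de_features: dict[str, float] = field(default_factory=dict)
    planted_triplets: list[tuple[str, str, str]] = field(default_factory=list)
    planted_sites: list[tuple[str, str, int]] = field(default_factory=list)
    planted_trans_pairs: list[tuple[str, str, int]] = field(default_factory=list)
    cis_pair_truth: list[tuple[str, str, int]] = field(default_factory=list)

    def validate(self, records: Sequence[TranscriptRecord]) -> None:
        known = {r.transcript_id for r in records} | {r.gene_id for r in records}
        referenced = set(self.de_features)
        for m, mi, l in self.planted_triplets:
            referenced |= {m, mi, l}
        for mi, t, _ in self.planted_sites:
            referenced |= {mi, t}
        for l, m, _ in self.planted_trans_pairs:
            referenced |= {l, m}
        for l, g, _ in self.cis_pair_truth:
            referenced |= {l, g}
        unknown = referenced - known
        if unknown:
            raise ValueError(f"truth references unknown ids: {sorted(unknown)[:5]}")
        sited = {(mi, t) for mi, t, _ in self.planted_sites}
        for m, mi, l in self.planted_triplets:
            if (mi, m) not in sited or (mi, l) not in sited:
                raise ValueError(f"triplet ({m}, {mi}, {l}) lacks a planted site")


@dataclass
class SimResult:
    """Everything one simulation produced, in memory."""

    config: SimConfig
    records: list[TranscriptRecord]
    truth: TruthSet
    sequences: dict[str, str]
    mrna: ExpressionMatrix
    mirna: ExpressionMatrix
    lncrna: ExpressionMatrix

    def records_by_class(self, biotype: str) -> list[TranscriptRecord]:
        return [r for r in self.records if r.biotype == biotype]


# ---------------------------------------------------------------------------
# Annotation


def generate_annotation(config: SimConfig) -> list[TranscriptRecord]:
    """Place genes, lncRNA loci and miRNA loci on synthetic chromosomes.

    The first ``len(cis_pair_distances)`` lncRNAs are placed at exactly
    those distances from the first mRNA genes (distance measured between
    interval ends; 0 means overlapping). Every mRNA has 1-3 exons; every
    lncRNA has >= 2 exons and spliced length > 200 nt.
    """
    rng = config._rng(0)
    chroms = [f"chr{i + 1}" for i in range(config.genome_n_chroms)]
    cursor = {c: 1 for c in chroms}
    records: list[TranscriptRecord] = []

    def _exon_layout(start: int, exon_lens: list[int], rng) -> tuple[tuple[int, int], ...]:
        exons = []
        pos = start
        for i, el in enumerate(exon_lens):
            exons.append((pos, pos + el - 1))
            pos += el + (int(rng.integers(100, 2000)) if i < len(exon_lens) - 1 else 0)
        return tuple(exons)

    def _place(chrom: str, tid: str, gid: str, biotype: str,
               exon_lens: list[int], start: int | None = None) -> TranscriptRecord:
        s = cursor[chrom] if start is None else start
        exons = _exon_layout(s, exon_lens, rng)
        rec = TranscriptRecord(
            transcript_id=tid,
            gene_id=gid,
            biotype=biotype,
            chrom=chrom,
            strand="+" if rng.random() < 0.5 else "-",
            start=exons[0][0],
            end=exons[-1][1],
            exons=exons,
        )
        if start is None:
            cursor[chrom] = rec.start + _GENE_SLOT_BP
        records.append(rec)
        return rec

    def _split_length(total: int, n_exons: int) -> list[int]:
        if n_exons == 1:
            return [total]
        cuts = np.sort(rng.integers(50, total - 50, size=n_exons - 1))
        # ensure each exon gets >= 30 nt by re-drawing degenerate splits
        lens = np.diff(np.concatenate([[0], cuts, [total]]))
        while (lens < 30).any():
            cuts = np.sort(rng.integers(50, total - 50, size=n_exons - 1))
            lens = np.diff(np.concatenate([[0], cuts, [total]]))
        return [int(x) for x in lens]

    mrna_records = []
    for i, tid in enumerate(config.mrna_ids()):
        chrom = chroms[i % len(chroms)]
        total = int(rng.integers(500, 1501))
        n_ex = int(rng.integers(1, 4))
        mrna_records.append(
            _place(chrom, tid, f"G{tid}", "mRNA", _split_length(total, n_ex))
        )

    n_cis = len(config.cis_pair_distances)
    if n_cis > min(config.n_lncrna, config.n_mrna):
        raise ValueError("more cis distances than available lncRNAs/genes")
    for j, (lid, d) in enumerate(
        zip(config.lncrna_ids()[:n_cis], config.cis_pair_distances)
    ):
        gene = mrna_records[j]
        total = int(rng.integers(300, 1001))
        n_ex = int(rng.integers(2, 4))
        if d == 0:
            start = gene.start + 5  # overlapping => distance 0
        else:
            start = gene.end + d
        _place(gene.chrom, lid, f"G{lid}", "lncRNA", _split_length(total, n_ex), start=start)

    for lid in config.lncrna_ids()[n_cis:]:
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        total = int(rng.integers(300, 1001))
        n_ex = int(rng.integers(2, 4))
        _place(chrom, lid, f"G{lid}", "lncRNA", _split_length(total, n_ex))

    for rid in config.mirna_ids():
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        mature_len = int(rng.integers(21, 24))
        _place(chrom, rid, f"G{rid}", "miRNA", [mature_len])

    if config.chrom_length_bp is not None:
        for c in chroms:
            used = max((r.end for r in records if r.chrom == c), default=0)
            if used > config.chrom_length_bp:
                raise ValueError(
                    f"chromosome {c} too short ({config.chrom_length_bp} bp) to "
                    f"host requested features (needs {used} bp)"
                )
    return records


# ---------------------------------------------------------------------------
# Truth planning


def plan_truth(config: SimConfig, records: Sequence[TranscriptRecord]) -> TruthSet:
    """Choose DE features, triplets, binding-site positions, trans pairs
    and cis truth, consistently with the annotation."""
    rng = config._rng(1)
    by_id = {r.transcript_id: r for r in records}
    mrnas = config.mrna_ids()
    lncs = config.lncrna_ids()
    mirs = config.mirna_ids()
    n_cis = len(config.cis_pair_distances)

    truth = TruthSet()

    # Cis pairs occupy the first lncRNAs / genes by construction.
    cis_lncs = lncs[:n_cis]
    cis_genes = mrnas[:n_cis]
    for lid, gid, d in zip(cis_lncs, cis_genes, config.cis_pair_distances):
        truth.cis_pair_truth.append((lid, gid, int(d)))

    # Triplet members: sampled without replacement, away from cis features
    # so each target carries at most one implant.
    free_m = [m for m in mrnas if m not in set(cis_genes)]
    free_l = [l for l in lncs if l not in set(cis_lncs)]
    trip_m = [free_m[i] for i in rng.choice(len(free_m), config.n_triplets, replace=False)]
    trip_l = [free_l[i] for i in rng.choice(len(free_l), config.n_triplets, replace=False)]
    trip_mi = [mirs[i] for i in rng.choice(len(mirs), config.n_triplets, replace=False)]

    # Trans pairs: disjoint from triplet and cis features.
    rem_m = [m for m in free_m if m not in set(trip_m)]
    rem_l = [l for l in free_l if l not in set(trip_l)]
    n_trans = min(config.n_trans_pairs, len(rem_m), len(rem_l))
    trans_m = [rem_m[i] for i in rng.choice(len(rem_m), n_trans, replace=False)]
    trans_l = [rem_l[i] for i in rng.choice(len(rem_l), n_trans, replace=False)]

    lfc = float(config.planted_lfc)

    def _plant(fid: str, sign: int) -> None:
        truth.de_features[fid] = sign * lfc

    for m, mi, l in zip(trip_m, trip_mi, trip_l):
        truth.planted_triplets.append((m, mi, l))
        s = 1 if rng.random() < 0.5 else -1
        _plant(mi, s)
        _plant(m, -s)
        _plant(l, -s)
        mi_len = by_id[mi].length
        for target in (m, l):
            t_len = by_id[target].length
            if t_len < mi_len + 100:
                raise ValueError(f"target {target} too short to host a planted site")
            pos = int(rng.integers(50, t_len - mi_len - 50))
            truth.planted_sites.append((mi, target, pos))

    for l, m in zip(trans_l, trans_m):
        s = 1 if rng.random() < 0.5 else -1
        _plant(l, s)
        _plant(m, s)
        truth.planted_trans_pairs.append((l, m, int(config.trans_stretch_len)))

    for lid, gid, _ in truth.cis_pair_truth:
        s = 1 if rng.random() < 0.5 else -1
        _plant(lid, s)
        _plant(gid, s)

    # Fill each class up to the planted DE fraction with plain DE features.
    for ids in (mrnas, lncs, mirs):
        want = int(round(config.planted_de_fraction * len(ids)))
        have = [f for f in ids if f in truth.de_features]
        pool = [f for f in ids if f not in truth.de_features]
        extra = max(0, want - len(have))
        for i in rng.choice(len(pool), min(extra, len(pool)), replace=False):
            _plant(pool[i], 1 if rng.random() < 0.5 else -1)

    truth.validate(records)
    return truth


# ---------------------------------------------------------------------------
# Sequences


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def generate_sequences(
    records: Sequence[TranscriptRecord],
    truth: TruthSet,
    config: SimConfig,
) -> dict[str, str]:
    """Uniform-random transcript sequences with the truth's implants.

    Planted miRNA sites are the exact reverse complement of the full
    miRNA at the recorded position; planted trans pairs share an exact
    complementary stretch of the configured length. Triplet miRNAs are
    redrawn until their perfect-duplex energy is comfortably below the
    -30 kcal/mol site threshold, so no planted site is lost to an
    AU-rich composition.
    """
    rng = config._rng(2)
    by_id = {r.transcript_id: r for r in records}
    seqs: dict[str, str] = {}

    triplet_mirnas = {mi for _, mi, _ in truth.planted_triplets}
    for rec in records:
        if rec.biotype != "miRNA":
            continue
        seq = _random_seq(rng, rec.length)
        if rec.transcript_id in triplet_mirnas:
            for _ in range(200):
                pairs = [(b + _comp(b)) for b in seq]
                if duplex_energy(pairs, DEFAULT_MODEL) <= _MIN_DG_PLANTED_SITE:
                    break
                seq = _random_seq(rng, rec.length)
        seqs[rec.transcript_id] = seq

    for rec in records:
        if rec.biotype == "miRNA":
            continue
        seqs[rec.transcript_id] = _random_seq(rng, rec.length)

    for mi, target, pos in truth.planted_sites:
        mi_seq = seqs[mi]
        t_seq = seqs[target]
        if pos - 1 + len(mi_seq) > len(t_seq):
            raise ValueError(f"planted site for {mi} exceeds {target} length")
        site = revcomp(mi_seq)
        seqs[target] = t_seq[: pos - 1] + site + t_seq[pos - 1 + len(site) :]

    for l, m, slen in truth.planted_trans_pairs:
        m_seq = seqs[m]
        l_seq = seqs[l]
        if slen > len(m_seq) or slen > len(l_seq):
            raise ValueError(f"trans stretch of {slen} nt exceeds {l} or {m}")
        m_start = int(rng.integers(0, len(m_seq) - slen + 1))
        window = m_seq[m_start : m_start + slen]
        l_start = int(rng.integers(0, len(l_seq) - slen + 1))
        seqs[l] = l_seq[:l_start] + revcomp(window) + l_seq[l_start + slen :]

    return seqs


def _comp(b: str) -> str:
    return {"A": "U", "T": "A", "G": "C", "C": "G"}[b]


# ---------------------------------------------------------------------------
# Counts


def generate_counts(
    config: SimConfig, truth: TruthSet
) -> tuple[ExpressionMatrix, ExpressionMatrix, ExpressionMatrix]:
    """Negative-binomial count matrices for mRNA, miRNA, and lncRNA.

    Planted DE features get a one-sided group-mean shift of
    2^(signed lfc) applied to group A, drawn from the upper half of the
    abundance range so pseudocounted fold-change estimates stay within
    0.1 of the planted value in the zero-noise limit. Triplet, trans and
    cis partners additionally share a per-sample latent factor on their
    log2 means (mRNA and lncRNA only), inducing positive mRNA-lncRNA and
    negative miRNA-target correlations pooled across samples. With
    nb_dispersion = 0 all noise sources (NB sampling, depth factors,
    latent factors) are switched off and counts equal rounded means.
    """
    rng = config._rng(3)
    samples = config.sample_ids()
    group_of = config.group_of()
    n_samples = len(samples)
    in_a = np.array([group_of[s] == "A" for s in samples])
    lo, hi = config.mean_count_log_range
    mid = (lo + hi) / 2.0
    alpha = float(config.nb_dispersion)
    noisy = alpha > 0

    depth = rng.uniform(0.75, 1.3, size=n_samples) if noisy else np.ones(n_samples)

    # Shared latent factors (one per planted multi-feature structure).
    latent: dict[str, np.ndarray] = {}
    for group in (
        [(m, l) for m, _, l in truth.planted_triplets]
        + [(l, m) for l, m, _ in truth.planted_trans_pairs]
        + [(l, g) for l, g, _ in truth.cis_pair_truth]
    ):
        z = rng.normal(0.0, _LATENT_SD_LOG2, size=n_samples) if noisy else np.zeros(n_samples)
        for fid in group:
            latent[fid] = latent.get(fid, 0.0) + z

    def _matrix(ids: list[str]) -> ExpressionMatrix:
        counts = np.zeros((len(ids), n_samples), dtype=np.int64)
        for i, fid in enumerate(ids):
            signed = truth.de_features.get(fid)
            if signed is None:
                base = 10.0 ** rng.uniform(lo, hi)
            else:
                base = 10.0 ** rng.uniform(mid, hi)
            log2_mean = np.full(n_samples, np.log2(base))
            if signed is not None:
                log2_mean = log2_mean + np.where(in_a, signed, 0.0)
            z = latent.get(fid)
            if z is not None:
                log2_mean = log2_mean + z
            mu = (2.0**log2_mean) * depth
            if noisy:
                size = 1.0 / alpha
                p = size / (size + mu)
                counts[i] = rng.negative_binomial(size, p)
            else:
                counts[i] = np.rint(mu).astype(np.int64)
        df = pd.DataFrame(counts, index=ids, columns=samples)
        return ExpressionMatrix(df, dict(group_of))

    return _matrix(config.mrna_ids()), _matrix(config.mirna_ids()), _matrix(
        config.lncrna_ids()
    )


# ---------------------------------------------------------------------------
# Truth round trip and orchestration


def write_truth(truth: TruthSet, path) -> None:
    payload = {
        "de_features": truth.de_features,
        "planted_triplets": [list(t) for t in truth.planted_triplets],
        "planted_sites": [list(t) for t in truth.planted_sites],
        "planted_trans_pairs": [list(t) for t in truth.planted_trans_pairs],
        "cis_pair_truth": [list(t) for t in truth.cis_pair_truth],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_truth(path) -> TruthSet:
    payload = json.loads(Path(path).read_text())
    return TruthSet(
        de_features={k: float(v) for k, v in payload["de_features"].items()},
        planted_triplets=[tuple(t) for t in payload["planted_triplets"]],
        planted_sites=[(a, b, int(c)) for a, b, c in payload["planted_sites"]],
        planted_trans_pairs=[(a, b, int(c)) for a, b, c in payload["planted_trans_pairs"]],
        cis_pair_truth=[(a, b, int(c)) for a, b, c in payload["cis_pair_truth"]],
    )


def simulate(config: SimConfig, outdir=None) -> SimResult:
    """Run all generator stages; optionally write the full file bundle.

    The bundle contains annotation.gtf, one FASTA per RNA class, one
    counts TSV per class plus a group-map sidecar, truth.json, and a
    config.yaml echo with every default filled in.
    """
    records = generate_annotation(config)
    truth = plan_truth(config, records)
    seqs = generate_sequences(records, truth, config)
    mrna, mirna, lncrna = generate_counts(config, truth)
    result = SimResult(config, records, truth, seqs, mrna, mirna, lncrna)
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_gtf(records, out / "annotation.gtf")
        for biotype, fname in (
            ("mRNA", "mrna.fa"),
            ("lncRNA", "lncrna.fa"),
            ("miRNA", "mirna.fa"),
        ):
            ids = {r.transcript_id for r in records if r.biotype == biotype}
            write_fasta({k: v for k, v in seqs.items() if k in ids}, out / fname)
        write_counts(mrna, out / "counts_mrna.tsv", out / "groups.tsv")
        write_counts(mirna, out / "counts_mirna.tsv")
        write_counts(lncrna, out / "counts_lncrna.tsv")
        write_truth(truth, out / "truth.json")
        cfg = asdict(config)
        cfg["mean_count_log_range"] = list(config.mean_count_log_range)
        cfg["cis_pair_distances"] = list(config.cis_pair_distances)
        (out / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    return result
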