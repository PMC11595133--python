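"""Readers and writers for the on-disk formats the pipeline touches.

All coordinates follow the GTF convention: 1-based, closed intervals.
Sequences are normalized to the DNA alphabet (U -> T, upper case) at parse
time so downstream scanners never have to care about RNA vs DNA spelling.
Readers validate strictly and raise rather than coerce; writers emit
deterministic output (sorted rows, fixed float formatting) so identical
inputs produce byte-identical files.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ExpressionMatrix",
    "TranscriptRecord",
    "read_gtf",
    "write_gtf",
    "read_fasta",
    "write_fasta",
    "read_counts",
    "write_counts",
    "write_edges",
    "read_edges",
    "write_triplets",
    "read_triplets",
]

BIOTYPES = {"mRNA", "lncRNA_candidate", "lncRNA", "miRNA"}

# IUPAC nucleotide one-letter codes (after U->T normalization).
_IUPAC_DNA = set("ACGTRYSWKMBDHVN")

_FLOAT_FMT = "%.6g"


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


@dataclass(frozen=True)
class TranscriptRecord:
    """A transcript-level genomic feature with its exon structure.

    ``start``/``end`` and each exon are 1-based closed genomic intervals;
    ``length`` is the spliced transcript length (sum of exon lengths).
    """

    transcript_id: str
    gene_id: str
    biotype: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start > self.end:
            raise ValueError(f"{self.transcript_id}: start > end")
        prev_end = None
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"{self.transcript_id}: exon start > end")
            if s < self.start or e > self.end:
                raise ValueError(f"{self.transcript_id}: exon outside transcript span")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"{self.transcript_id}: exons overlap or are unsorted")
            prev_end = e
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: no exons")

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass
class ExpressionMatrix:
    """A features x samples matrix of non-negative expression values.

    ``counts`` has feature ids as the index and sample ids as columns;
    ``group_of`` maps every sample to its group label (exactly two groups
    are required for differential expression).
    """

    counts: pd.DataFrame
    group_of: dict[str, str]

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate feature ids")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        if (self.counts.values < 0).any():
            raise ValueError("negative expression values")
        missing = [s for s in self.counts.columns if s not in self.group_of]
        if missing:
            raise ValueError(f"samples without group label: {missing}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def groups(self) -> list[str]:
        return sorted(set(self.group_of[s] for s in self.counts.columns))

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.counts.columns if self.group_of[s] == group]

    def subset(self, feature_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = [f for f in feature_ids if f in self.counts.index]
        return ExpressionMatrix(self.counts.loc[ids].copy(), dict(self.group_of))


# ---------------------------------------------------------------------------
# GTF

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gtf(path) -> list[TranscriptRecord]:
    """Parse a GTF file into transcript records.

    Exon lines are aggregated per transcript_id; the transcript span is the
    hull of its exons. Malformed lines raise :class:`FormatError` naming the
    offending line number.
    """
    per_tx: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"line {lineno}: expected 9 tab-separated fields")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"line {lineno}: non-integer coordinates") from None
            if end < start:
                raise FormatError(f"line {lineno}: end < start")
            if strand not in {"+", "-"}:
                raise FormatError(f"line {lineno}: unknown strand {strand!r}")
            attr = dict(_ATTR_RE.findall(attrs))
            if "transcript_id" not in attr:
                raise FormatError(f"line {lineno}: missing transcript_id attribute")
            tid = attr["transcript_id"]
            rec = per_tx.get(tid)
            if rec is None:
                per_tx[tid] = rec = {
                    "gene_id": attr.get("gene_id", tid),
                    "biotype": attr.get("biotype", "mRNA"),
                    "chrom": chrom,
                    "strand": strand,
                    "exons": [],
                }
                order.append(tid)
            if rec["chrom"] != chrom or rec["strand"] != strand:
                raise FormatError(f"line {lineno}: transcript {tid} spans chrom/strand")
            rec["exons"].append((start, end))
    records = []
    for tid in order:
        rec = per_tx[tid]
        exons = tuple(sorted(rec["exons"]))
        records.append(
            TranscriptRecord(
                transcript_id=tid,
                gene_id=rec["gene_id"],
                biotype=rec["biotype"],
                chrom=rec["chrom"],
                strand=rec["strand"],
                start=exons[0][0],
                end=exons[-1][1],
                exons=exons,
            )
        )
    return records


def write_gtf(records: Sequence[TranscriptRecord], path) -> None:
    """Write exon lines for each record, sorted by (chrom, start, id)."""
    lines = []
    for rec in sorted(records, key=lambda r: (r.chrom, r.start, r.transcript_id)):
        for s, e in rec.exons:
            attrs = (
                f'gene_id "{rec.gene_id}"; transcript_id "{rec.transcript_id}"; '
                f'biotype "{rec.biotype}";'
            )
            lines.append(
                f"{rec.chrom}\tcernakit\texon\t{s}\t{e}\t.\t{rec.strand}\t.\t{attrs}"
            )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence map.

    Sequences are upper-cased with U normalized to T. Duplicate ids, empty
    sequences, and non-IUPAC characters are rejected.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"duplicate FASTA id {rec.id!r}")
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise FormatError(f"empty sequence for {rec.id!r}")
        bad = set(seq) - _IUPAC_DNA
        if bad:
            raise FormatError(f"non-IUPAC characters {sorted(bad)} in {rec.id!r}")
        seqs[rec.id] = seq
    return seqs


def write_fasta(seqs: Mapping[str, str], path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seqs[name]), id=name, description="") for name in sorted(seqs)
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Count matrices


def read_counts(path, groups_path) -> ExpressionMatrix:
    """Read a counts TSV (feature rows, sample columns) plus a group map TSV.

    The group map has columns ``sample`` and ``group``; its sample set must
    equal the matrix columns exactly.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise FormatError("missing values in count matrix")
    if (df.values < 0).any():
        raise FormatError("negative values in count matrix")
    gmap = pd.read_csv(groups_path, sep="\t")
    if not {"sample", "group"}.issubset(gmap.columns):
        raise FormatError("group map needs columns 'sample' and 'group'")
    group_of = dict(zip(gmap["sample"].astype(str), gmap["group"].astype(str)))
    matrix_samples = set(map(str, df.columns))
    if matrix_samples != set(group_of):
        raise FormatError(
            "sample set mismatch between count matrix and group map: "
            f"{sorted(matrix_samples ^ set(group_of))}"
        )
    return ExpressionMatrix(df, group_of)


def write_counts(matrix: ExpressionMatrix, path, groups_path=None) -> None:
    matrix.counts.to_csv(path, sep="\t")
    if groups_path is not None:
        pd.DataFrame(
            {
                "sample": list(matrix.counts.columns),
                "group": [matrix.group_of[s] for s in matrix.counts.columns],
            }
        ).to_csv(groups_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Tabular results (edges, triplets, generic)


def _write_table(df: pd.DataFrame, path, sort_cols: list[str]) -> None:
    df = df.copy()
    if sort_cols and len(df):
        df = df.sort_values(sort_cols, kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_edges(edges, path) -> None:
    """Write correlation edges as a TSV, sorted by (id_a, id_b)."""
    rows = [
        {
            "id_a": e.id_a,
            "id_b": e.id_b,
            "class_pair": e.class_pair,
            "r": e.r,
            "p": e.p,
            "required_sign": e.required_sign,
        }
        for e in edges
    ]
    df = pd.DataFrame(rows, columns=["id_a", "id_b", "class_pair", "r", "p", "required_sign"])
    _write_table(df, path, ["id_a", "id_b"])


def read_edges(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_triplets(triplets, path) -> None:
    """Write ceRNA triplets as a TSV, sorted by descending score then ids."""
    rows = [
        {
            "mrna_id": t.mrna_id,
            "mirna_id": t.mirna_id,
            "lncrna_id": t.lncrna_id,
            "r_mrna_lncrna": t.r_mrna_lncrna,
            "r_mirna_mrna": t.r_mirna_mrna,
            "r_mirna_lncrna": t.r_mirna_lncrna,
            "cerna_score": t.cerna_score,
        }
        for t in triplets
    ]
    cols = [
        "mrna_id",
        "mirna_id",
        "lncrna_id",
        "r_mrna_lncrna",
        "r_mirna_mrna",
        "r_mirna_lncrna",
        "cerna_score",
    ]
    df = pd.DataFrame(rows, columns=cols)
    if len(df):
        df = df.sort_values(
            ["cerna_score", "mrna_id", "mirna_id", "lncrna_id"],
            ascending=[False, True, True, True],
            kind="mergesort",
        )
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_triplets(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
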