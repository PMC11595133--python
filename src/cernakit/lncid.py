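"""lncRNA candidate filtering and coding-potential verdict intersection.

Candidate lncRNAs are transcripts longer than 200 nt (strict) with at
least two exons. Coding potential is decided by intersecting four
per-tool non-coding verdicts (CPC2, CNCI, PLEK, Pfam in the standard
workflow): a transcript is retained as non-coding only when all four
tools agree. The verdicts are consumed as a table, not computed — for
self-contained runs an ORF-length heuristic can fill all four slots.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import TranscriptRecord

__all__ = [
    "PREDICTORS",
    "CodingVerdictTable",
    "filter_candidates",
    "intersect_verdicts",
    "orf_coding_heuristic",
    "longest_orf_codons",
    "verdicts_from_heuristic",
    "identify_lncrnas",
]

PREDICTORS = ("cpc2", "cnci", "plek", "pfam")

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class CodingVerdictTable:
    """Per-transcript non-coding verdicts from four predictors.

    ``verdicts[tid][tool]`` is True when the tool predicts *non-coding*.
    Every transcript must carry all four slots.
    """

    verdicts: dict[str, dict[str, bool]]

    def __post_init__(self) -> None:
        for tid, v in self.verdicts.items():
            if set(v) != set(PREDICTORS):
                raise ValueError(
                    f"{tid}: verdict slots {sorted(v)} != {sorted(PREDICTORS)}"
                )

    @classmethod
    def from_tsv(cls, path) -> "CodingVerdictTable":
        df = pd.read_csv(path, sep="\t")
        need = {"transcript_id", *PREDICTORS}
        if not need.issubset(df.columns):
            raise ValueError(f"verdict table needs columns {sorted(need)}")
        if df["transcript_id"].duplicated().any():
            raise ValueError("duplicate transcript ids in verdict table")
        verdicts = {
            str(row.transcript_id): {tool: bool(getattr(row, tool)) for tool in PREDICTORS}
            for row in df.itertuples()
        }
        return cls(verdicts)

    def to_tsv(self, path) -> None:
        rows = [
            {"transcript_id": tid, **{t: int(v[t]) for t in PREDICTORS}}
            for tid, v in sorted(self.verdicts.items())
        ]
        pd.DataFrame(rows, columns=["transcript_id", *PREDICTORS]).to_csv(
            path, sep="\t", index=False
        )


def filter_candidates(transcripts: Iterable[TranscriptRecord]) -> list[TranscriptRecord]:
    """Keep transcripts with spliced length > 200 nt and >= 2 exons."""
    return [t for t in transcripts if t.length > 200 and t.n_exons >= 2]


def intersect_verdicts(table: CodingVerdictTable) -> set[str]:
    """Transcripts every one of the four predictors calls non-coding."""
    return {
        tid
        for tid, v in table.verdicts.items()
        if all(v[tool] for tool in PREDICTORS)
    }


def longest_orf_codons(sequence: str) -> int:
    """Length in codons (ATG included, stop excluded) of the longest
    ATG-to-stop open reading frame over the three forward frames.

    Open-ended runs without a stop codon do not count as ORFs.
    """
    seq = sequence.upper().replace("U", "T")
    if not seq:
        raise ValueError("empty sequence")
    best = 0
    for frame in range(3):
        start = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if codon in _STOPS:
                if start is not None:
                    best = max(best, (i - start) // 3)
                    start = None
            elif codon == "ATG" and start is None:
                start = i
    return best


def orf_coding_heuristic(sequence: str, min_orf_codons: int = 100) -> bool:
    """Heuristic coding-potential verdict; True means *non-coding*.

    A transcript is called non-coding iff its longest forward-frame ORF
    is shorter than ``min_orf_codons`` codons (an ORF of exactly the
    threshold length is coding).
    """
    return longest_orf_codons(sequence) < min_orf_codons


def verdicts_from_heuristic(
    sequences: Mapping[str, str], min_orf_codons: int = 100
) -> CodingVerdictTable:
    """Fill all four verdict slots identically from the ORF heuristic."""
    return CodingVerdictTable(
        {
            tid: {tool: orf_coding_heuristic(seq, min_orf_codons) for tool in PREDICTORS}
            for tid, seq in sequences.items()
        }
    )


def identify_lncrnas(
    transcripts: Sequence[TranscriptRecord],
    sequences: Mapping[str, str],
    verdict_table: CodingVerdictTable | None = None,
    exclude_ids: Iterable[str] = (),
    min_orf_codons: int = 100,
) -> list[TranscriptRecord]:
    """Full identification: candidate filter, then verdict intersection.

    ``exclude_ids`` optionally removes already-annotated transcripts
    before the coding-potential step.
    """
    exclude = set(exclude_ids)
    candidates = [t for t in filter_candidates(transcripts) if t.transcript_id not in exclude]
    if verdict_table is None:
        missing = [t.transcript_id for t in candidates if t.transcript_id not in sequences]
        if missing:
            raise ValueError(f"no sequence for candidates: {missing[:5]}")
        verdict_table = verdicts_from_heuristic(
            {t.transcript_id: sequences[t.transcript_id] for t in candidates},
            min_orf_codons,
        )
    noncoding = intersect_verdicts(verdict_table)
    return [t for t in candidates if t.transcript_id in noncoding]
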