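"""End-to-end ceRNA network inference on a simulated or loaded dataset.

The stages mirror the standard two-group ceRNA workflow: differential
expression per RNA class; lncRNA identification (candidate filter +
coding-potential verdict intersection); miRNA binding-site and
lncRNA-mRNA duplex scanning over the differential sets; sign-constrained
co-expression networks on log2 normalized expression; cis/trans lncRNA
target assignment; and triplet assembly. Correlations pool all samples
from both groups; the network universe is the differential features
(lift with ``all_features=True``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import binding, diffexpr, lncid, network
from .io_formats import (
    ExpressionMatrix,
    TranscriptRecord,
    write_counts,
    write_edges,
    write_triplets,
)
from .syndata import SimConfig, SimResult, simulate

__all__ = ["AnalysisParams", "AnalysisResult", "analyze", "run_pipeline"]


@dataclass(frozen=True)
class AnalysisParams:
    """Decision thresholds for every stage, at their field defaults."""

    p_threshold: float = 0.05
    lfc_threshold: float = 1.0
    r_threshold: float = 0.8
    corr_p_threshold: float = 0.05
    s_min: float = 150.0
    dg_max: float = -30.0
    strict_seed: bool = True
    min_stretch: int = 10
    trans_energy_cutoff: float = -100.0
    cis_window_bp: int = 100_000
    score_min: float | None = None
    all_features: bool = False
    min_orf_codons: int = 100


@dataclass
class AnalysisResult:
    de_mrna: pd.DataFrame
    de_mirna: pd.DataFrame
    de_lncrna: pd.DataFrame
    identified_lncrnas: list[str]
    sites: list[binding.BindingSite]
    duplex_hits: list[binding.DuplexHit]
    mirna_mrna_edges: list[network.CorrelationEdge]
    mirna_lncrna_edges: list[network.CorrelationEdge]
    mrna_lncrna_edges: list[network.CorrelationEdge]
    cis: list[tuple[str, str, int, int]]
    trans: list[tuple[str, str]]
    triplets: list[network.CeRNATriplet]

    def de_ids(self, table: pd.DataFrame) -> list[str]:
        return list(table.loc[table["direction"] != "ns", "feature_id"])


def _log_expression(matrix: ExpressionMatrix) -> pd.DataFrame:
    """log2(size-factor-normalized count + 1), the correlation input."""
    return np.log2(diffexpr.normalized_counts(matrix) + 1.0)


def analyze(sim: SimResult, params: AnalysisParams = AnalysisParams()) -> AnalysisResult:
    """Run the full inference chain on one simulated dataset."""
    de_m = diffexpr.de_test(sim.mrna, params.p_threshold, params.lfc_threshold)
    de_mi = diffexpr.de_test(sim.mirna, params.p_threshold, params.lfc_threshold)
    de_l = diffexpr.de_test(sim.lncrna, params.p_threshold, params.lfc_threshold)

    lnc_records = sim.records_by_class("lncRNA")
    identified = lncid.identify_lncrnas(
        lnc_records, sim.sequences, min_orf_codons=params.min_orf_codons
    )
    identified_ids = [r.transcript_id for r in identified]

    def _sig(table: pd.DataFrame) -> list[str]:
        return list(table.loc[table["direction"] != "ns", "feature_id"])

    if params.all_features:
        mrna_ids = list(sim.mrna.counts.index)
        mirna_ids = list(sim.mirna.counts.index)
        lnc_ids = [i for i in sim.lncrna.counts.index if i in set(identified_ids)]
    else:
        mrna_ids = _sig(de_m)
        mirna_ids = _sig(de_mi)
        lnc_ids = [i for i in _sig(de_l) if i in set(identified_ids)]

    expr_m = _log_expression(sim.mrna).loc[mrna_ids]
    expr_mi = _log_expression(sim.mirna).loc[mirna_ids]
    expr_l = _log_expression(sim.lncrna).loc[lnc_ids]

    mi_seqs = {i: sim.sequences[i] for i in mirna_ids}
    m_seqs = {i: sim.sequences[i] for i in mrna_ids}
    l_seqs = {i: sim.sequences[i] for i in lnc_ids}

    sites = binding.scan_many(
        mi_seqs,
        {**m_seqs, **l_seqs},
        s_min=params.s_min,
        dg_max=params.dg_max,
        strict_seed=params.strict_seed,
    )

    duplex_hits: list[binding.DuplexHit] = []
    for lid in sorted(l_seqs):
        for mid in sorted(m_seqs):
            duplex_hits.extend(
                binding.trans_duplex_scan(
                    l_seqs[lid],
                    m_seqs[mid],
                    min_stretch=params.min_stretch,
                    energy_cutoff=params.trans_energy_cutoff,
                    lncrna_id=lid,
                    mrna_id=mid,
                )
            )

    kwargs = dict(r_threshold=params.r_threshold, p_threshold=params.corr_p_threshold)
    e_mi_m = network.coexpression_edges(expr_mi, expr_m, "miRNA-mRNA", "negative", **kwargs)
    e_mi_l = network.coexpression_edges(expr_mi, expr_l, "miRNA-lncRNA", "negative", **kwargs)
    e_m_l = network.coexpression_edges(expr_m, expr_l, "mRNA-lncRNA", "positive", **kwargs)
    # cis/trans assignment uses |r| without a sign constraint
    e_l_m_any = network.coexpression_edges(expr_l, expr_m, "mRNA-lncRNA", "any", **kwargs)

    mm = network.mirna_target_edges(e_mi_m, sites)
    ml = network.mirna_target_edges(e_mi_l, sites)

    records_by_id = {r.transcript_id: r for r in sim.records}
    cis = network.cis_pairs(
        [records_by_id[i] for i in lnc_ids if i in records_by_id],
        [records_by_id[i] for i in mrna_ids if i in records_by_id],
        e_l_m_any,
        window_bp=params.cis_window_bp,
    )
    trans = network.trans_pairs(duplex_hits, e_l_m_any)

    triplets = network.assemble_triplets(
        mm, ml, e_m_l, sites=sites, score_min=params.score_min
    )

    return AnalysisResult(
        de_mrna=de_m,
        de_mirna=de_mi,
        de_lncrna=de_l,
        identified_lncrnas=identified_ids,
        sites=sites,
        duplex_hits=duplex_hits,
        mirna_mrna_edges=mm,
        mirna_lncrna_edges=ml,
        mrna_lncrna_edges=e_m_l,
        cis=cis,
        trans=trans,
        triplets=triplets,
    )


def _write_results(res: AnalysisResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    fmt = dict(sep="\t", index=False, float_format="%.6g")
    res.de_mrna.to_csv(outdir / "de_mrna.tsv", **fmt)
    res.de_mirna.to_csv(outdir / "de_mirna.tsv", **fmt)
    res.de_lncrna.to_csv(outdir / "de_lncrna.tsv", **fmt)
    pd.DataFrame({"transcript_id": sorted(res.identified_lncrnas)}).to_csv(
        outdir / "identified_lncrnas.tsv", **fmt
    )
    pd.DataFrame(
        [
            {
                "mirna_id": s.mirna_id,
                "target_id": s.target_id,
                "target_start": s.target_start,
                "target_end": s.target_end,
                "align_score": s.align_score,
                "delta_g": s.delta_g,
                "seed_perfect": int(s.seed_perfect),
            }
            for s in sorted(res.sites, key=lambda s: (s.mirna_id, s.target_id, s.target_start))
        ],
        columns=[
            "mirna_id", "target_id", "target_start", "target_end",
            "align_score", "delta_g", "seed_perfect",
        ],
    ).to_csv(outdir / "sites.tsv", **fmt)
    pd.DataFrame(
        [
            {
                "lncrna_id": h.lncrna_id,
                "mrna_id": h.mrna_id,
                "lnc_start": h.lnc_start,
                "lnc_end": h.lnc_end,
                "mrna_start": h.mrna_start,
                "mrna_end": h.mrna_end,
                "stretch_len": h.stretch_len,
                "energy": h.energy,
            }
            for h in sorted(res.duplex_hits, key=lambda h: (h.lncrna_id, h.mrna_id, h.lnc_start))
        ],
        columns=[
            "lncrna_id", "mrna_id", "lnc_start", "lnc_end",
            "mrna_start", "mrna_end", "stretch_len", "energy",
        ],
    ).to_csv(outdir / "duplex.tsv", **fmt)
    write_edges(res.mirna_mrna_edges, outdir / "edges_mirna_mrna.tsv")
    write_edges(res.mirna_lncrna_edges, outdir / "edges_mirna_lncrna.tsv")
    write_edges(res.mrna_lncrna_edges, outdir / "edges_mrna_lncrna.tsv")
    pd.DataFrame(
        res.cis, columns=["lncrna_id", "gene_id", "distance_bp", "signed_distance_bp"]
    ).to_csv(outdir / "cis_pairs.tsv", **fmt)
    pd.DataFrame(res.trans, columns=["lncrna_id", "mrna_id"]).to_csv(
        outdir / "trans_pairs.tsv", **fmt
    )
    write_triplets(res.triplets, outdir / "triplets.tsv")


def run_pipeline(
    config: SimConfig,
    outdir=None,
    params: AnalysisParams = AnalysisParams(),
) -> tuple[SimResult, AnalysisResult]:
    """Simulate one dataset and analyze it; optionally write all outputs.

    With ``outdir`` set, both the simulation bundle (under ``sim/``) and
    the analysis tables (under ``results/``) are written; identical
    config and seed reproduce every file byte for byte.
    """
    if outdir is not None:
        outdir = Path(outdir)
        sim = simulate(config, outdir / "sim")
    else:
        sim = simulate(config)
    res = analyze(sim, params)
    if outdir is not None:
        _write_results(res, outdir / "results")
    return sim, res
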