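"""Predict miRNA binding sites and lncRNA-mRNA trans duplexes.

A miRNA site needs alignment score S >= 150, duplex energy <= -30
kcal/mol, and strict Watson-Crick seed pairing (miRNA positions 2-8).
A trans interaction needs a complementary stretch of >= 10 bp below the
energy cutoff.
"""

from cernakit.binding import mirna_scan, revcomp, trans_duplex_scan

mirna = "TGAGGTAGTAGGTTGTATAGTT"  # a let-7 family mature sequence
target = (
    "CCAGGAAGCTGGTTTCATATGGTGGTTTAGATTTAAATAGTGATTGTCTAGCACCATCT"
    + revcomp(mirna)  # a perfect response element
    + "GATTACCTTGGATGTTCTGACCTTTTTCCACAGCTGGTTG"
)

sites = mirna_scan(mirna, target, mirna_id="let-7", target_id="demo-3UTR")
for s in sites:
    print(
        f"site at {s.target_start}-{s.target_end}: S={s.align_score:.0f}, "
        f"dG={s.delta_g:.1f} kcal/mol, strict seed={s.seed_perfect}"
    )
# S is the seed-weighted complementarity alignment score; dG is the
# nearest-neighbor free energy of the predicted duplex.

mrna = "GCTAGCTAGGATCCGATTTACGCGGCATTAGCCGGAAGTCCTGAGGACTAATGCCATGC"
lnc = "TTTTTTTT" + revcomp(mrna[10:40]) + "AAAAAAAA"  # 30-bp complementary stretch
hits = trans_duplex_scan(lnc, mrna, min_stretch=10, energy_cutoff=-30.0,
                         lncrna_id="demo-lnc", mrna_id="demo-mrna")
for h in hits:
    print(
        f"trans duplex: lnc {h.lnc_start}-{h.lnc_end} vs mRNA "
        f"{h.mrna_start}-{h.mrna_end}, {h.stretch_len} bp, "
        f"energy {h.energy:.1f}"
    )
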