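"""Hypergeometric over-representation of a gene set in functional terms.

Tests whether the differential genes from a simulation are over-
represented in each term of a user-supplied term -> gene map, with
Benjamini-Hochberg FDR control across terms.
"""

from cernakit.diffexpr import de_test
from cernakit.enrich import enrich
from cernakit.syndata import SimConfig, simulate

sim = simulate(SimConfig(n_mrna=400, n_lncrna=40, n_mirna=30, n_triplets=8, seed=3))
de = de_test(sim.mrna)
query = set(de.loc[de["direction"] != "ns", "feature_id"])
background = set(sim.mrna.counts.index)

# In a real analysis the term map comes from GO/KEGG annotation files;
# here one term is built around the differential genes and two are random.
ids = sorted(background)
terms = {
    "T:planted": ("planted-response genes", set(sorted(query)[:40])),
    "T:house": ("housekeeping-like set", set(ids[::7])),
    "T:misc": ("unrelated set", set(ids[3::11])),
}

for r in enrich(query, background, terms):
    print(
        f"{r.term_id:>10} {r.term_name:<24} k={r.k:<3} K={r.K:<3} "
        f"p={r.p:.3g} fdr={r.fdr:.3g} score={r.enrichment_score:.2f}"
    )
# k of K term genes appear among the n query genes (N = background);
# the enrichment score is -log10(p), larger = more over-represented.
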