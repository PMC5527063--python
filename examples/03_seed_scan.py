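"""Scan transcripts for miRNA response elements (MREs).

A site is an exact match to the reverse complement of the miRNA seed
(positions 2-8); each hit is reported with its 1-based position."""

from cernet import scan_mre
from cernet.targets import seed_site

mirnas = {"bta-miR-x": "UAGCAGCACAUAAUGGUUUGU"}
targets = {
    "GENE1-3UTR": "AAAACCCGTGCTGCTACCCAAAGGGTGCTGCTTT",  # two sites
    "LNC1": "ACGT" * 12,                                   # none
}

print("seed site to find:", seed_site(mirnas["bta-miR-x"]))
table, hits = scan_mre(mirnas, targets, {"GENE1-3UTR": "mRNA", "LNC1": "lncRNA"})
for h in hits:
    print(f"{h.mirna_id} -> {h.target_id} at {h.site_start} ({h.site_type})")
print("edges (one per targeted transcript):", [(e.mirna_id, e.target_id, e.score) for e in table])
# score on an edge = number of seed sites found in that target.
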