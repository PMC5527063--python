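"""Score lncRNA-mRNA pairs by their shared miRNA regulators.

A pair sharing c of the mRNA's n and the lncRNA's K miRNA regulators, out
of a universe of N miRNAs, gets the upper hypergeometric tail probability
P(X >= c) — small P means more sharing than random targeting explains."""

from cernet import PipelineConfig, TargetEdge, TargetEdgeTable, build_candidate_pairs
from cernet.network import HypergeomParams, hypergeom_pvalue

# direct scoring: 3 shared miRNAs out of degrees K=4 and n=5, universe 200
params = HypergeomParams(N=200, K=4, n=5, c=3)
print(f"P(X >= 3 | N=200, K=4, n=5) = {hypergeom_pvalue(params):.3g}")

# from an edge table: lnc1 and gene1 share m1+m2; lnc1-gene2 share nothing
edges = TargetEdgeTable(
    [
        TargetEdge("m1", "lnc1", "lncRNA"),
        TargetEdge("m2", "lnc1", "lncRNA"),
        TargetEdge("m1", "gene1", "mRNA"),
        TargetEdge("m2", "gene1", "mRNA"),
        TargetEdge("m3", "gene2", "mRNA"),
    ]
)
pairs = build_candidate_pairs(edges, PipelineConfig(), n_universe=100)
for p in pairs:
    print(
        f"{p.lncrna_id} ~ {p.mrna_id}: shared={sorted(p.shared_mirnas)} "
        f"c={p.params.c} K={p.params.K} n={p.params.n} N={p.params.N} "
        f"p={p.p:.3g} q={p.q:.3g}"
    )
# only pairs with >= 1 shared miRNA are candidates; the pair passes the
# conventional gate when its raw hypergeometric P < 0.05.
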