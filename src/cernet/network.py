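"""Shared-miRNA hypergeometric scoring of lncRNA-mRNA pairs, FDR
correction, and expression-trend pruning — the ceRNA network construction
itself.

A candidate ceRNA pair is a (lncRNA, mRNA) couple sharing at least one
miRNA regulator.  With N the miRNA universe, K the number of miRNAs
targeting the lncRNA, n the number targeting the mRNA and c the number
shared, the enrichment P-value is the upper hypergeometric tail

    P = sum_{i=c}^{min(K, n)}  C(K, i) * C(N-K, n-i) / C(N, n),

i.e. the probability of sharing at least c regulators if the mRNA's n
regulators were drawn uniformly from the universe.  The sum is evaluated in
log space (log-gamma binomials + log-sum-exp), which is exact to double
precision for the integer parameters arising here.

The sponge signature used for trend pruning: across the comparison's period
span the lncRNA and mRNA must move in the *same* non-flat direction while
at least one shared miRNA moves in the *opposite* direction.  Shared
miRNAs moving with their targets contradict the sponge model and are
removed from the pair's shared set before re-scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .model import DomainError, PipelineConfig, TargetEdgeTable
from .diffexpr import benjamini_hochberg

logger = logging.getLogger(__name__)

__all__ = [
    "HypergeomParams",
    "CeRNAPair",
    "hypergeom_pvalue",
    "build_candidate_pairs",
    "trend_prune",
    "summarize_network",
]


@dataclass(frozen=True)
class HypergeomParams:
    """N: miRNA universe size; n: miRNAs targeting the mRNA; K: miRNAs
    targeting the lncRNA; c: miRNAs shared by the pair."""

    N: int
    K: int
    n: int
    c: int

    def __post_init__(self) -> None:
        if not (0 <= self.K <= self.N and 0 <= self.n <= self.N):
            raise DomainError(
                f"degrees exceed universe: N={self.N}, K={self.K}, n={self.n}"
            )
        if not (0 <= self.c <= min(self.K, self.n)):
            raise DomainError(
                f"shared count c={self.c} outside [0, min(K={self.K}, n={self.n})]"
            )


@dataclass
class CeRNAPair:
    lncrna_id: str
    mrna_id: str
    shared_mirnas: frozenset[str]
    params: HypergeomParams
    p: float
    q: float | None = None
    trend_consistent: bool | None = None
    comparison: tuple[str, str] | None = None
    dropped_mirnas: frozenset[str] = frozenset()


def _log_binom(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def hypergeom_pvalue(params: HypergeomParams) -> float:
    """Upper-tail probability P(X >= c) for X ~ Hypergeom(N, K, n)."""
    N, K, n, c = params.N, params.K, params.n, params.c
    if c == 0:
        return 1.0
    i = np.arange(c, min(K, n) + 1)
    log_terms = _log_binom(K, i) + _log_binom(N - K, n - i) - _log_binom(N, n)
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def build_candidate_pairs(
    edges: TargetEdgeTable,
    config: PipelineConfig,
    n_universe: int | None = None,
    comparison: tuple[str, str] | None = None,
    keep_all: bool = False,
) -> list[CeRNAPair]:
    """Score every (lncRNA, mRNA) pair with >= 1 shared miRNA.

    ``edges`` should already be restricted to the differentially expressed
    features of ``comparison`` — degrees K and n are counted over exactly
    the miRNAs present in this table.  The universe N is resolved as
    ``config.n_total_mirnas``, else ``n_universe`` (pass the distinct-miRNA
    count of the *unrestricted* table), else this table's own miRNA count.

    Pairs are BH-corrected together and, unless ``keep_all``, filtered by
    the configured gate (raw P by default, matching the conventional rule).
    """
    N = config.n_total_mirnas or n_universe or len(edges.mirnas)
    lnc_ids = edges.targets("lncRNA")
    mrna_ids = edges.targets("mRNA")
    mirnas_of = {t: edges.mirnas_targeting(t) for t in lnc_ids + mrna_ids}
    for t, ms in mirnas_of.items():
        if len(ms) > N:
            raise DomainError(
                f"universe N={N} smaller than degree {len(ms)} of {t}"
            )
    pairs: list[CeRNAPair] = []
    for lid in lnc_ids:
        K_set = mirnas_of[lid]
        for gid in mrna_ids:
            shared = K_set & mirnas_of[gid]
            if not shared:
                continue
            params = HypergeomParams(N=N, K=len(K_set), n=len(mirnas_of[gid]), c=len(shared))
            pairs.append(
                CeRNAPair(
                    lncrna_id=lid,
                    mrna_id=gid,
                    shared_mirnas=frozenset(shared),
                    params=params,
                    p=hypergeom_pvalue(params),
                    comparison=comparison,
                )
            )
    # deterministic BH: sort by id before correcting so ties break stably
    pairs.sort(key=lambda pr: (pr.lncrna_id, pr.mrna_id))
    if pairs:
        q = benjamini_hochberg([pr.p for pr in pairs])
        for pr, qv in zip(pairs, q):
            pr.q = float(qv)
    if keep_all:
        return pairs
    if config.cerna_gate == "p":
        kept = [pr for pr in pairs if pr.p < config.cerna_alpha]
    else:
        kept = [pr for pr in pairs if pr.q is not None and pr.q < config.cerna_alpha]
    logger.info(
        "candidate pairs%s: %d scored, %d pass %s < %g (N=%d)",
        f" [{comparison[0]} vs {comparison[1]}]" if comparison else "",
        len(pairs),
        len(kept),
        config.cerna_gate,
        config.cerna_alpha,
        N,
    )
    return kept


_FLIP = {"up": "down", "down": "up", "flat": "flat"}

DirectionLookup = Callable[[str, tuple[str, str]], str]


def _resolve_lookup(
    directions: Mapping[tuple[str, tuple[str, str]], str] | DirectionLookup,
) -> DirectionLookup:
    if callable(directions):
        return directions

    def lookup(fid: str, comp: tuple[str, str]) -> str:
        try:
            return directions[(fid, comp)]
        except KeyError:
            raise KeyError(
                f"no trend direction for feature {fid!r} over comparison {comp}"
            ) from None

    return lookup


def trend_prune(
    pairs: Sequence[CeRNAPair],
    directions: Mapping[tuple[str, tuple[str, str]], str] | DirectionLookup,
    config: PipelineConfig,
) -> tuple[list[CeRNAPair], list[CeRNAPair]]:
    """Apply the sponge-pattern consistency filter.

    For each pair: shared miRNAs whose direction over the pair's comparison
    equals the common direction of both targets are removed from the shared
    set ("same expression trend" exclusion) and the pair is re-scored with
    the reduced c (by default K and n keep their original degrees — the
    dropped miRNA still targets both members; ``config.rescore == "full"``
    shrinks all three).  The pair is then kept iff the lncRNA and mRNA move
    in the same non-flat direction and at least one remaining shared miRNA
    moves opposite.

    Returns ``(kept, annotated)``: the pruned network, and every input pair
    annotated with its verdict.  q-values are re-corrected over the kept set.
    """
    lookup = _resolve_lookup(directions)
    annotated: list[CeRNAPair] = []
    for pr in pairs:
        if pr.comparison is None:
            raise DomainError(f"pair ({pr.lncrna_id}, {pr.mrna_id}) has no comparison")
        comp = pr.comparison
        d_lnc = lookup(pr.lncrna_id, comp)
        d_mrna = lookup(pr.mrna_id, comp)
        target_dir = d_lnc if d_lnc == d_mrna else None
        kept_mirnas, dropped = set(), set()
        for m in pr.shared_mirnas:
            d_m = lookup(m, comp)
            if target_dir is not None and target_dir != "flat" and d_m == target_dir:
                dropped.add(m)
            else:
                kept_mirnas.add(m)
        c_new = len(kept_mirnas)
        if config.rescore == "full":
            params = HypergeomParams(
                N=pr.params.N,
                K=pr.params.K - len(dropped),
                n=pr.params.n - len(dropped),
                c=c_new,
            )
        else:
            params = replace(pr.params, c=c_new)
        p_new = hypergeom_pvalue(params)
        consistent = (
            target_dir is not None
            and target_dir != "flat"
            and any(lookup(m, comp) == _FLIP[target_dir] for m in kept_mirnas)
        )
        annotated.append(
            replace(
                pr,
                shared_mirnas=frozenset(kept_mirnas),
                dropped_mirnas=frozenset(dropped),
                params=params,
                p=p_new,
                trend_consistent=bool(consistent),
            )
        )
    kept = [pr for pr in annotated if pr.trend_consistent and pr.params.c >= 1]
    kept.sort(key=lambda pr: (pr.comparison or ("", ""), pr.lncrna_id, pr.mrna_id))
    if kept:
        q = benjamini_hochberg([pr.p for pr in kept])
        for pr, qv in zip(kept, q):
            pr.q = float(qv)
    return kept, annotated


def summarize_network(pairs: Sequence[CeRNAPair]) -> dict:
    """Distinct-entity counts per comparison and overall."""

    def tally(subset: Sequence[CeRNAPair]) -> dict:
        return {
            "pairs": len(subset),
            "mrnas": len({p.mrna_id for p in subset}),
            "mirnas": len({m for p in subset for m in p.shared_mirnas}),
            "lncrnas": len({p.lncrna_id for p in subset}),
        }

    comps = sorted({p.comparison for p in pairs if p.comparison is not None})
    return {
        "overall": tally(pairs),
        "by_comparison": {
            "|".join(c): tally([p for p in pairs if p.comparison == c]) for c in comps
        },
    }
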