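"""Target assignment: lncRNA cis genes, lncRNA trans genes, and the
miRNA-response-element (MRE) seed scanner.

The scanner is an exact 7-mer seed matcher: a site is a perfect match in the
target to the reverse complement of miRNA positions 2-8 (the seed region).
No G:U wobble, no free-energy model, no conservation — users with real
miRanda/RNAhybrid predictions bypass the scanner entirely via the target
table reader, which is the supported path for production tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .model import (
    DesignError,
    ExpressionMatrix,
    TargetEdge,
    TargetEdgeTable,
    TranscriptRecord,
    ValidationError,
)

__all__ = [
    "MREHit",
    "cis_targets",
    "trans_targets",
    "scan_mre",
    "seed_site",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class MREHit:
    """One seed-match site; ``site_start`` is 1-based in the target, and the
    7-base window starting there equals the reverse complement of miRNA
    positions 2-8."""

    mirna_id: str
    target_id: str
    site_start: int
    site_type: str = "7mer-seed"


def _interval_gap(s1: int, e1: int, s2: int, e2: int) -> int:
    """Gap between two 1-based inclusive intervals; 0 when they overlap,
    otherwise the coordinate difference between the facing boundaries."""
    if e1 >= s2 and e2 >= s1:
        return 0
    if e1 < s2:
        return s2 - e1
    return s1 - e2


def cis_targets(
    lncrnas: Sequence[TranscriptRecord],
    genes: Sequence[TranscriptRecord],
    window_bp: int,
) -> list[tuple[str, str, int]]:
    """Coding genes within ``window_bp`` of each lncRNA on the same
    chromosome (inclusive boundary; overlap counts as distance 0).

    Returns ``(lncrna_id, gene_id, signed_distance)`` triples, the distance
    negative when the gene lies upstream (lower coordinates) of the lncRNA
    in reference orientation.  The search window is symmetric, so strand is
    irrelevant by construction.
    """
    by_chrom: dict[str, list[TranscriptRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    out: list[tuple[str, str, int]] = []
    for lnc in lncrnas:
        for g in by_chrom.get(lnc.chromosome, ()):
            gap = _interval_gap(lnc.start, lnc.end, g.start, g.end)
            if gap > window_bp:
                continue
            if gap == 0:
                dist = 0
            elif g.end < lnc.start:  # gene upstream
                dist = -gap
            else:
                dist = gap
            out.append((lnc.id, g.id, dist))
    out.sort(key=lambda t: (t[0], t[1]))
    return out


def trans_targets(
    expr_lncrna: ExpressionMatrix,
    expr_genes: ExpressionMatrix,
    min_abs_r: float,
    pseudocount: float = 1.0,
    scale: str = "log",
) -> list[tuple[str, str, float]]:
    """Co-expression (trans) gene assignment for lncRNAs.

    Pearson r is computed across all samples, by default on
    log2(abundance + pseudocount); an edge is kept iff |r| is *strictly*
    greater than ``min_abs_r``.  Zero-variance profiles have undefined r
    and yield no edge.
    """
    if expr_lncrna.sample_design != expr_genes.sample_design:
        raise DesignError("lncRNA and gene matrices have different sample designs")
    if expr_lncrna.values.shape[1] < 3:
        raise DesignError("need >= 3 samples for a correlation")
    a = expr_lncrna.values.to_numpy(dtype=float)
    b = expr_genes.values.to_numpy(dtype=float)
    if scale == "log":
        a = np.log2(a + pseudocount)
        b = np.log2(b + pseudocount)
    elif scale != "linear":
        raise ValidationError(f"unknown scale {scale!r}")
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    sa = np.sqrt((ac**2).sum(axis=1))
    sb = np.sqrt((bc**2).sum(axis=1))
    out: list[tuple[str, str, float]] = []
    lnc_ids = expr_lncrna.feature_ids
    gene_ids = expr_genes.feature_ids
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (ac @ bc.T) / np.outer(sa, sb)
    for i, lid in enumerate(lnc_ids):
        if sa[i] == 0:
            continue
        for j in np.nonzero(np.abs(r[i]) > min_abs_r)[0]:
            if sb[j] == 0 or gene_ids[j] == lid:
                continue
            out.append((lid, gene_ids[j], float(r[i, j])))
    out.sort(key=lambda t: (t[0], t[1]))
    return out


def _normalize(seq: str, name: str, min_len: int = 1) -> str:
    s = seq.upper().replace("U", "T")
    if any(ch not in "ACGT" for ch in s):
        bad = sorted({ch for ch in s if ch not in "ACGT"})
        raise ValidationError(f"{name}: non-ACGU/ACGT symbols {bad}")
    if len(s) < min_len:
        raise ValidationError(f"{name}: sequence shorter than {min_len} nt")
    return s


def seed_site(mirna_seq: str, name: str = "miRNA") -> str:
    """The 7-mer a target must contain: reverse complement (DNA alphabet)
    of miRNA positions 2-8 (1-based)."""
    s = _normalize(mirna_seq, name, min_len=8)
    seed = s[1:8]
    return seed.translate(_COMPLEMENT)[::-1]


def scan_mre(
    mirna_seqs: Mapping[str, str],
    target_seqs: Mapping[str, str],
    target_classes: Mapping[str, str] | str = "mRNA",
) -> tuple[TargetEdgeTable, list[MREHit]]:
    """Scan every target for seed sites of every miRNA.

    Returns one edge per (miRNA, target) with at least one site, plus every
    site as an :class:`MREHit` (all overlapping occurrences reported), in
    deterministic (miRNA, target, position) order.  ``target_classes`` maps
    target ids to ``mRNA``/``lncRNA`` (or one class for all).
    """
    sites = {m: seed_site(seq, m) for m, seq in mirna_seqs.items()}
    targets_norm = {t: _normalize(seq, t) for t, seq in target_seqs.items()}
    hits: list[MREHit] = []
    edges: list[TargetEdge] = []
    for m in sorted(sites):
        site = sites[m]
        for t in sorted(targets_norm):
            seq = targets_norm[t]
            pos = seq.find(site)
            found = 0
            while pos != -1:
                hits.append(MREHit(m, t, pos + 1))
                found += 1
                pos = seq.find(site, pos + 1)
            if found:
                cls = target_classes if isinstance(target_classes, str) else target_classes[t]
                edges.append(TargetEdge(m, t, cls, float(found)))
    return TargetEdgeTable(edges), hits
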