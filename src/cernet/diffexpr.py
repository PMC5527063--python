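"""Differential expression between ordered condition pairs, and trend
classification across the full period sequence.

The test behind the thresholds is a Welch two-sample t-test on
log2(abundance + pseudocount) with a per-sample variance floor — the
tools conventionally used here (Cuffdiff, edgeR) operate on read-level
data, which an abundance-matrix pipeline does not consume; the contract implemented here is
the thresholding logic, and externally computed p-values can be injected
per feature to bypass the built-in test entirely.

Class-specific significance gates:

* miRNA: raw P < ``mirna_p`` AND linear |fold change| > ``mirna_min_abs_fc``
  AND miRDeep2 score >= ``mirna_min_score`` (records without a score — known
  miRBase miRNAs — pass the score gate).
* mRNA / lncRNA: Benjamini-Hochberg q < ``gene_q``.

q-values are BH-adjusted within one pairwise comparison and one feature
class, mirroring the per-comparison reporting structure of the study design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import DesignError, DomainError, ExpressionMatrix, PipelineConfig

__all__ = [
    "DEResult",
    "TrendProfile",
    "log2_fold_change",
    "benjamini_hochberg",
    "de_test",
    "de_union",
    "classify_trend",
    "direction_between",
    "direction_table",
]

_VAR_FLOOR = 1e-8


@dataclass(frozen=True)
class DEResult:
    feature_id: str
    comparison: tuple[str, str]
    log2_fc: float
    p: float
    q: float
    is_de: bool


@dataclass(frozen=True)
class TrendProfile:
    """Per-feature direction vector across ordered conditions.

    ``directions`` has one entry per consecutive condition pair, each one of
    ``"up"``, ``"down"`` or ``"flat"`` (flat iff the |log2| change of the
    condition means is <= ``trend_epsilon``).
    """

    feature_id: str
    directions: tuple[str, ...]


def log2_fold_change(mean_a: float, mean_b: float, pseudocount: float) -> float:
    """log2((mean_b + pc) / (mean_a + pc)); antisymmetric in (a, b)."""
    if mean_a < 0 or mean_b < 0:
        raise DomainError("abundance means must be non-negative")
    if pseudocount <= 0:
        raise DomainError("pseudocount must be > 0")
    return math.log2((mean_b + pseudocount) / (mean_a + pseudocount))


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted q-values (monotone, clipped to 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise DomainError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Welch t-test along axis 1, with a variance floor so that
    identical degenerate groups give t = 0 (p = 1) instead of NaN."""
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va = np.maximum(a.var(axis=1, ddof=1), _VAR_FLOOR)
    vb = np.maximum(b.var(axis=1, ddof=1), _VAR_FLOOR)
    se2 = va / na + vb / nb
    t = (mb - ma) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, np.minimum(p, 1.0)


def de_test(
    expr: ExpressionMatrix,
    comparison: tuple[str, str],
    config: PipelineConfig,
    mirdeep2_scores: Mapping[str, float] | None = None,
    external_p: Mapping[str, float] | None = None,
) -> list[DEResult]:
    """Test every feature for differential expression between two conditions.

    ``comparison = (condition_a, condition_b)``; fold changes are reported as
    b relative to a.  ``external_p`` substitutes per-feature p-values (e.g.
    from Cuffdiff/edgeR run outside) for the built-in Welch test; BH and the
    class gates are still applied here.
    """
    cond_a, cond_b = comparison
    cols_a = expr.samples_of(cond_a)
    cols_b = expr.samples_of(cond_b)
    for cond, cols in ((cond_a, cols_a), (cond_b, cols_b)):
        if len(cols) < 2:
            raise DesignError(
                f"condition {cond!r} has {len(cols)} replicate(s); "
                "need >= 2 for a location test"
            )
    arr = expr.values.to_numpy(dtype=float)
    pc = config.pseudocount
    la = np.log2(arr[:, cols_a] + pc)
    lb = np.log2(arr[:, cols_b] + pc)
    if external_p is None:
        _, p = _welch(la, lb)
    else:
        missing = [f for f in expr.feature_ids if f not in external_p]
        if missing:
            raise DesignError(f"external p-values missing for {missing[:5]}")
        p = np.array([external_p[f] for f in expr.feature_ids], dtype=float)
    q = benjamini_hochberg(p)
    mean_a = arr[:, cols_a].mean(axis=1)
    mean_b = arr[:, cols_b].mean(axis=1)
    lfc = np.log2(mean_b + pc) - np.log2(mean_a + pc)

    results = []
    log2_fc_gate = math.log2(config.mirna_min_abs_fc)
    for i, fid in enumerate(expr.feature_ids):
        if expr.feature_class == "miRNA":
            score = None if mirdeep2_scores is None else mirdeep2_scores.get(fid)
            score_ok = score is None or score >= config.mirna_min_score
            de = bool(
                p[i] < config.mirna_p and abs(lfc[i]) > log2_fc_gate and score_ok
            )
        else:
            de = bool(q[i] < config.gene_q)
        results.append(
            DEResult(fid, comparison, float(lfc[i]), float(p[i]), float(q[i]), de)
        )
    return results


def de_union(results_by_comparison: Mapping[tuple[str, str], Sequence[DEResult]]) -> set[str]:
    """Features significant in at least one pairwise comparison — the
    "differentially expressed between at least two of the periods" set."""
    return {
        r.feature_id
        for results in results_by_comparison.values()
        for r in results
        if r.is_de
    }


def _direction(delta_log2: float, epsilon: float) -> str:
    if delta_log2 > epsilon:
        return "up"
    if delta_log2 < -epsilon:
        return "down"
    return "flat"


def classify_trend(
    expr: ExpressionMatrix, feature_id: str, config: PipelineConfig
) -> TrendProfile:
    """Direction vector over consecutive ordered conditions for one feature."""
    if feature_id not in expr.values.index:
        raise KeyError(f"unknown feature {feature_id!r}")
    means = expr.condition_means().loc[feature_id]
    pc = config.pseudocount
    dirs = []
    conds = expr.conditions
    for a, b in zip(conds[:-1], conds[1:]):
        delta = math.log2(means[b] + pc) - math.log2(means[a] + pc)
        dirs.append(_direction(delta, config.trend_epsilon))
    return TrendProfile(feature_id, tuple(dirs))


def direction_between(
    expr: ExpressionMatrix,
    feature_id: str,
    comparison: tuple[str, str],
    config: PipelineConfig,
) -> str:
    """Direction of one feature over an arbitrary (possibly non-adjacent)
    period pair, under the same epsilon rule as :func:`classify_trend`."""
    if feature_id not in expr.values.index:
        raise KeyError(f"unknown feature {feature_id!r}")
    means = expr.condition_means().loc[feature_id]
    pc = config.pseudocount
    delta = math.log2(means[comparison[1]] + pc) - math.log2(means[comparison[0]] + pc)
    return _direction(delta, config.trend_epsilon)


def direction_table(
    exprs: Sequence[ExpressionMatrix],
    comparisons: Sequence[tuple[str, str]],
    config: PipelineConfig,
) -> dict[tuple[str, tuple[str, str]], str]:
    """Directions for every (feature, comparison) across several matrices;
    the lookup the trend-pruning stage consumes."""
    out: dict[tuple[str, tuple[str, str]], str] = {}
    for expr in exprs:
        means = expr.condition_means()
        pc = config.pseudocount
        logm = np.log2(means.to_numpy(dtype=float) + pc)
        cond_idx = {c: i for i, c in enumerate(means.columns)}
        for comp in comparisons:
            delta = logm[:, cond_idx[comp[1]]] - logm[:, cond_idx[comp[0]]]
            for fid, d in zip(means.index, delta):
                out[(fid, comp)] = _direction(float(d), config.trend_epsilon)
    return out
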