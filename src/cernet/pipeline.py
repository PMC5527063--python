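"""End-to-end orchestration: lncRNA filtering -> differential expression ->
target assignment -> ceRNA scoring -> trend pruning -> reporting.

The stage boundaries are plain tables, so any stage can be replaced by an
externally computed artifact (real miRanda/RNAhybrid edges through the
target-table reader, external DE p-values through ``de_test``'s injection
hook) without touching the rest of the pipeline.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import io as cio
from .diffexpr import DEResult, de_test, de_union, direction_table
from .lncrna import RejectionLog, filter_lncrna_candidates
from .model import (
    ExpressionMatrix,
    PipelineConfig,
    TargetEdgeTable,
    TranscriptRecord,
)
from .network import CeRNAPair, build_candidate_pairs, summarize_network, trend_prune
from .targets import cis_targets, trans_targets

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "analyze", "run_from_files", "run_synthetic", "pair_recovery"]

VERSION = "0.1.0"


@dataclass
class PipelineResult:
    config: PipelineConfig
    comparisons: list[tuple[str, str]]
    de_results: dict[tuple[str, str], dict[str, list[DEResult]]]
    de_sets: dict[tuple[str, str], dict[str, set[str]]]
    de_union_sets: dict[str, set[str]]
    lnc_kept: list[str]
    rejection_log: RejectionLog | None
    cis_edges: list[tuple[str, str, int]]
    trans_edges: list[tuple[str, str, float]]
    candidate_pairs: list[CeRNAPair]
    final_pairs: list[CeRNAPair]
    annotated_pairs: list[CeRNAPair]
    summary: dict
    counts: dict = field(default_factory=dict)


def _pairwise_comparisons(conditions: Sequence[str]) -> list[tuple[str, str]]:
    """All ordered period pairs (earlier, later)."""
    return [
        (conditions[i], conditions[j])
        for i in range(len(conditions))
        for j in range(i + 1, len(conditions))
    ]


def analyze(
    annotation: Sequence[TranscriptRecord],
    expr_mrna: ExpressionMatrix,
    expr_lncrna: ExpressionMatrix,
    expr_mirna: ExpressionMatrix,
    edges: TargetEdgeTable,
    config: PipelineConfig,
    coding_calls: Mapping[str, tuple[bool, bool, bool, bool]] | None = None,
    skip_lnc_filter: bool = False,
) -> PipelineResult:
    """Run the full analysis on in-memory inputs."""
    by_id = {r.id: r for r in annotation}

    # -- stage 1: lncRNA candidate filter ---------------------------------
    rejection_log = None
    lnc_ids = list(expr_lncrna.feature_ids)
    if not skip_lnc_filter:
        lnc_records = [by_id[i] for i in lnc_ids if i in by_id]
        kept_records, rejection_log = filter_lncrna_candidates(
            lnc_records, config, coding_calls
        )
        lnc_ids = [r.id for r in kept_records]
        expr_lncrna = expr_lncrna.subset(lnc_ids)

    # -- stage 2: differential expression ---------------------------------
    conditions = expr_mrna.conditions
    comparisons = _pairwise_comparisons(conditions)
    mirdeep2 = {
        r.id: r.mirdeep2_score
        for r in annotation
        if r.mirdeep2_score is not None
    }
    de_results: dict[tuple[str, str], dict[str, list[DEResult]]] = {}
    de_sets: dict[tuple[str, str], dict[str, set[str]]] = {}
    for comp in comparisons:
        per_class = {
            "mRNA": de_test(expr_mrna, comp, config),
            "lncRNA": de_test(expr_lncrna, comp, config),
            "miRNA": de_test(expr_mirna, comp, config, mirdeep2_scores=mirdeep2),
        }
        de_results[comp] = per_class
        de_sets[comp] = {
            cls: {r.feature_id for r in res if r.is_de}
            for cls, res in per_class.items()
        }
    union_sets = {
        cls: de_union({c: de_results[c][cls] for c in comparisons})
        for cls in ("mRNA", "lncRNA", "miRNA")
    }

    # -- stage 3: target assignment ---------------------------------------
    de_lnc_records = [by_id[i] for i in sorted(union_sets["lncRNA"]) if i in by_id]
    gene_records = [r for r in annotation if r.biotype == "coding"]
    cis = cis_targets(de_lnc_records, gene_records, config.cis_window_bp)
    de_lnc_ids = [i for i in expr_lncrna.feature_ids if i in union_sets["lncRNA"]]
    trans = (
        trans_targets(
            expr_lncrna.subset(de_lnc_ids),
            expr_mrna,
            config.trans_min_abs_r,
            pseudocount=config.pseudocount,
            scale=config.trans_scale,
        )
        if de_lnc_ids
        else []
    )

    # -- stage 4: ceRNA scoring + trend pruning per comparison ------------
    n_universe = len(edges.mirnas)  # unrestricted table defines the universe
    directions = direction_table(
        [expr_mrna, expr_lncrna, expr_mirna], comparisons, config
    )
    candidate_pairs: list[CeRNAPair] = []
    final_pairs: list[CeRNAPair] = []
    annotated: list[CeRNAPair] = []
    for comp in comparisons:
        ds = de_sets[comp]
        sub = edges.restrict(
            mirnas=ds["miRNA"], targets=ds["mRNA"] | ds["lncRNA"]
        )
        pairs = build_candidate_pairs(sub, config, n_universe=n_universe, comparison=comp)
        candidate_pairs.extend(pairs)
        kept, ann = trend_prune(pairs, directions, config)
        final_pairs.extend(kept)
        annotated.extend(ann)

    summary = summarize_network(final_pairs)
    counts = {
        "lncrna_candidates_kept": len(lnc_ids),
        "de_mrna": len(union_sets["mRNA"]),
        "de_lncrna": len(union_sets["lncRNA"]),
        "de_mirna": len(union_sets["miRNA"]),
        "cis_edges": len(cis),
        "trans_edges": len(trans),
        "candidate_pairs": len(candidate_pairs),
        "final_pairs": len(final_pairs),
        "n_universe": config.n_total_mirnas or n_universe,
    }
    logger.info("pipeline counts: %s", counts)
    return PipelineResult(
        config=config,
        comparisons=comparisons,
        de_results=de_results,
        de_sets=de_sets,
        de_union_sets=union_sets,
        lnc_kept=lnc_ids,
        rejection_log=rejection_log,
        cis_edges=cis,
        trans_edges=trans,
        candidate_pairs=candidate_pairs,
        final_pairs=final_pairs,
        annotated_pairs=annotated,
        summary=summary,
        counts=counts,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_outputs(
    result: PipelineResult,
    outdir,
    input_paths: Mapping[str, Path] | None = None,
) -> dict[str, Path]:
    """Write pairs TSV, GraphML network, summary and run manifest.

    Outputs are deterministic: identical (config, inputs) give byte-identical
    files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "pairs": out / "cerna_pairs.tsv",
        "graphml": out / "cerna_network.graphml",
        "summary": out / "summary.json",
        "manifest": out / "manifest.json",
    }
    cio.write_network(result.final_pairs, paths["pairs"], fmt="tsv")
    cio.write_network(result.final_pairs, paths["graphml"], fmt="graphml")
    with open(paths["summary"], "w") as fh:
        json.dump(result.summary, fh, indent=1, sort_keys=True)
    manifest = {
        "tool_version": VERSION,
        "config": result.config.to_dict(),
        "rng_seed": result.config.rng_seed,
        "counts": result.counts,
        "inputs": {
            k: _sha256(Path(p)) for k, p in (input_paths or {}).items() if Path(p).exists()
        },
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return paths


def run_from_files(
    config: PipelineConfig,
    inputs: Mapping[str, Path],
    outdir,
    design_spec: Sequence[tuple[str, str]],
) -> PipelineResult:
    """Validate and read on-disk inputs, run the analysis, write artifacts.

    Required ``inputs`` keys: annotation, expr_mrna, expr_lncrna,
    expr_mirna, targets; optional: coding_calls.
    """
    required = ["annotation", "expr_mrna", "expr_lncrna", "expr_mirna", "targets"]
    missing = [k for k in required if k not in inputs or not Path(inputs[k]).exists()]
    if missing:
        raise FileNotFoundError(f"missing required inputs: {missing}")
    annotation = cio.read_annotation(inputs["annotation"])
    expr_mrna = cio.read_expression(inputs["expr_mrna"], design_spec, "mRNA")
    expr_lncrna = cio.read_expression(inputs["expr_lncrna"], design_spec, "lncRNA")
    expr_mirna = cio.read_expression(inputs["expr_mirna"], design_spec, "miRNA")
    edges = cio.read_target_table(inputs["targets"])
    coding_calls = (
        cio.read_coding_calls(inputs["coding_calls"])
        if "coding_calls" in inputs and Path(inputs["coding_calls"]).exists()
        else None
    )
    result = analyze(
        annotation, expr_mrna, expr_lncrna, expr_mirna, edges, config, coding_calls
    )
    write_outputs(result, outdir, input_paths=inputs)
    return result


def run_synthetic(spec, config: PipelineConfig, outdir=None) -> tuple[PipelineResult, "object"]:
    """Generate a synthetic dataset and analyze it in memory."""
    from .simulate import generate_dataset

    ds = generate_dataset(spec)
    result = analyze(
        ds.annotation, ds.expr_mrna, ds.expr_lncrna, ds.expr_mirna, ds.edges, config
    )
    if outdir is not None:
        write_outputs(result, outdir)
    return result, ds


def pair_recovery(final_pairs: Sequence[CeRNAPair], truth) -> dict[str, float]:
    """Recall/precision of recovered (lncRNA, mRNA) pairs vs ground truth."""
    found = {(p.lncrna_id, p.mrna_id) for p in final_pairs}
    planted = truth.planted_pairs
    tp = len(found & planted)
    recall = tp / len(planted) if planted else float("nan")
    precision = tp / len(found) if found else float("nan")
    return {
        "recall": recall,
        "precision": precision,
        "true_positives": tp,
        "reported": len(found),
        "planted": len(planted),
    }
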