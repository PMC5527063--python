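"""Typed readers and writers for the pipeline's on-disk formats.

Formats handled here: TSV expression matrices (header row of sample labels,
first column the feature id), Ensembl-dialect GTF annotation, TSV miRNA
target tables, TSV coding-potential call tables, FASTA sequence files, and
the finalized ceRNA network as TSV or GraphML.  Every reader validates and
rejects malformed records with the offending file position rather than
coercing silently.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import gffutils
import networkx as nx
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    BIOTYPES,
    ExpressionMatrix,
    TargetEdge,
    TargetEdgeTable,
    TranscriptRecord,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "write_expression",
    "read_annotation",
    "write_annotation",
    "read_coding_calls",
    "read_target_table",
    "write_target_table",
    "read_fasta",
    "write_fasta",
    "write_network",
    "read_network_graphml",
]


def _sample_label(condition: str, replicate: str) -> str:
    return f"{condition}_{replicate}"


def read_expression(
    path,
    design_spec: Sequence[tuple[str, str]],
    feature_class: str,
) -> ExpressionMatrix:
    """Read a TSV abundance matrix whose header matches a sample design.

    ``design_spec`` lists ``(condition, replicate)`` pairs in the desired
    column order; the file's header must contain the label
    ``{condition}_{replicate}`` for each.  Columns are reordered to the
    design, so period order is owned by the caller, not the file.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    expected = [_sample_label(c, r) for c, r in design_spec]
    missing = [lab for lab in expected if lab not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}: header lacks sample columns {missing}; found "
            f"{list(df.columns)}"
        )
    df = df[expected]
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise ValidationError(f"{path}: duplicated feature ids {dups[:5]}")
    values = pd.DataFrame(index=df.index.astype(str))
    for col in expected:
        # float() round-trips shortest-repr output exactly (pandas' fast
        # parser can be one ulp off)
        try:
            values[col] = [float(v) for v in df[col]]
        except (ValueError, TypeError):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise ValidationError(
                f"{path}: malformed numeric cell at feature {row!r}, "
                f"column {col!r}"
            ) from None
    return ExpressionMatrix(values.astype(float), list(design_spec), feature_class)


def write_expression(expr: ExpressionMatrix, path) -> None:
    """Write the matrix back to TSV with ``condition_replicate`` headers.

    Round-trips bit-exactly through :func:`read_expression` (float repr is
    shortest-exact in Python 3)."""
    out = expr.values.copy()
    out.columns = [_sample_label(c, r) for c, r in expr.sample_design]
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", float_format=None)


# ---------------------------------------------------------------------------
# GTF annotation
# ---------------------------------------------------------------------------

_BIOTYPE_MAP = {
    "protein_coding": "coding",
    "lncRNA": "lncRNA_candidate",
    "lincRNA": "lncRNA_candidate",
    "lncRNA_candidate": "lncRNA_candidate",
    "miRNA": "known_ncRNA",
    "snoRNA": "known_ncRNA",
    "snRNA": "known_ncRNA",
    "rRNA": "known_ncRNA",
    "tRNA": "known_ncRNA",
    "known_ncRNA": "known_ncRNA",
}


def read_annotation(path) -> list[TranscriptRecord]:
    """Parse a GTF file into one :class:`TranscriptRecord` per transcript.

    Exon features are grouped by ``transcript_id``; ``exon_count`` is the
    number of exon lines and ``length`` the sum of exon lengths (1-based
    inclusive, ``end - start + 1`` each).  Recognised optional attributes:
    ``transcript_biotype``/``gene_biotype`` (mapped onto the internal
    biotype vocabulary, unknown values -> ``other``), ``cov`` (read
    coverage; the maximum over exon lines is kept) and ``mirdeep2_score``.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    groups: dict[str, dict] = {}
    order: list[str] = []
    for feat in db.all_features():
        if feat.featuretype != "exon":
            continue
        if feat.end < feat.start:
            raise ValidationError(
                f"{path}: exon with end < start for transcript "
                f"{feat.attributes.get('transcript_id', ['?'])[0]} "
                f"({feat.seqid}:{feat.start}-{feat.end})"
            )
        tid = feat.attributes.get("transcript_id", [None])[0]
        if tid is None:
            raise ValidationError(f"{path}: exon line without transcript_id")
        if tid not in groups:
            order.append(tid)
            groups[tid] = {
                "chrom": feat.seqid,
                "strand": feat.strand if feat.strand in "+-" else "unknown",
                "start": feat.start,
                "end": feat.end,
                "n_exons": 0,
                "length": 0,
                "cov": 0.0,
                "biotype": None,
                "mirdeep2_score": None,
            }
        g = groups[tid]
        if feat.seqid != g["chrom"]:
            raise ValidationError(f"{path}: transcript {tid} spans chromosomes")
        g["n_exons"] += 1
        g["length"] += feat.end - feat.start + 1
        g["start"] = min(g["start"], feat.start)
        g["end"] = max(g["end"], feat.end)
        attrs = feat.attributes
        if "cov" in attrs:
            g["cov"] = max(g["cov"], float(attrs["cov"][0]))
        for key in ("transcript_biotype", "gene_biotype"):
            if g["biotype"] is None and key in attrs:
                g["biotype"] = _BIOTYPE_MAP.get(attrs[key][0], "other")
        if "mirdeep2_score" in attrs:
            g["mirdeep2_score"] = float(attrs["mirdeep2_score"][0])
    records = []
    for tid in order:
        g = groups[tid]
        records.append(
            TranscriptRecord(
                id=tid,
                chromosome=g["chrom"],
                strand=g["strand"],
                start=g["start"],
                end=g["end"],
                exon_count=g["n_exons"],
                length=g["length"],
                min_coverage=g["cov"],
                biotype=g["biotype"] or "other",
                mirdeep2_score=g["mirdeep2_score"],
            )
        )
    return records


_BIOTYPE_GTF = {
    "coding": "protein_coding",
    "lncRNA_candidate": "lncRNA",
    "known_ncRNA": "miRNA",
    "other": "misc_RNA",
}


def write_annotation(
    records: Iterable[TranscriptRecord],
    path,
    exon_layout: Mapping[str, list[tuple[int, int]]] | None = None,
) -> None:
    """Emit records as Ensembl-style GTF exon lines.

    Without an explicit per-transcript ``exon_layout`` the exons are laid
    out contiguously inside the transcript span, preserving exon count and
    total exon length (sufficient for round-tripping the filter-relevant
    attributes; real intron structure is not modelled).
    """
    with open(path, "w") as fh:
        for rec in records:
            if exon_layout and rec.id in exon_layout:
                exons = exon_layout[rec.id]
            else:
                exons = _contiguous_exons(rec)
            for start, end in exons:
                attrs = (
                    f'gene_id "{rec.id}_g"; transcript_id "{rec.id}"; '
                    f'transcript_biotype "{_BIOTYPE_GTF[rec.biotype]}"; '
                    f'cov "{rec.min_coverage:g}";'
                )
                if rec.mirdeep2_score is not None:
                    attrs += f' mirdeep2_score "{rec.mirdeep2_score:g}";'
                strand = rec.strand if rec.strand in "+-" else "."
                fh.write(
                    f"{rec.chromosome}\tcernet\texon\t{start}\t{end}\t.\t"
                    f"{strand}\t.\t{attrs}\n"
                )


def _contiguous_exons(rec: TranscriptRecord) -> list[tuple[int, int]]:
    """Split ``rec.length`` bases over ``rec.exon_count`` abutting exons
    starting at ``rec.start``."""
    base = rec.length // rec.exon_count
    sizes = [base] * rec.exon_count
    sizes[-1] += rec.length - base * rec.exon_count
    exons = []
    pos = rec.start
    for s in sizes:
        exons.append((pos, pos + s - 1))
        pos += s
    return exons


def read_coding_calls(path) -> dict[str, tuple[bool, bool, bool, bool]]:
    """Read the four-classifier coding-potential table.

    Expected columns: ``transcript_id, cnci, cpc, pfam, phylocsf`` with
    values in {0, 1}; 1 means the tool called the transcript coding.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["transcript_id", "cnci", "cpc", "pfam", "phylocsf"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    calls: dict[str, tuple[bool, bool, bool, bool]] = {}
    for i, row in df.iterrows():
        vals = []
        for tool in required[1:]:
            v = str(row[tool]).strip()
            if v not in ("0", "1"):
                raise ValidationError(
                    f"{path}: line {i + 2}: {tool} value {v!r} not in {{0,1}}"
                )
            vals.append(v == "1")
        calls[str(row["transcript_id"])] = tuple(vals)  # type: ignore[assignment]
    return calls


# ---------------------------------------------------------------------------
# Target tables
# ---------------------------------------------------------------------------


def read_target_table(path) -> TargetEdgeTable:
    """Read a TSV of miRNA->target edges (columns mirna, target, class
    [, score]); duplicates are collapsed with a logged warning."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["mirna", "target", "class"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    edges = []
    for i, row in df.iterrows():
        cls = str(row["class"])
        if cls not in ("mRNA", "lncRNA"):
            raise ValidationError(
                f"{path}: line {i + 2}: unknown target class {cls!r}"
            )
        score = None
        if "score" in df.columns and pd.notna(row["score"]) and str(row["score"]) != "":
            score = float(row["score"])
        edges.append(TargetEdge(str(row["mirna"]), str(row["target"]), cls, score))
    table = TargetEdgeTable(edges)
    if table.n_duplicates_dropped:
        logger.warning(
            "%s: collapsed %d duplicate target edges",
            path,
            table.n_duplicates_dropped,
        )
    return table


def write_target_table(table: TargetEdgeTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    """Read sequences into an id -> uppercase-string mapping (order kept)."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValidationError(f"{path}: duplicated sequence id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Network export
# ---------------------------------------------------------------------------

_PAIR_COLUMNS = [
    "lncrna",
    "mrna",
    "comparison",
    "c",
    "K",
    "n",
    "N",
    "p",
    "q",
    "shared_mirnas",
    "trend_consistent",
]


def pairs_to_frame(pairs) -> pd.DataFrame:
    """Finalized ceRNA pairs as a deterministic, sorted DataFrame."""
    rows = []
    for pr in pairs:
        comp = "|".join(pr.comparison) if pr.comparison else ""
        rows.append(
            (
                pr.lncrna_id,
                pr.mrna_id,
                comp,
                pr.params.c,
                pr.params.K,
                pr.params.n,
                pr.params.N,
                f"{pr.p:.6g}",
                f"{pr.q:.6g}" if pr.q is not None else "",
                ";".join(sorted(pr.shared_mirnas)),
                "" if pr.trend_consistent is None else str(pr.trend_consistent),
            )
        )
    df = pd.DataFrame(rows, columns=_PAIR_COLUMNS)
    return df.sort_values(["comparison", "lncrna", "mrna"], kind="mergesort").reset_index(
        drop=True
    )


def write_network(pairs, path, fmt: str = "tsv") -> None:
    """Write the finalized ceRNA network as a TSV edge list or as a
    tripartite GraphML graph (nodes typed miRNA/mRNA/lncRNA; lncRNA--mRNA
    edges carry P and q)."""
    if fmt == "tsv":
        pairs_to_frame(pairs).to_csv(path, sep="\t", index=False)
        return
    if fmt != "graphml":
        raise ValidationError(f"unknown network format {fmt!r}")
    g = nx.Graph()
    for pr in sorted(pairs, key=lambda x: (x.lncrna_id, x.mrna_id)):
        g.add_node(pr.lncrna_id, node_type="lncRNA")
        g.add_node(pr.mrna_id, node_type="mRNA")
        g.add_edge(
            pr.lncrna_id,
            pr.mrna_id,
            p=float(pr.p),
            q=float(pr.q) if pr.q is not None else float("nan"),
            shared=";".join(sorted(pr.shared_mirnas)),
        )
        for m in sorted(pr.shared_mirnas):
            g.add_node(m, node_type="miRNA")
            g.add_edge(m, pr.lncrna_id, kind="mre")
            g.add_edge(m, pr.mrna_id, kind="mre")
    nx.write_graphml(g, path)


def read_network_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)
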