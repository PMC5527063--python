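"""Synthetic test bed with the statistical structure the analysis assumes.

The generator emulates the study design the pipeline targets: three ordered
physiological periods (dry period, early lactation, peak of lactation) with
three biological replicates each, log-normal FPKM/TPM-scale abundances,
planted differential-expression effects, a random miRNA->target wiring, and
planted ceRNA triplets (lncRNA, miRNA, mRNA) in which the miRNA's
condition-mean profile is the exact sign-flip of its two targets' — the
operational signature of miRNA sponging.  Ground truth is returned for
every planted structure, so recovery is measurable end to end.

All randomness flows from one ``numpy.random.Generator`` (PCG64) seeded by
``rng_seed``; a fixed seed reproduces every array bit-identically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .model import (
    ExpressionMatrix,
    TargetEdge,
    TargetEdgeTable,
    TranscriptRecord,
    ValidationError,
)

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "SyntheticDataset",
    "generate_dataset",
    "generate_null_dataset",
    "generate_sequences",
    "write_dataset",
]

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class SpecError(ValidationError):
    """The simulation spec is internally infeasible."""


@dataclass(frozen=True)
class SimulationSpec:
    """Simulation parameters: the conditions the generator emulates.

    Defaults give a desk-scale lactation-cycle bed:
    3 periods x 3 cows, log2-normal baseline abundances around 2^5 FPKM,
    multiplicative replicate noise of 0.25 on the log2 scale, planted
    effects of |log2 FC| = 3 (8-fold), 20 planted ceRNA triplets and a mean
    miRNA out-degree of 5.
    """

    n_mrna: int = 500
    n_lncrna: int = 100
    n_mirna: int = 200
    n_conditions: int = 3
    n_replicates: int = 3
    base_log2_mean: float = 5.0
    base_log2_sd: float = 1.5
    noise_log2_sd: float = 0.25
    planted_de_fraction: float = 0.05
    planted_log2_fc: float = 3.0
    n_planted_triplets: int = 20
    n_decoy_triplets: int = 0
    mirna_targets_per_mirna: float = 5.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_mrna", "n_lncrna", "n_mirna", "n_conditions", "n_replicates"):
            if getattr(self, name) <= 0:
                raise SpecError(f"{name} must be > 0")
        if self.noise_log2_sd <= 0:
            raise SpecError("noise_log2_sd must be > 0")
        if not 0 <= self.planted_de_fraction <= 1:
            raise SpecError("planted_de_fraction must be in [0, 1]")
        if self.n_planted_triplets < 0:
            raise SpecError("n_planted_triplets must be >= 0")
        if self.n_decoy_triplets < 0:
            raise SpecError("n_decoy_triplets must be >= 0")
        total = self.n_planted_triplets + self.n_decoy_triplets
        if total > min(self.n_mrna, self.n_lncrna, self.n_mirna):
            raise SpecError(
                f"cannot plant {total} triplets with only "
                f"{self.n_mrna} mRNAs, {self.n_lncrna} lncRNAs and "
                f"{self.n_mirna} miRNAs"
            )

    @property
    def condition_labels(self) -> tuple[str, ...]:
        if self.n_conditions == 3:
            return ("dry", "early", "peak")
        return tuple(f"cond{i + 1}" for i in range(self.n_conditions))

    @property
    def sample_design(self) -> list[tuple[str, str]]:
        return [
            (c, f"cow{r + 1}")
            for c in self.condition_labels
            for r in range(self.n_replicates)
        ]


@dataclass
class GroundTruth:
    planted_triplets: set[tuple[str, str, str]] = field(default_factory=set)
    decoy_triplets: set[tuple[str, str, str]] = field(default_factory=set)
    planted_de: dict[str, set[str]] = field(
        default_factory=lambda: {"mRNA": set(), "lncRNA": set(), "miRNA": set()}
    )
    planted_target_edges: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        for lnc, mir, mrna in self.planted_triplets:
            if (mir, lnc) not in self.planted_target_edges or (
                mir,
                mrna,
            ) not in self.planted_target_edges:
                raise ValidationError(
                    f"triplet ({lnc}, {mir}, {mrna}) lacks its target edges"
                )

    @property
    def planted_pairs(self) -> set[tuple[str, str]]:
        """The (lncRNA, mRNA) couples the pipeline should recover."""
        return {(lnc, mrna) for lnc, _mir, mrna in self.planted_triplets}


@dataclass
class SyntheticDataset:
    spec: SimulationSpec
    annotation: list[TranscriptRecord]
    expr_mrna: ExpressionMatrix
    expr_lncrna: ExpressionMatrix
    expr_mirna: ExpressionMatrix
    edges: TargetEdgeTable
    truth: GroundTruth


def _step_offsets(rng: np.random.Generator, n_conditions: int, fc: float) -> np.ndarray:
    """Cumulative condition offsets from random +/-fc steps (first = 0)."""
    steps = rng.choice([-1.0, 1.0], size=n_conditions - 1) * fc
    return np.concatenate([[0.0], np.cumsum(steps)])


def _expression(
    rng: np.random.Generator,
    spec: SimulationSpec,
    ids: list[str],
    offsets: np.ndarray,
    feature_class: str,
) -> ExpressionMatrix:
    n = len(ids)
    base = rng.normal(spec.base_log2_mean, spec.base_log2_sd, size=n)
    noise = rng.normal(
        0.0, spec.noise_log2_sd, size=(n, spec.n_conditions, spec.n_replicates)
    )
    log2v = base[:, None, None] + offsets[:, :, None] + noise
    values = 2.0 ** log2v.reshape(n, spec.n_conditions * spec.n_replicates)
    cols = [f"{c}_{r}" for c, r in spec.sample_design]
    return ExpressionMatrix(
        pd.DataFrame(values, index=ids, columns=cols),
        spec.sample_design,
        feature_class,
    )


def _annotation(
    rng: np.random.Generator,
    mrna_ids: list[str],
    lnc_ids: list[str],
    mir_ids: list[str],
) -> list[TranscriptRecord]:
    chroms = [str(i) for i in range(1, 6)]
    records: list[TranscriptRecord] = []
    mrna_pos: list[tuple[str, int]] = []
    for mid in mrna_ids:
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(1, 50_000_000))
        exons = int(rng.integers(2, 13))
        length = exons * int(rng.integers(150, 400))
        mrna_pos.append((chrom, start))
        records.append(
            TranscriptRecord(
                id=mid,
                chromosome=chrom,
                strand="+" if rng.random() < 0.5 else "-",
                start=start,
                end=start + length - 1,
                exon_count=exons,
                length=length,
                min_coverage=float(rng.uniform(3.0, 60.0)),
                biotype="coding",
            )
        )
    for lid in lnc_ids:
        # half the lncRNAs are placed near a coding gene so the cis search
        # has realistic non-empty output; the rest land anywhere
        if rng.random() < 0.5 and mrna_pos:
            chrom, anchor = mrna_pos[int(rng.integers(len(mrna_pos)))]
            start = max(1, anchor + int(rng.integers(-500_000, 500_000)))
        else:
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(1, 50_000_000))
        exons = int(rng.integers(2, 5))
        length = int(rng.integers(200, 2000))
        calls = tuple(bool(rng.random() < 0.15) for _ in range(4))
        if all(calls):  # generated candidates must survive the 4-tool filter
            calls = calls[:3] + (False,)
        records.append(
            TranscriptRecord(
                id=lid,
                chromosome=chrom,
                strand="+" if rng.random() < 0.5 else "-",
                start=start,
                end=start + length - 1,
                exon_count=exons,
                length=length,
                min_coverage=float(rng.uniform(3.0, 30.0)),
                biotype="lncRNA_candidate",
                coding_calls=calls,  # type: ignore[arg-type]
            )
        )
    for mid in mir_ids:
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(1, 50_000_000))
        records.append(
            TranscriptRecord(
                id=mid,
                chromosome=chrom,
                strand="+",
                start=start,
                end=start + 21,
                exon_count=1,
                length=22,
                min_coverage=float(rng.uniform(3.0, 100.0)),
                biotype="known_ncRNA",
                mirdeep2_score=float(rng.uniform(1.0, 10.0)),
            )
        )
    return records


def _generate(spec: SimulationSpec, planted: bool) -> SyntheticDataset:
    rng = np.random.default_rng(spec.rng_seed)
    mrna_ids = [f"MRNA{i:04d}" for i in range(spec.n_mrna)]
    lnc_ids = [f"LNC{i:04d}" for i in range(spec.n_lncrna)]
    mir_ids = [f"MIR{i:04d}" for i in range(spec.n_mirna)]

    truth = GroundTruth()
    off_mrna = np.zeros((spec.n_mrna, spec.n_conditions))
    off_lnc = np.zeros((spec.n_lncrna, spec.n_conditions))
    off_mir = np.zeros((spec.n_mirna, spec.n_conditions))
    edges: list[TargetEdge] = []

    k_true = spec.n_planted_triplets if planted else 0
    k_decoy = spec.n_decoy_triplets if planted else 0
    k = k_true + k_decoy
    if k:
        tri_mrna = rng.choice(spec.n_mrna, size=k, replace=False)
        tri_lnc = rng.choice(spec.n_lncrna, size=k, replace=False)
        tri_mir = rng.choice(spec.n_mirna, size=k, replace=False)
        for idx, (im, il, ir) in enumerate(zip(tri_mrna, tri_lnc, tri_mir)):
            is_decoy = idx >= k_true
            target_off = _step_offsets(rng, spec.n_conditions, spec.planted_log2_fc)
            # sponge triplet: miRNA anti-correlated with both targets;
            # decoy triplet: miRNA moves with its targets (to be pruned)
            off_mir[ir] = target_off if is_decoy else -target_off
            off_lnc[il] = target_off
            off_mrna[im] = target_off
            lnc, mir, mrna = lnc_ids[il], mir_ids[ir], mrna_ids[im]
            edges.append(TargetEdge(mir, lnc, "lncRNA"))
            edges.append(TargetEdge(mir, mrna, "mRNA"))
            truth.planted_target_edges.update({(mir, lnc), (mir, mrna)})
            (truth.decoy_triplets if is_decoy else truth.planted_triplets).add(
                (lnc, mir, mrna)
            )
            truth.planted_de["mRNA"].add(mrna)
            truth.planted_de["lncRNA"].add(lnc)
            truth.planted_de["miRNA"].add(mir)
    else:
        tri_mrna = tri_lnc = tri_mir = np.array([], dtype=int)

    if planted and spec.planted_de_fraction > 0:
        for ids, off, taken, cls, n_class in (
            (mrna_ids, off_mrna, set(tri_mrna), "mRNA", spec.n_mrna),
            (lnc_ids, off_lnc, set(tri_lnc), "lncRNA", spec.n_lncrna),
            (mir_ids, off_mir, set(tri_mir), "miRNA", spec.n_mirna),
        ):
            free = np.array([i for i in range(n_class) if i not in taken])
            n_extra = min(len(free), int(round(spec.planted_de_fraction * n_class)))
            if n_extra:
                chosen = rng.choice(free, size=n_extra, replace=False)
                for i in chosen:
                    off[i] = _step_offsets(rng, spec.n_conditions, spec.planted_log2_fc)
                    truth.planted_de[cls].add(ids[i])

    expr_mrna = _expression(rng, spec, mrna_ids, off_mrna, "mRNA")
    expr_lnc = _expression(rng, spec, lnc_ids, off_lnc, "lncRNA")
    expr_mir = _expression(rng, spec, mir_ids, off_mir, "miRNA")
    annotation = _annotation(rng, mrna_ids, lnc_ids, mir_ids)

    # Background wiring: Poisson out-degree, uniform targets.  In the
    # planted dataset the background avoids planted-DE features so that the
    # planted triplets are the *exhaustive* set of sponge-consistent
    # signals (otherwise a random edge from a planted miRNA onto another
    # planted-DE feature manufactures an unlabelled true positive); the
    # null dataset is wired fully uniformly.
    all_targets = mrna_ids + lnc_ids
    if planted:
        blocked = truth.planted_de["mRNA"] | truth.planted_de["lncRNA"]
        bg_targets = [t for t in all_targets if t not in blocked]
    else:
        bg_targets = all_targets
    classes = {t: ("mRNA" if t in set(mrna_ids) else "lncRNA") for t in all_targets}
    for mir in mir_ids:
        deg = int(rng.poisson(spec.mirna_targets_per_mirna))
        deg = min(deg, len(bg_targets))
        if deg == 0:
            continue
        for j in rng.choice(len(bg_targets), size=deg, replace=False):
            t = bg_targets[j]
            edges.append(TargetEdge(mir, t, classes[t]))

    return SyntheticDataset(
        spec=spec,
        annotation=annotation,
        expr_mrna=expr_mrna,
        expr_lncrna=expr_lnc,
        expr_mirna=expr_mir,
        edges=TargetEdgeTable(edges),
        truth=truth,
    )


def generate_dataset(spec: SimulationSpec) -> SyntheticDataset:
    """Generate a dataset with planted DE effects and ceRNA triplets.

    For every planted triplet the miRNA condition means follow a drawn
    +/-``planted_log2_fc`` step pattern and both targets follow its exact
    sign-flip; replicates multiply the condition mean by log-normal noise.
    Non-planted features have flat condition means.
    """
    return _generate(spec, planted=True)


def generate_null_dataset(spec: SimulationSpec) -> SyntheticDataset:
    """Same marginal structure, no planted effects, uniform random wiring —
    the null bed for false-positive-rate checks."""
    return _generate(spec, planted=False)


# ---------------------------------------------------------------------------
# Sequence generation for the seed scanner
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, length: int) -> list[str]:
    return list(_BASES[rng.integers(0, 4, size=length)])


def _scrub(
    rng: np.random.Generator,
    seq: list[str],
    forbidden: set[str],
    protected: set[int],
    max_rounds: int = 10_000,
) -> None:
    """Mutate bases in place until no forbidden 7-mer remains, never
    touching protected positions (planted sites)."""
    for _ in range(max_rounds):
        s = "".join(seq)
        dirty = False
        for pos in range(len(seq) - 6):
            if s[pos : pos + 7] in forbidden:
                editable = [i for i in range(pos, pos + 7) if i not in protected]
                if not editable:
                    continue  # an occurrence fully inside a planted site of
                    # another miRNA cannot happen: sites are distinct 7-mers
                i = editable[int(rng.integers(len(editable)))]
                seq[i] = str(_BASES[int(rng.integers(4))])
                dirty = True
                break
        if not dirty:
            return
    raise ValidationError("could not scrub forbidden seed sites (raise target length)")


def generate_sequences(
    spec: SimulationSpec,
    edges: TargetEdgeTable,
    target_length: int = 300,
    mirna_length: int = 22,
) -> tuple[dict[str, str], dict[str, str]]:
    """Mature miRNA sequences (RNA alphabet) and target sequences (DNA)
    consistent with an edge table: every edge's target contains at least one
    exact seed site (reverse complement of miRNA positions 2-8) and no
    target contains a site of any miRNA it has no edge with.

    Seed 7-mers are rejection-sampled to be pairwise distinct so edge
    membership is unambiguous; non-edge sites are scrubbed out of the random
    background by local mutation.
    """
    if mirna_length < 8:
        raise ValidationError("miRNAs must be at least 8 nt")
    rng = np.random.default_rng([spec.rng_seed, 7])
    mirna_ids = edges.mirnas
    sites: dict[str, str] = {}
    mirna_seqs: dict[str, str] = {}
    used: set[str] = set()
    for m in mirna_ids:
        for _ in range(1000):
            seq = "".join(_random_seq(rng, mirna_length))
            site = seq[1:8].translate(_COMPLEMENT)[::-1]
            if site not in used:
                used.add(site)
                sites[m] = site
                mirna_seqs[m] = seq.replace("T", "U")
                break
        else:
            raise ValidationError("could not draw distinct seed sites")
    forbidden = set(sites.values())

    target_seqs: dict[str, str] = {}
    for t in edges.targets():
        wanted = sorted(edges.mirnas_targeting(t))
        need = len(wanted) * 8
        length = max(target_length, need + 20)
        seq = _random_seq(rng, length)
        # non-overlapping planted positions, >= 8 apart
        n_slots = length // 8
        slot_idx = rng.choice(n_slots, size=len(wanted), replace=False)
        protected: set[int] = set()
        for m, slot in zip(wanted, sorted(int(s) for s in slot_idx)):
            pos = slot * 8
            for k, ch in enumerate(sites[m]):
                seq[pos + k] = ch
            protected.update(range(pos, pos + 7))
        _scrub(rng, seq, forbidden - {sites[m] for m in wanted}, protected)
        target_seqs[t] = "".join(seq)
    return mirna_seqs, target_seqs


# ---------------------------------------------------------------------------
# On-disk emission
# ---------------------------------------------------------------------------


def write_dataset(ds: SyntheticDataset, outdir, sequences: bool = False) -> dict[str, Path]:
    """Emit the dataset in the exact formats the readers consume.

    Files: ``annotation.gtf``, ``expr_{mrna,lncrna,mirna}.tsv``,
    ``targets.tsv``, ``coding_calls.tsv``, ``ground_truth.json`` and
    (optionally) ``mirna.fa`` / ``targets.fa``.
    """
    from . import io as cio  # local import to avoid a cycle
    import json

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotation": out / "annotation.gtf",
        "expr_mrna": out / "expr_mrna.tsv",
        "expr_lncrna": out / "expr_lncrna.tsv",
        "expr_mirna": out / "expr_mirna.tsv",
        "targets": out / "targets.tsv",
        "coding_calls": out / "coding_calls.tsv",
        "ground_truth": out / "ground_truth.json",
    }
    cio.write_annotation(ds.annotation, paths["annotation"])
    cio.write_expression(ds.expr_mrna, paths["expr_mrna"])
    cio.write_expression(ds.expr_lncrna, paths["expr_lncrna"])
    cio.write_expression(ds.expr_mirna, paths["expr_mirna"])
    cio.write_target_table(ds.edges, paths["targets"])
    rows = [
        {
            "transcript_id": r.id,
            **{
                tool: int(call)
                for tool, call in zip(("cnci", "cpc", "pfam", "phylocsf"), r.coding_calls)
            },
        }
        for r in ds.annotation
        if r.coding_calls is not None
    ]
    pd.DataFrame(rows).to_csv(paths["coding_calls"], sep="\t", index=False)
    with open(paths["ground_truth"], "w") as fh:
        json.dump(
            {
                "planted_triplets": sorted(ds.truth.planted_triplets),
                "planted_de": {k: sorted(v) for k, v in ds.truth.planted_de.items()},
                "planted_target_edges": sorted(ds.truth.planted_target_edges),
                "spec": dataclasses.asdict(ds.spec),
            },
            fh,
            indent=1,
        )
    if sequences:
        mirna_seqs, target_seqs = generate_sequences(ds.spec, ds.edges)
        paths["mirna_fasta"] = out / "mirna.fa"
        paths["target_fasta"] = out / "targets.fa"
        cio.write_fasta(mirna_seqs, paths["mirna_fasta"])
        cio.write_fasta(target_seqs, paths["target_fasta"])
    return paths
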