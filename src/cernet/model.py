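"""Shared data model for the ceRNA inference pipeline.

Conventions used throughout the package:

* Genomic coordinates are 1-based and inclusive on both ends, matching the
  GTF files they are read from.  No module converts to half-open intervals.
* Long-transcript abundances carry FPKM semantics, small-RNA abundances TPM
  semantics; both are non-negative reals and are never treated as counts.
* Conditions (physiological periods) are an *ordered* sequence — trend
  classification depends on that order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal, Sequence

import numpy as np
import pandas as pd
import yaml

FeatureClass = Literal["mRNA", "lncRNA", "miRNA"]
Biotype = Literal["coding", "lncRNA_candidate", "known_ncRNA", "other"]

FEATURE_CLASSES: tuple[str, ...] = ("mRNA", "lncRNA", "miRNA")
BIOTYPES: tuple[str, ...] = ("coding", "lncRNA_candidate", "known_ncRNA", "other")


class ValidationError(ValueError):
    """An input violated a documented invariant."""


class DesignError(ValidationError):
    """Sample design is inconsistent with the data or with another matrix."""


class DomainError(ValidationError):
    """A statistical routine received parameters outside its domain."""


@dataclass
class ExpressionMatrix:
    """Feature x sample abundance table with its condition/replicate design.

    Parameters
    ----------
    values
        DataFrame indexed by feature id, one column per sample.  All entries
        must be finite and non-negative.
    sample_design
        One ``(condition, replicate)`` label pair per column, in column
        order.  Condition order of first appearance defines the period order.
    feature_class
        Which RNA class the matrix holds; one matrix never mixes classes.
    """

    values: pd.DataFrame
    sample_design: list[tuple[str, str]]
    feature_class: str

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValidationError(
                f"unknown feature class {self.feature_class!r}; "
                f"expected one of {FEATURE_CLASSES}"
            )
        if len(self.sample_design) != self.values.shape[1]:
            raise DesignError(
                f"design lists {len(self.sample_design)} samples but the "
                f"matrix has {self.values.shape[1]} columns"
            )
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValidationError(f"duplicated feature ids: {dups[:5]}")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValidationError("expression values must be finite")
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative abundance at feature {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r}"
            )
        seen: dict[str, None] = {}
        for cond, _rep in self.sample_design:
            seen.setdefault(cond, None)
        self._conditions: tuple[str, ...] = tuple(seen)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> tuple[str, ...]:
        """Condition labels in period order (order of first appearance)."""
        return self._conditions

    def samples_of(self, condition: str) -> list[int]:
        """Column positions belonging to one condition."""
        cols = [i for i, (c, _r) in enumerate(self.sample_design) if c == condition]
        if not cols:
            raise DesignError(f"unknown condition {condition!r}")
        return cols

    def n_replicates(self, condition: str) -> int:
        return len(self.samples_of(condition))

    def condition_means(self) -> pd.DataFrame:
        """Linear-scale mean abundance per (feature, condition)."""
        arr = self.values.to_numpy(dtype=float)
        cols = {c: self.samples_of(c) for c in self.conditions}
        out = {c: arr[:, idx].mean(axis=1) for c, idx in cols.items()}
        return pd.DataFrame(out, index=self.values.index)

    def subset(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [f for f in feature_ids if f not in self.values.index]
        if missing:
            raise ValidationError(f"unknown features: {missing[:5]}")
        return ExpressionMatrix(
            self.values.loc[list(feature_ids)].copy(),
            list(self.sample_design),
            self.feature_class,
        )


@dataclass(frozen=True)
class TranscriptRecord:
    """A genomic feature as assembled/annotated: coordinates plus the
    attributes the lncRNA candidate filter consumes.

    ``length`` is the mature transcript length (sum of exon lengths), the
    convention coding-potential classifiers use; the genomic span
    ``end - start + 1`` can be larger for multi-exon transcripts.
    ``coding_calls`` holds one boolean per external coding-potential
    classifier (CNCI, CPC, Pfam, PhyloCSF), True meaning "called coding".
    ``mirdeep2_score`` is only meaningful for novel miRNA records.
    """

    id: str
    chromosome: str
    strand: str
    start: int
    end: int
    exon_count: int
    length: int
    min_coverage: float = 0.0
    biotype: str = "other"
    coding_calls: tuple[bool, bool, bool, bool] | None = None
    mirdeep2_score: float | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"{self.id}: start {self.start} > end {self.end}"
            )
        if self.exon_count < 1:
            raise ValidationError(f"{self.id}: exon_count must be >= 1")
        if self.biotype not in BIOTYPES:
            raise ValidationError(f"{self.id}: unknown biotype {self.biotype!r}")
        if self.coding_calls is not None and len(self.coding_calls) != 4:
            raise ValidationError(
                f"{self.id}: coding_calls needs exactly 4 entries, "
                f"got {len(self.coding_calls)}"
            )
        if self.min_coverage < 0:
            raise ValidationError(f"{self.id}: negative coverage")


@dataclass(frozen=True, order=True)
class TargetEdge:
    """One directed miRNA -> target interaction."""

    mirna_id: str
    target_id: str
    target_class: str  # "mRNA" or "lncRNA"
    score: float | None = field(default=None, compare=False)


class TargetEdgeTable:
    """Deduplicated set of miRNA->target edges with class-consistent targets.

    Duplicate ``(mirna, target)`` pairs are collapsed (first occurrence wins)
    and counted in :attr:`n_duplicates_dropped`; a target id appearing with
    two different classes is a hard error.
    """

    def __init__(self, edges: Iterable[TargetEdge]) -> None:
        kept: dict[tuple[str, str], TargetEdge] = {}
        classes: dict[str, str] = {}
        dropped = 0
        for e in edges:
            if e.target_class not in ("mRNA", "lncRNA"):
                raise ValidationError(
                    f"unknown target class {e.target_class!r} for edge "
                    f"({e.mirna_id}, {e.target_id})"
                )
            key = (e.mirna_id, e.target_id)
            if key in kept:
                dropped += 1
                continue
            prev = classes.setdefault(e.target_id, e.target_class)
            if prev != e.target_class:
                raise ValidationError(
                    f"target {e.target_id} appears as both {prev} and "
                    f"{e.target_class}"
                )
            kept[key] = e
        self._edges: tuple[TargetEdge, ...] = tuple(sorted(kept.values()))
        self.n_duplicates_dropped = dropped
        self._by_mirna: dict[str, set[str]] = {}
        self._by_target: dict[str, set[str]] = {}
        self._class_of: dict[str, str] = classes
        for e in self._edges:
            self._by_mirna.setdefault(e.mirna_id, set()).add(e.target_id)
            self._by_target.setdefault(e.target_id, set()).add(e.mirna_id)

    def __len__(self) -> int:
        return len(self._edges)

    def __iter__(self) -> Iterator[TargetEdge]:
        return iter(self._edges)

    @property
    def edges(self) -> tuple[TargetEdge, ...]:
        return self._edges

    @property
    def mirnas(self) -> list[str]:
        return sorted(self._by_mirna)

    def targets(self, target_class: str | None = None) -> list[str]:
        if target_class is None:
            return sorted(self._by_target)
        return sorted(
            t for t, c in self._class_of.items()
            if c == target_class and t in self._by_target
        )

    def target_class_of(self, target_id: str) -> str:
        return self._class_of[target_id]

    def targets_of(self, mirna_id: str) -> frozenset[str]:
        return frozenset(self._by_mirna.get(mirna_id, ()))

    def mirnas_targeting(self, target_id: str) -> frozenset[str]:
        return frozenset(self._by_target.get(target_id, ()))

    def restrict(
        self,
        mirnas: Iterable[str] | None = None,
        targets: Iterable[str] | None = None,
    ) -> "TargetEdgeTable":
        """Keep only edges whose endpoints lie in the given id sets."""
        mset = None if mirnas is None else set(mirnas)
        tset = None if targets is None else set(targets)
        return TargetEdgeTable(
            e for e in self._edges
            if (mset is None or e.mirna_id in mset)
            and (tset is None or e.target_id in tset)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.mirna_id, e.target_id, e.target_class, e.score) for e in self._edges],
            columns=["mirna", "target", "class", "score"],
        )


# Valid ranges for the tunable thresholds; used by PipelineConfig validation.
_CONFIG_RANGES: dict[str, tuple[float, float]] = {
    "mirna_p": (0.0, 1.0),
    "mirna_min_abs_fc": (1.0, float("inf")),
    "mirna_min_score": (0.0, float("inf")),
    "gene_q": (0.0, 1.0),
    "cis_window_bp": (0, float("inf")),
    "trans_min_abs_r": (0.0, 1.0),
    "cerna_alpha": (0.0, 1.0),
    "lnc_min_len": (1, float("inf")),
    "lnc_min_exons": (1, float("inf")),
    "lnc_min_cov": (0.0, float("inf")),
    "trend_epsilon": (0.0, float("inf")),
    "pseudocount": (0.0, float("inf")),
}


@dataclass
class PipelineConfig:
    """All thresholds driving the pipeline, with the study defaults.

    The defaults encode the conventional gates: miRNA raw P < 0.05 with linear
    fold change > 2 and a miRDeep2 score >= 1; gene/lncRNA BH-corrected
    q < 0.05; cis window +/-100 kb; trans |r| > 0.95 (strict); ceRNA
    retention at hypergeometric P < 0.05 with BH q reported alongside.
    ``n_total_mirnas`` fixes the hypergeometric universe N explicitly; when
    None, N defaults to the number of distinct miRNAs in the supplied
    (unrestricted) target table.
    """

    mirna_p: float = 0.05
    mirna_min_abs_fc: float = 2.0
    mirna_min_score: float = 1.0
    gene_q: float = 0.05
    cis_window_bp: int = 100_000
    trans_min_abs_r: float = 0.95
    cerna_alpha: float = 0.05
    lnc_min_len: int = 200
    lnc_min_exons: int = 2
    lnc_min_cov: float = 3.0
    trend_epsilon: float = 0.25
    pseudocount: float = 1.0
    coding_filter: str = "all"       # "all": drop if all 4 tools call coding
    cerna_gate: str = "p"            # "p" (raw, as conventional) or "q"
    rescore: str = "keep_degrees"    # after same-trend miRNA drop: or "full"
    trans_scale: str = "log"         # "log": Pearson on log2(x+pc); "linear"
    n_total_mirnas: int | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, (lo, hi) in _CONFIG_RANGES.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValidationError(
                    f"config {name}={v} outside valid range [{lo}, {hi}]"
                )
        if self.mirna_p == 0.0 or self.gene_q == 0.0 or self.cerna_alpha == 0.0:
            raise ValidationError("significance gates must be > 0")
        if self.pseudocount <= 0:
            raise ValidationError("pseudocount must be > 0")
        if self.coding_filter not in ("all", "any"):
            raise ValidationError("coding_filter must be 'all' or 'any'")
        if self.cerna_gate not in ("p", "q"):
            raise ValidationError("cerna_gate must be 'p' or 'q'")
        if self.rescore not in ("keep_degrees", "full"):
            raise ValidationError("rescore must be 'keep_degrees' or 'full'")
        if self.trans_scale not in ("log", "linear"):
            raise ValidationError("trans_scale must be 'log' or 'linear'")
        if self.n_total_mirnas is not None and self.n_total_mirnas < 1:
            raise ValidationError("n_total_mirnas must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)
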