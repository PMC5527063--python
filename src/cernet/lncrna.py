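"""Four-step lncRNA candidate selection from assembled-transcript records.

Steps, applied in order:

1. mature transcript length >= ``lnc_min_len`` AND exon count >= ``lnc_min_exons``
2. read coverage >= ``lnc_min_cov`` in at least one sample
3. drop transcripts with a known non-lncRNA annotation (coding, known
   ncRNA classes, anything else already classified)
4. coding-potential consensus over the four external classifiers
   (CNCI, CPC, Pfam, PhyloCSF)

Step 4 has two documented modes: ``"all"`` (default) removes only
transcripts that *all four* tools call coding; ``"any"`` removes
transcripts that *any* tool calls coding.  The source protocol states both
readings in adjacent clauses, so neither is asserted as the intent — the
mode in force is always logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .model import PipelineConfig, TranscriptRecord, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["RejectionLog", "filter_lncrna_candidates"]

STEP_NAMES = (
    "length_and_exons",
    "coverage",
    "known_annotation",
    "coding_potential",
)


@dataclass
class RejectionLog:
    """Per-step bookkeeping: how many records survived each gate and which
    ids each gate removed.  ``kept + sum(rejected) == input`` always."""

    n_input: int
    survivors: dict[str, int] = field(default_factory=dict)
    rejected_ids: dict[str, list[str]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [("input", self.n_input, 0)]
        for step in STEP_NAMES:
            rows.append((step, self.survivors[step], len(self.rejected_ids[step])))
        return pd.DataFrame(rows, columns=["step", "survivors", "rejected"])


def filter_lncrna_candidates(
    records: Sequence[TranscriptRecord],
    config: PipelineConfig,
    coding_calls: Mapping[str, tuple[bool, bool, bool, bool]] | None = None,
) -> tuple[list[TranscriptRecord], RejectionLog]:
    """Run the 4-step candidate filter; returns survivors and the log.

    ``coding_calls`` supplements records whose own ``coding_calls`` field is
    absent; a record reaching step 4 with no calls from either source is a
    configuration error.
    """
    log = RejectionLog(n_input=len(records))
    current = list(records)

    def apply(step: str, keep_pred) -> None:
        nonlocal current
        kept, lost = [], []
        for rec in current:
            (kept if keep_pred(rec) else lost).append(rec)
        log.survivors[step] = len(kept)
        log.rejected_ids[step] = [r.id for r in lost]
        current = kept

    apply(
        "length_and_exons",
        lambda r: r.length >= config.lnc_min_len and r.exon_count >= config.lnc_min_exons,
    )
    apply("coverage", lambda r: r.min_coverage >= config.lnc_min_cov)
    apply("known_annotation", lambda r: r.biotype == "lncRNA_candidate")

    def calls_of(rec: TranscriptRecord) -> tuple[bool, bool, bool, bool]:
        if rec.coding_calls is not None:
            return rec.coding_calls
        if coding_calls is not None and rec.id in coding_calls:
            return coding_calls[rec.id]
        raise ValidationError(
            f"transcript {rec.id} reached the coding-potential step without "
            "coding calls from any of the four classifiers"
        )

    if config.coding_filter == "all":
        apply("coding_potential", lambda r: not all(calls_of(r)))
    else:  # "any": strict mode, keep only transcripts no tool calls coding
        apply("coding_potential", lambda r: not any(calls_of(r)))
    logger.info(
        "lncRNA filter: %d -> %s (coding_filter=%r)",
        log.n_input,
        {s: log.survivors[s] for s in STEP_NAMES},
        config.coding_filter,
    )
    return current, log
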