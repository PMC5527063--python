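"""lncRNA candidate selection and cis/trans target assignment."""

import numpy as np
import pandas as pd

from cernet import (
    ExpressionMatrix,
    PipelineConfig,
    TranscriptRecord,
    cis_targets,
    filter_lncrna_candidates,
    trans_targets,
)

cfg = PipelineConfig()

records = [
    TranscriptRecord("short", "1", "+", 1000, 1198, 2, 199, 10, "lncRNA_candidate", (False,) * 4),
    TranscriptRecord("ok", "1", "+", 5000, 5999, 2, 1000, 10, "lncRNA_candidate", (False,) * 4),
    TranscriptRecord("coding_by_all", "1", "+", 9000, 9999, 3, 1000, 10, "lncRNA_candidate", (True,) * 4),
]
kept, log = filter_lncrna_candidates(records, cfg)
print("kept:", [r.id for r in kept])
print(log.to_frame().to_string(index=False))
# gates: length >= 200 nt & >= 2 exons; coverage >= 3; known-annotation
# removal; removed only if all four coding-potential tools call it coding.

gene_near = TranscriptRecord("GENE_NEAR", "1", "+", 80_000, 90_000, 4, 4000, 20, "coding")
gene_far = TranscriptRecord("GENE_FAR", "1", "+", 900_000, 910_000, 4, 4000, 20, "coding")
print("cis (window 100 kb):", cis_targets(kept, [gene_near, gene_far], cfg.cis_window_bp))
# the near gene sits 74,001 bp downstream of 'ok', inside the 100-kb
# window (sign convention: negative = upstream, positive = downstream)

design = [("dry", "r1"), ("dry", "r2"), ("early", "r1"), ("early", "r2"),
          ("peak", "r1"), ("peak", "r2")]
x = np.array([4.0, 5, 20, 22, 90, 100])
lnc = ExpressionMatrix(pd.DataFrame([x], index=["ok"], columns=[f"{c}_{r}" for c, r in design]), design, "lncRNA")
genes = ExpressionMatrix(pd.DataFrame([3 * x, x[::-1]], index=["G_corr", "G_anti"],
                                      columns=[f"{c}_{r}" for c, r in design]), design, "mRNA")
print("trans (|r| > 0.95):", trans_targets(lnc, genes, cfg.trans_min_abs_r))
# G_corr tracks the lncRNA (r ~ 1, kept); G_anti mirrors it (r ~ -1, also
# kept: the gate is on |r|).
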