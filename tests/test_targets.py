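"""Cis-window search, trans co-expression edges, and the seed-match MRE
scanner."""

import numpy as np
import pandas as pd
import pytest

from cernet import ExpressionMatrix, TranscriptRecord, cis_targets, scan_mre, trans_targets
from cernet.model import DesignError, ValidationError
from cernet.targets import seed_site


def interval(id, start, end, chrom="1", biotype="coding"):
    return TranscriptRecord(
        id=id, chromosome=chrom, strand="+", start=start, end=end,
        exon_count=2, length=end - start + 1, biotype=biotype,
    )


class TestCisTargets:
    def test_inclusive_window_boundary(self):
        lnc = interval("l", 1_000_000, 1_001_000, biotype="lncRNA_candidate")
        at_limit = interval("g_in", 899_000, 900_000)     # gap exactly 100 kb
        past_limit = interval("g_out", 898_999, 899_999)  # gap 100,001
        hits = cis_targets([lnc], [at_limit, past_limit], 100_000)
        assert [(g, d) for _l, g, d in hits] == [("g_in", -100_000)]

    def test_overlap_gives_distance_zero(self):
        lnc = interval("l", 500, 1500, biotype="lncRNA_candidate")
        inside = interval("g", 900, 1100)
        assert cis_targets([lnc], [inside], 100_000) == [("l", "g", 0)]

    def test_downstream_gene_positive_distance(self):
        lnc = interval("l", 100, 200, biotype="lncRNA_candidate")
        down = interval("g", 700, 900)
        assert cis_targets([lnc], [down], 100_000) == [("l", "g", 500)]

    def test_different_chromosome_excluded(self):
        lnc = interval("l", 100, 200, biotype="lncRNA_candidate")
        far = interval("g", 150, 250, chrom="2")
        assert cis_targets([lnc], [far], 100_000) == []

    def test_gap_symmetric_under_role_swap(self):
        a = interval("a", 1000, 2000, biotype="lncRNA_candidate")
        b = interval("b", 5000, 6000)
        (d_ab,) = [d for *_x, d in cis_targets([a], [b], 10_000)]
        b2 = interval("b", 5000, 6000, biotype="lncRNA_candidate")
        a2 = interval("a", 1000, 2000)
        (d_ba,) = [d for *_x, d in cis_targets([b2], [a2], 10_000)]
        assert abs(d_ab) == abs(d_ba) == 3000


def _expr(rows: dict, feature_class: str, n_samples=9) -> ExpressionMatrix:
    design = [(c, f"r{i}") for c in ("dry", "early", "peak") for i in range(3)]
    df = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    df.columns = [f"{c}_{r}" for c, r in design][: df.shape[1]]
    return ExpressionMatrix(df, design[: df.shape[1]], feature_class)


class TestTransTargets:
    def test_scaled_profile_is_perfectly_correlated(self):
        x = np.array([10.0, 20, 40, 80, 160, 320, 640, 1280, 2560])
        lnc = _expr({"l": x}, "lncRNA")
        genes = _expr({"g": 2 * x}, "mRNA")
        (edge,) = trans_targets(lnc, genes, 0.95)
        assert edge[:2] == ("l", "g")
        assert edge[2] == pytest.approx(1.0, abs=1e-4)
        # exact invariance on the linear scale
        (lin,) = trans_targets(lnc, genes, 0.95, scale="linear")
        assert lin[2] == pytest.approx(1.0, abs=1e-12)

    def test_threshold_is_strictly_greater_than(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(1, 100, 9)
        y = rng.uniform(1, 100, 9)
        lnc = _expr({"l": x}, "lncRNA")
        genes = _expr({"g": y}, "mRNA")
        lx, ly = np.log2(x + 1), np.log2(y + 1)
        r = abs(np.corrcoef(lx, ly)[0, 1])
        assert trans_targets(lnc, genes, r) == []          # |r| == cut: out
        assert trans_targets(lnc, genes, r - 1e-9) != []   # just below: in

    def test_constant_profile_yields_no_edge(self):
        lnc = _expr({"l": np.full(9, 7.0)}, "lncRNA")
        genes = _expr({"g": np.arange(1.0, 10.0)}, "mRNA")
        assert trans_targets(lnc, genes, 0.5) == []

    def test_mismatched_design_rejected(self):
        lnc = _expr({"l": np.arange(1.0, 10.0)}, "lncRNA")
        design = [("a", "r0"), ("a", "r1"), ("b", "r0")]
        genes = ExpressionMatrix(
            pd.DataFrame([[1.0, 2, 3]], index=["g"],
                         columns=["a_r0", "a_r1", "b_r0"]),
            design, "mRNA",
        )
        with pytest.raises(DesignError):
            trans_targets(lnc, genes, 0.95)


class TestScanMRE:
    def test_hand_checked_seed_match(self):
        # miRNA positions 2-8 of UAGCAGCAC are AGCAGCA; the DNA reverse
        # complement is TGCTGCT, contained in the GTGCTGCT region
        mirna = {"m1": "UAGCAGCACAUAAUGGUUUGU"}
        target = {"t1": "AAAACCCGTGCTGCTACCCAAA"}
        table, hits = scan_mre(mirna, target)
        assert len(table) == 1
        (h,) = hits
        assert (h.mirna_id, h.target_id, h.site_type) == ("m1", "t1", "7mer-seed")
        assert target["t1"][h.site_start - 1 : h.site_start + 6] == "TGCTGCT"

    def test_no_site_no_edge(self):
        mirna = {"m1": "UAGCAGCACAUAAUGGUUUGU"}
        table, hits = scan_mre(mirna, {"t2": "A" * 50})
        assert len(table) == 0 and not hits

    def test_overlapping_occurrences_all_reported(self):
        # seed site AAAAAAA occurs twice (overlapping) in AAAAAAAA
        mirna = {"m": "GUUUUUUUCCCC"}
        assert seed_site(mirna["m"]) == "AAAAAAA"
        table, hits = scan_mre(mirna, {"t": "GGAAAAAAAAGG"})
        assert [h.site_start for h in hits] == [3, 4]
        (edge,) = table.edges
        assert edge.score == 2.0

    def test_u_t_normalization_equivalent(self):
        rna = {"m": "UAGCAGCACAUA"}
        dna = {"m": "TAGCAGCACATA"}
        t = {"t": "CCTGCTGCTCC"}
        assert scan_mre(rna, t)[1] == scan_mre(dna, t)[1]

    def test_short_mirna_rejected(self):
        with pytest.raises(ValidationError, match="shorter"):
            scan_mre({"m": "ACGUACG"}, {"t": "ACGT" * 10})

    def test_bad_alphabet_rejected(self):
        with pytest.raises(ValidationError, match="non-ACGU"):
            scan_mre({"m": "ACGUNNNACGU"}, {"t": "ACGT" * 10})

    def test_self_scan_without_complement_is_empty(self):
        seq = "A" * 30  # reverse complement of its own seed is T-run
        table, hits = scan_mre({"m": seq}, {"m_as_target": seq})
        assert not hits and len(table) == 0
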