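"""Differential-expression stand-in test, class-specific gates, BH
properties and trend classification."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from cernet import (
    ExpressionMatrix,
    PipelineConfig,
    benjamini_hochberg,
    classify_trend,
    de_test,
    log2_fold_change,
)
from cernet.diffexpr import _welch, direction_between
from cernet.model import DesignError, DomainError


class TestLog2FoldChange:
    def test_hand_arithmetic(self):
        assert log2_fold_change(5, 10, 1) == pytest.approx(math.log2(11 / 6))

    @given(
        x=st.floats(0, 1e6, allow_nan=False),
        c=st.floats(0.01, 10, allow_nan=False),
    )
    def test_identity_at_equal_means(self, x, c):
        assert log2_fold_change(x, x, c) == 0.0

    def test_zero_means_with_pseudocount(self):
        assert log2_fold_change(0, 0, 1) == 0.0

    @given(
        a=st.floats(0, 1e5),
        b=st.floats(0, 1e5),
        c=st.floats(0.1, 5),
    )
    def test_antisymmetry(self, a, b, c):
        assert log2_fold_change(a, b, c) == pytest.approx(
            -log2_fold_change(b, a, c), abs=1e-12
        )

    def test_negative_mean_rejected(self):
        with pytest.raises(DomainError):
            log2_fold_change(-1, 2, 1)


def _two_cond_matrix(values: np.ndarray, feature_class="mRNA") -> ExpressionMatrix:
    n = values.shape[0]
    design = [(c, f"r{i}") for c in ("dry", "early") for i in range(values.shape[1] // 2)]
    df = pd.DataFrame(
        values, index=[f"f{i}" for i in range(n)], columns=[f"{c}_{r}" for c, r in design]
    )
    return ExpressionMatrix(df, design, feature_class)


class TestDETest:
    def test_identical_replicates_give_p_one_not_de(self, config):
        expr = _two_cond_matrix(np.full((3, 6), 7.0))
        for r in de_test(expr, ("dry", "early"), config):
            assert r.p == 1.0
            assert not r.is_de
            assert r.log2_fc == 0.0

    def test_planted_eightfold_detected_in_most_draws(self, config):
        """100 independent features with a true 8-fold shift at
        noise_log2_sd = 0.1 stand in for 100 generator seeds."""
        rng = np.random.default_rng(42)
        base = 5.0
        left = 2.0 ** (base + rng.normal(0, 0.1, size=(100, 3)))
        right = 2.0 ** (base + 3.0 + rng.normal(0, 0.1, size=(100, 3)))
        expr = _two_cond_matrix(np.hstack([left, right]), feature_class="miRNA")
        results = de_test(expr, ("dry", "early"), config)
        assert sum(r.is_de for r in results) >= 95

    def test_mirdeep2_score_gate(self, config):
        values = np.array([[10.0, 10.1, 9.9, 80.0, 80.5, 79.5]] * 2)
        expr = _two_cond_matrix(values, feature_class="miRNA")
        scores = {"f0": 0.5, "f1": 1.0}
        r0, r1 = de_test(expr, ("dry", "early"), config, mirdeep2_scores=scores)
        assert r0.p < 0.05 and abs(r0.log2_fc) > 1  # signal is there...
        assert not r0.is_de  # ...but the score gate vetoes it
        assert r1.is_de

    def test_absent_score_passes_gate(self, config):
        values = np.array([[10.0, 10.1, 9.9, 80.0, 80.5, 79.5]])
        expr = _two_cond_matrix(values, feature_class="miRNA")
        (r,) = de_test(expr, ("dry", "early"), config, mirdeep2_scores={})
        assert r.is_de

    def test_gene_class_uses_q_not_raw_p(self):
        # one strong feature among many nulls: raw p tiny, q survives BH
        rng = np.random.default_rng(0)
        values = 2.0 ** rng.normal(5, 0.2, size=(50, 6))
        values[0, 3:] *= 100
        expr = _two_cond_matrix(values)
        results = de_test(expr, ("dry", "early"), PipelineConfig())
        assert results[0].is_de
        assert all(r.q >= r.p for r in results)

    def test_single_replicate_condition_rejected(self, config):
        design = [("dry", "r1"), ("early", "r1"), ("early", "r2")]
        df = pd.DataFrame([[1.0, 2.0, 3.0]], index=["f0"],
                          columns=["dry_r1", "early_r1", "early_r2"])
        expr = ExpressionMatrix(df, design, "mRNA")
        with pytest.raises(DesignError, match="dry"):
            de_test(expr, ("dry", "early"), config)

    def test_external_pvalues_bypass_welch(self, config):
        expr = _two_cond_matrix(np.full((2, 6), 5.0))
        res = de_test(expr, ("dry", "early"), config,
                      external_p={"f0": 0.001, "f1": 0.8})
        assert res[0].p == 0.001 and res[1].p == 0.8

    def test_welch_agrees_with_scipy_on_nondegenerate_data(self):
        rng = np.random.default_rng(7)
        a = rng.normal(5, 1, size=(200, 4))
        b = rng.normal(5.5, 2, size=(200, 5))
        _, p = _welch(a, b)
        ref = stats.ttest_ind(a, b, axis=1, equal_var=False).pvalue
        np.testing.assert_allclose(p, ref, rtol=1e-10)


class TestBenjaminiHochberg:
    def test_q_dominates_p_and_is_monotone(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=500)
        q = benjamini_hochberg(p)
        assert (q >= p - 1e-15).all() and (q <= 1).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_rejects_invalid_p(self):
        with pytest.raises(DomainError):
            benjamini_hochberg([0.5, 1.2])


class TestTrend:
    @pytest.mark.parametrize(
        "means,expected",
        [
            ((1, 2, 4), ("up", "up")),
            ((5, 5, 5), ("flat", "flat")),
            ((4, 2, 2.05), ("down", "flat")),
        ],
    )
    def test_direction_vectors(self, expr_factory, means, expected):
        expr = expr_factory({"f": list(means)})
        cfg = PipelineConfig(trend_epsilon=0.1)
        assert classify_trend(expr, "f", cfg).directions == expected

    def test_unknown_feature_raises(self, expr_factory, config):
        expr = expr_factory({"f": [1, 2, 3]})
        with pytest.raises(KeyError):
            classify_trend(expr, "nope", config)

    def test_swapping_conditions_flips_everything(self, expr_factory, config):
        fwd = expr_factory({"f": [1, 4, 16]})
        rev = expr_factory({"f": [16, 4, 1]})
        f = classify_trend(fwd, "f", config).directions
        r = classify_trend(rev, "f", config).directions
        flip = {"up": "down", "down": "up", "flat": "flat"}
        assert tuple(flip[d] for d in reversed(f)) == r
        assert direction_between(fwd, "f", ("dry", "peak"), config) == "up"
        assert direction_between(fwd, "f", ("peak", "dry"), config) == "down"
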