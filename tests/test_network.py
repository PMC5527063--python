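"""Hypergeometric scoring, candidate-pair construction, trend pruning and
network summary."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from cernet import (
    PipelineConfig,
    TargetEdge,
    TargetEdgeTable,
    build_candidate_pairs,
    hypergeom_pvalue,
    summarize_network,
    trend_prune,
)
from cernet.model import DomainError
from cernet.network import CeRNAPair, HypergeomParams


class TestHypergeomPvalue:
    @pytest.mark.parametrize(
        "N,K,n,c,expected",
        [
            (10, 3, 3, 3, 1 / 120),     # all three shared: 1 / C(10,3)
            (5, 2, 2, 1, 7 / 10),       # (C(2,1)C(3,1)+C(2,2)C(3,0))/C(5,2)
            (100, 1, 1, 1, 1 / 100),    # K=n=c=1 reduces to n/N
            (7, 4, 2, 0, 1.0),          # c=0: whole support
        ],
    )
    def test_hand_enumerated_values(self, N, K, n, c, expected):
        p = hypergeom_pvalue(HypergeomParams(N=N, K=K, n=n, c=c))
        assert p == pytest.approx(expected, rel=1e-12)

    @given(
        st.integers(1, 400).flatmap(
            lambda N: st.tuples(
                st.just(N), st.integers(0, N), st.integers(0, N)
            )
        ),
        st.data(),
    )
    def test_matches_scipy_survival_function(self, Nkn, data):
        N, K, n = Nkn
        c = data.draw(st.integers(0, min(K, n)))
        p = hypergeom_pvalue(HypergeomParams(N=N, K=K, n=n, c=c))
        ref = stats.hypergeom.sf(c - 1, N, K, n)
        assert p == pytest.approx(ref, rel=1e-9, abs=1e-12)

    @given(
        st.integers(2, 300).flatmap(
            lambda N: st.tuples(st.just(N), st.integers(1, N), st.integers(1, N))
        )
    )
    def test_nonincreasing_in_shared_count(self, Nkn):
        N, K, n = Nkn
        ps = [
            hypergeom_pvalue(HypergeomParams(N=N, K=K, n=n, c=c))
            for c in range(0, min(K, n) + 1)
        ]
        assert ps[0] == 1.0
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))

    @pytest.mark.parametrize("bad", [(5, 6, 2, 1), (5, 2, 6, 1), (5, 2, 2, 3)])
    def test_domain_errors(self, bad):
        N, K, n, c = bad
        with pytest.raises(DomainError):
            HypergeomParams(N=N, K=K, n=n, c=c)


def _edges(*triples):
    return TargetEdgeTable(TargetEdge(m, t, cls) for m, t, cls in triples)


class TestBuildCandidatePairs:
    def test_single_shared_mirna_small_universe(self, config):
        table = _edges(("m1", "l1", "lncRNA"), ("m1", "g1", "mRNA"))
        (pair,) = build_candidate_pairs(table, config, n_universe=100)
        assert pair.params == HypergeomParams(N=100, K=1, n=1, c=1)
        assert pair.p == pytest.approx(0.01)
        assert pair.q == pytest.approx(0.01)

    def test_disjoint_target_sets_emit_nothing(self, config):
        table = _edges(("m1", "l1", "lncRNA"), ("m2", "g1", "mRNA"))
        assert build_candidate_pairs(table, config, keep_all=True) == []

    def test_universe_smaller_than_degree_rejected(self, config):
        table = _edges(
            ("m1", "l1", "lncRNA"), ("m2", "l1", "lncRNA"), ("m1", "g1", "mRNA")
        )
        with pytest.raises(DomainError, match="universe"):
            build_candidate_pairs(table, config, n_universe=1)

    def test_gate_on_q_is_stricter_or_equal(self):
        rng = np.random.default_rng(8)
        triples = []
        for m in range(30):
            for t in rng.choice(40, size=4, replace=False):
                cls = "lncRNA" if t < 10 else "mRNA"
                name = f"l{t}" if t < 10 else f"g{t}"
                triples.append((f"m{m}", name, cls))
        table = _edges(*triples)
        p_gate = build_candidate_pairs(table, PipelineConfig(), n_universe=200)
        q_gate = build_candidate_pairs(
            table, PipelineConfig(cerna_gate="q"), n_universe=200
        )
        keys = lambda pairs: {(p.lncrna_id, p.mrna_id) for p in pairs}
        assert keys(q_gate) <= keys(p_gate)


def _pair(shared, comparison=("dry", "early"), K=None, n=None, N=50):
    K = K or len(shared)
    n = n or len(shared)
    params = HypergeomParams(N=N, K=K, n=n, c=len(shared))
    return CeRNAPair(
        lncrna_id="l1",
        mrna_id="g1",
        shared_mirnas=frozenset(shared),
        params=params,
        p=hypergeom_pvalue(params),
        comparison=comparison,
    )


class TestTrendPrune:
    def lookup(self, table):
        return lambda fid, comp: table[fid]

    def test_canonical_sponge_pattern_kept(self, config):
        dirs = self.lookup({"l1": "up", "g1": "up", "m1": "down"})
        kept, _ = trend_prune([_pair({"m1"})], dirs, config)
        assert len(kept) == 1
        assert kept[0].trend_consistent

    def test_same_trend_mirna_dropped_then_pair_pruned(self, config):
        dirs = self.lookup({"l1": "up", "g1": "up", "m1": "up"})
        kept, (ann,) = trend_prune([_pair({"m1"})], dirs, config)
        assert kept == []
        assert ann.dropped_mirnas == {"m1"}
        assert ann.params.c == 0 and ann.p == 1.0

    def test_flat_or_discordant_targets_pruned(self, config):
        for l_dir, g_dir in (("flat", "flat"), ("up", "down")):
            dirs = self.lookup({"l1": l_dir, "g1": g_dir, "m1": "down"})
            kept, (ann,) = trend_prune([_pair({"m1"})], dirs, config)
            assert kept == [] and not ann.trend_consistent

    def test_rescoring_never_decreases_p_with_kept_degrees(self, config):
        pair = _pair({"m1", "m2", "m3"}, K=5, n=4, N=60)
        dirs = self.lookup(
            {"l1": "up", "g1": "up", "m1": "down", "m2": "up", "m3": "down"}
        )
        kept, (ann,) = trend_prune([pair], dirs, config)
        assert ann.params == HypergeomParams(N=60, K=5, n=4, c=2)
        assert ann.p >= pair.p
        assert kept and kept[0].shared_mirnas == {"m1", "m3"}

    def test_full_rescore_shrinks_degrees_too(self):
        cfg = PipelineConfig(rescore="full")
        pair = _pair({"m1", "m2"}, K=4, n=3, N=60)
        dirs = self.lookup({"l1": "up", "g1": "up", "m1": "down", "m2": "up"})
        _, (ann,) = trend_prune([pair], dirs, cfg)
        assert ann.params == HypergeomParams(N=60, K=3, n=2, c=1)

    def test_missing_direction_is_lookup_error(self, config):
        with pytest.raises(KeyError):
            trend_prune([_pair({"m1"})], {}, config)


class TestSummarize:
    def test_empty_network_all_zeros(self):
        s = summarize_network([])
        assert s["overall"] == {"pairs": 0, "mrnas": 0, "mirnas": 0, "lncrnas": 0}

    def test_single_pair_two_shared_mirnas(self):
        s = summarize_network([_pair({"m1", "m2"})])
        assert s["overall"] == {"pairs": 1, "mrnas": 1, "mirnas": 2, "lncrnas": 1}
        assert s["by_comparison"]["dry|early"]["pairs"] == 1
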