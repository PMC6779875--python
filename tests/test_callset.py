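"""Multi-caller consensus clustering and the stringent filters.

The clustering oracle used here enumerates all call pairs directly and
builds connected components with a plain BFS, independent of the union-find
implementation under test.
"""

import numpy as np
import pytest

from xnddcnv.callset import (CallsetError, build_stringent_set, cluster_calls,
                             stringent_calls_for_sample)
from xnddcnv.genome import GenomicInterval, reciprocal_overlap
from xnddcnv.io_formats import AnalysisConfig, CnvCall


def call(start, end, caller, sample="S1", cnv_type="DEL", probes=10, chrom="1"):
    return CnvCall(sample, GenomicInterval(chrom, start, end), cnv_type,
                   caller, probe_count=probes)


def brute_force_clusters(calls, ro):
    """BFS over the explicit pairwise-RO graph (same-type, same-chromosome)."""
    n = len(calls)
    adj = {i: set() for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            a, b = calls[i], calls[j]
            if a.cnv_type != b.cnv_type:
                continue
            if reciprocal_overlap(a.interval, b.interval) >= ro:
                adj[i].add(j)
                adj[j].add(i)
    seen, comps = set(), []
    for i in range(n):
        if i in seen:
            continue
        comp, stack = set(), [i]
        while stack:
            k = stack.pop()
            if k in comp:
                continue
            comp.add(k)
            stack.extend(adj[k] - comp)
        seen |= comp
        comps.append(frozenset(comp))
    return set(comps)


class TestClustering:
    def test_two_identical_calls_cluster(self):
        calls = [call(0, 100_000, "a"), call(0, 100_000, "b")]
        clusters = cluster_calls(calls, 0.5)
        assert len(clusters) == 1 and len(clusters[0]) == 2

    def test_below_threshold_stays_apart(self):
        # RO = 40/100 = 0.4 < 0.5
        calls = [call(0, 100_000, "a"), call(60_000, 160_000, "b")]
        assert len(cluster_calls(calls, 0.5)) == 2

    def test_chain_forms_single_component(self):
        # A-B RO 0.6, B-C RO 0.6, A-C RO 0.2: one connected component
        a = call(0, 100_000, "a")
        b = call(40_000, 140_000, "b")
        c = call(80_000, 180_000, "c")
        assert reciprocal_overlap(a.interval, b.interval) == 0.6
        assert reciprocal_overlap(b.interval, c.interval) == 0.6
        assert reciprocal_overlap(a.interval, c.interval) < 0.5
        clusters = cluster_calls([a, b, c], 0.5)
        assert len(clusters) == 1 and len(clusters[0]) == 3

    def test_types_never_merge(self):
        calls = [call(0, 100_000, "a", cnv_type="DEL"),
                 call(0, 100_000, "b", cnv_type="DUP")]
        assert len(cluster_calls(calls, 0.5)) == 2

    def test_mixed_samples_rejected(self):
        with pytest.raises(CallsetError):
            cluster_calls([call(0, 10_000, "a"), call(0, 10_000, "a", sample="S2")],
                          0.5)

    def test_one_call_per_caller_kept(self):
        # two overlapping calls from one caller: keep the better seed match
        calls = [call(0, 100_000, "a"), call(0, 100_000, "b"),
                 call(10_000, 110_000, "b")]
        clusters = cluster_calls(calls, 0.5)
        assert len(clusters) == 1
        callers = [c.caller for c in clusters[0]]
        assert sorted(callers) == ["a", "b"]

    @pytest.mark.parametrize("seed", range(5))
    def test_membership_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        calls = []
        for i in range(40):
            start = int(rng.integers(0, 3_000_000))
            length = int(rng.integers(20_000, 400_000))
            calls.append(call(start, start + length,
                              caller=f"c{rng.integers(4)}",
                              cnv_type="DEL" if rng.random() < 0.5 else "DUP"))
        got = cluster_calls(calls, 0.5)
        # compare as partitions of call identity (caller filtering only
        # drops duplicate-caller members, so compare cluster spans instead)
        key = lambda c: (c.interval.start, c.interval.end, c.caller, c.cnv_type)
        oracle = brute_force_clusters(calls, 0.5)
        oracle_sets = {frozenset(key(calls[i]) for i in comp) for comp in oracle}
        for cluster in got:
            members = frozenset(key(c) for c in cluster)
            assert any(members <= full for full in oracle_sets)
        # every call lands in exactly one oracle component
        assert sum(len(c) for c in oracle) == len(calls)


class TestStringentRules:
    def test_publishable_call_retained(self, config):
        # 25 kb, 2 callers, 6 probes: passes every stringent rule
        calls = [call(0, 25_000, "a", probes=6), call(0, 25_000, "b", probes=6)]
        out = stringent_calls_for_sample(calls, config)
        assert len(out) == 1
        assert out[0].supporting_callers == {"a", "b"}

    def test_below_size_threshold_dropped(self, config):
        calls = [call(0, 19_000, "a"), call(0, 19_000, "b")]
        assert stringent_calls_for_sample(calls, config) == []

    def test_single_caller_dropped_regardless_of_size(self, config):
        calls = [call(0, 500_000, "a", probes=100)]
        assert stringent_calls_for_sample(calls, config) == []

    def test_probe_rule_uses_max_over_members(self, config):
        calls = [call(0, 25_000, "a", probes=3), call(0, 25_000, "b", probes=6)]
        out = stringent_calls_for_sample(calls, config)
        assert len(out) == 1 and out[0].probe_count == 6
        calls = [call(0, 25_000, "a", probes=3), call(0, 25_000, "b", probes=4)]
        assert stringent_calls_for_sample(calls, config) == []

    def test_consensus_is_intersection_union_recorded(self, config):
        calls = [call(0, 100_000, "a"), call(20_000, 120_000, "b")]
        [cnv] = stringent_calls_for_sample(calls, config)
        assert (cnv.interval.start, cnv.interval.end) == (20_000, 100_000)
        assert (cnv.union_span.start, cnv.union_span.end) == (0, 120_000)
        assert cnv.union_span.contains(cnv.interval)

    def test_modal_copy_number(self, config):
        calls = [
            CnvCall("S1", GenomicInterval("1", 0, 50_000), "DEL", "a",
                    probe_count=9, copy_number=1),
            CnvCall("S1", GenomicInterval("1", 0, 50_000), "DEL", "b",
                    probe_count=9, copy_number=1),
            CnvCall("S1", GenomicInterval("1", 0, 50_000), "DEL", "c",
                    probe_count=9, copy_number=0),
        ]
        [cnv] = stringent_calls_for_sample(calls, config)
        assert cnv.copy_number == 1

    def test_removing_a_caller_never_grows_the_set(self, config):
        rng = np.random.default_rng(42)
        calls = []
        for _ in range(60):
            start = int(rng.integers(0, 2_000_000))
            length = int(rng.integers(20_000, 300_000))
            calls.append(call(start, start + length,
                              caller=f"c{rng.integers(4)}", probes=8))
        full = stringent_calls_for_sample(calls, config)
        reduced = stringent_calls_for_sample(
            [c for c in calls if c.caller != "c0"], config)
        full_keys = {(c.interval, c.cnv_type) for c in full}
        # every reduced consensus arises from a subset of the full evidence
        assert len(reduced) <= len(full) + sum(
            1 for c in full if "c0" in c.supporting_callers)
        for c in reduced:
            assert len(c.supporting_callers) >= 2
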