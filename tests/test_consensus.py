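"""Consensus construction: sample collection, edge filtering, trimming,
aggregation, and the end-to-end builder against a brute-force oracle."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from braincons.consensus import (
    ConsensusPolicy,
    aggregate_edge,
    build_consensus,
    collect_samples,
    filter_consensus_edges,
    trim_extremes,
)
from braincons.exceptions import ConfigError, InputError
from braincons.model import BrainGraph, EdgeRecord

from conftest import brute_force_consensus, make_nodes, random_runs


def _single_edge_run(nodes, count, length=40.0, fa=0.5):
    g = BrainGraph(nodes=dict(nodes))
    g.add_edge(EdgeRecord(u=1, v=2, fiber_count=count, mean_length=length, mean_fa=fa))
    return g


# ---------------------------------------------------------------------------
# collect_samples
# ---------------------------------------------------------------------------

def test_collect_identical_runs(nodes5):
    runs = [_single_edge_run(nodes5, 4) for _ in range(10)]
    table = collect_samples(runs)
    assert set(table) == {(1, 2)}
    s = table[(1, 2)]
    assert s.runs_present == 10
    assert s.fiber_counts == [4.0] * 10
    assert s.run_ids == list(range(10))


def test_collect_partial_presence(nodes5):
    runs = [_single_edge_run(nodes5, 4) for _ in range(9)]
    runs.append(BrainGraph(nodes=dict(nodes5)))  # run 10 misses the edge
    table = collect_samples(runs)
    assert table[(1, 2)].runs_present == 9


def test_collect_rejects_single_run(nodes5):
    with pytest.raises(InputError):
        collect_samples([_single_edge_run(nodes5, 4)])


def test_collect_rejects_node_set_mismatch(nodes5):
    runs = [_single_edge_run(nodes5, 4), BrainGraph(nodes=make_nodes(4))]
    with pytest.raises(InputError, match="run 1"):
        collect_samples(runs)


def test_collect_matches_exhaustive_enumeration():
    """Table contents equal a direct pair-by-run scan on random runs."""
    runs = random_runs(5, 3, seed=9, edge_prob=0.6)
    table = collect_samples(runs)
    ids = sorted(runs[0].nodes)
    for i, u in enumerate(ids):
        for v in ids[i + 1:]:
            expected = [
                (ri, run.edges[(u, v)].fiber_count)
                for ri, run in enumerate(runs)
                if (u, v) in run.edges
            ]
            if not expected:
                assert (u, v) not in table
            else:
                s = table[(u, v)]
                assert list(zip(s.run_ids, s.fiber_counts)) == expected


# ---------------------------------------------------------------------------
# filter_consensus_edges
# ---------------------------------------------------------------------------

def test_filter_drops_nine_of_ten(nodes5):
    runs = [_single_edge_run(nodes5, 4) for _ in range(9)]
    runs.append(BrainGraph(nodes=dict(nodes5)))
    table = collect_samples(runs)
    kept = filter_consensus_edges(table, ConsensusPolicy(), n_runs=10)
    assert kept == {}


def test_filter_is_identity_when_all_present(runs10):
    # restrict to an always-present synthetic edge set
    runs = [_single_edge_run(runs10[0].nodes, c) for c in range(1, 11)]
    table = collect_samples(runs)
    assert filter_consensus_edges(table, ConsensusPolicy(), 10) == table


def test_filter_equals_set_intersection_oracle():
    runs = random_runs(8, 10, seed=5, edge_prob=0.85)
    table = collect_samples(runs)
    kept = filter_consensus_edges(table, ConsensusPolicy(), len(runs))
    expected = frozenset.intersection(*(r.edge_set() for r in runs))
    assert frozenset(kept) == expected


def test_filter_relaxed_presence():
    runs = random_runs(6, 10, seed=2, edge_prob=0.5)
    table = collect_samples(runs)
    kept = filter_consensus_edges(
        table, ConsensusPolicy(required_presence=7), len(runs)
    )
    assert frozenset(kept) == frozenset(
        k for k, s in table.items() if s.runs_present >= 7
    )


# ---------------------------------------------------------------------------
# trim_extremes
# ---------------------------------------------------------------------------

def test_trim_ten_values_leaves_eight():
    retained, dropped = trim_extremes([3, 9, 1, 7, 5, 8, 2, 6, 4, 10])
    assert len(retained) == 8
    assert len(dropped) == 2
    assert 1 not in retained and 10 not in retained


def test_trim_constant_vector():
    retained, dropped = trim_extremes([5.0] * 10)
    assert retained == [5.0] * 8
    assert sorted(dropped) == [0, 9]  # lowest index for min, highest for max


def test_trim_one_to_ten_mean():
    retained, _ = trim_extremes(list(range(1, 11)))
    assert retained == list(range(2, 10))
    assert np.mean(retained) == 5.5


def test_trim_too_short_vector_rejected():
    with pytest.raises(InputError):
        trim_extremes([1.0, 2.0])


@settings(derandomize=True, max_examples=200)
@given(st.lists(st.floats(min_value=1, max_value=1e6), min_size=3, max_size=30))
def test_trim_bounds_property(values):
    """Trimming can only shrink the range; the trimmed mean stays within
    the raw [min, max]."""
    retained, dropped = trim_extremes(values)
    assert len(retained) == len(values) - 2
    assert min(retained) >= min(values)
    assert max(retained) <= max(values)
    eps = 1e-9 * max(abs(v) for v in values)
    assert min(values) - eps <= np.mean(retained) <= max(values) + eps
    # dropped indices actually attain the extremes
    assert values[dropped[0]] == min(values)
    assert values[dropped[1]] == max(values)


# ---------------------------------------------------------------------------
# aggregate_edge
# ---------------------------------------------------------------------------

def _samples(counts, lengths=None, fas=None):
    from braincons.consensus import EdgeSamples

    n = len(counts)
    s = EdgeSamples()
    lengths = lengths or [40.0] * n
    fas = fas or [0.5] * n
    for i in range(n):
        s.append(i, counts[i], lengths[i], fas[i])
    return s


def test_aggregate_constant_coweights():
    fiber, length, fa = aggregate_edge(_samples(list(range(1, 11))), ConsensusPolicy())
    assert (fiber, length, fa) == (5.5, 40.0, 0.5)


def test_aggregate_constant_counts():
    fiber, _, _ = aggregate_edge(_samples([3] * 10), ConsensusPolicy())
    assert fiber == 3.0


def test_aggregate_all_runs_population_switch():
    s = _samples([1, 2, 3, 4], lengths=[10, 20, 30, 40], fas=[0.1, 0.2, 0.3, 0.4])
    f1, l1, a1 = aggregate_edge(s, ConsensusPolicy(length_fa_population="trimmed"))
    f2, l2, a2 = aggregate_edge(s, ConsensusPolicy(length_fa_population="all"))
    assert f1 == f2 == 2.5
    assert (l1, a1) == (25.0, pytest.approx(0.25))  # rows 2 and 3 kept
    assert (l2, a2) == (25.0, pytest.approx(0.25))  # all four rows, same mean here
    s2 = _samples([1, 2, 3, 4], lengths=[100, 20, 30, 40], fas=[0.9, 0.2, 0.3, 0.4])
    _, l3, a3 = aggregate_edge(s2, ConsensusPolicy(length_fa_population="all"))
    assert l3 == pytest.approx(47.5)
    assert a3 == pytest.approx(0.45)


def test_aggregate_matches_sort_drop_average_oracle():
    rng = np.random.default_rng(3)
    for _ in range(50):
        n = int(rng.integers(3, 12))
        counts = rng.integers(1, 100, size=n).astype(float).tolist()
        lengths = rng.uniform(5, 150, size=n).tolist()
        fas = rng.uniform(0, 1, size=n).tolist()
        got = aggregate_edge(_samples(counts, lengths, fas), ConsensusPolicy())
        rows = sorted(zip(counts, lengths, fas))[1:-1]
        exp = tuple(sum(r[j] for r in rows) / len(rows) for j in range(3))
        assert got == pytest.approx(exp, rel=1e-12)


# ---------------------------------------------------------------------------
# build_consensus
# ---------------------------------------------------------------------------

def test_consensus_of_identical_runs_is_fixed_point(nodes5):
    runs = [_single_edge_run(nodes5, 7, length=52.0, fa=0.61) for _ in range(10)]
    cons = build_consensus(runs)
    assert cons.edge_set() == runs[0].edge_set()
    e = cons.edges[(1, 2)]
    assert (e.fiber_count, e.mean_length, e.mean_fa) == (7.0, 52.0, 0.61)


def test_private_edge_excluded(nodes5):
    runs = [_single_edge_run(nodes5, 5) for _ in range(10)]
    runs[3].add_edge(EdgeRecord(u=2, v=3, fiber_count=9, mean_length=30, mean_fa=0.4))
    cons = build_consensus(runs)
    assert (2, 3) not in cons.edges
    assert (1, 2) in cons.edges


def test_consensus_matches_brute_force_oracle():
    runs = random_runs(8, 10, seed=17, edge_prob=0.9)
    cons = build_consensus(runs)
    expected = brute_force_consensus(runs)
    assert cons.edge_set() == frozenset(expected)
    for key, (f, l, a) in expected.items():
        e = cons.edges[key]
        assert (e.fiber_count, e.mean_length, e.mean_fa) == pytest.approx((f, l, a))


def test_consensus_order_invariance():
    runs = random_runs(6, 10, seed=23, edge_prob=0.8)
    base = build_consensus(runs)
    rng = np.random.default_rng(0)
    for _ in range(5):
        perm = list(rng.permutation(len(runs)))
        shuffled = build_consensus([runs[i] for i in perm])
        assert shuffled.edges == base.edges


def test_adding_a_run_shrinks_or_preserves_edges():
    runs = random_runs(6, 11, seed=31, edge_prob=0.8)
    before = build_consensus(runs[:10]).edge_set()
    after = build_consensus(runs).edge_set()
    assert after <= before


def test_degenerate_policy_rejected(nodes5):
    runs = [_single_edge_run(nodes5, 4), _single_edge_run(nodes5, 6)]
    with pytest.raises(ConfigError):
        build_consensus(runs)  # 2 runs, trim 1+1 leaves nothing


def test_consensus_preserves_nodes_and_records_provenance(runs10):
    cons = build_consensus(runs10)
    assert cons.nodes == runs10[0].nodes
    assert cons.provenance["stage"] == "consensus"
    assert cons.provenance["n_runs"] == 10
    assert cons.provenance["required_presence"] == 10
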