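"""Shared fixtures and independent oracles used across the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from braincons.model import BrainGraph, EdgeRecord, Hemisphere, NodeRecord


def make_nodes(n: int) -> dict[int, NodeRecord]:
    return {
        i: NodeRecord(
            node_id=i,
            label=f"region_{i:03d}",
            hemisphere=Hemisphere.LEFT if i % 2 else Hemisphere.RIGHT,
            position=(float(i), float(2 * i), float(3 * i)),
        )
        for i in range(1, n + 1)
    }


def random_run(nodes: dict[int, NodeRecord], rng: np.random.Generator,
               edge_prob: float = 0.5) -> BrainGraph:
    """One synthetic per-run graph: random edge subset, integer fiber
    counts >= 1, random lengths and FA."""
    g = BrainGraph(nodes=dict(nodes))
    ids = sorted(nodes)
    for i, u in enumerate(ids):
        for v in ids[i + 1:]:
            if rng.random() < edge_prob:
                g.add_edge(EdgeRecord(
                    u=u, v=v,
                    fiber_count=float(rng.integers(1, 50)),
                    mean_length=float(rng.uniform(10.0, 150.0)),
                    mean_fa=float(rng.uniform(0.05, 0.95)),
                ))
    return g


def random_runs(n_nodes: int, n_runs: int, seed: int,
                edge_prob: float = 0.5) -> list[BrainGraph]:
    rng = np.random.default_rng(seed)
    nodes = make_nodes(n_nodes)
    return [random_run(nodes, rng, edge_prob) for _ in range(n_runs)]


def brute_force_consensus(runs, n_trim_low=1, n_trim_high=1):
    """Monolithic re-implementation of the consensus rule, written as a
    direct double loop over node pairs and runs (the independent oracle):
    keep a pair iff every run contains it, sort its (count, length, fa)
    observations, drop the extremes, average the rest."""
    ids = sorted(runs[0].nodes)
    out = {}
    for i, u in enumerate(ids):
        for v in ids[i + 1:]:
            obs = []
            for run in runs:
                if (u, v) in run.edges:
                    e = run.edges[(u, v)]
                    obs.append((e.fiber_count, e.mean_length, e.mean_fa))
            if len(obs) != len(runs):
                continue
            obs.sort()
            kept = obs[n_trim_low:len(obs) - n_trim_high]
            m = len(kept)
            out[(u, v)] = (
                sum(o[0] for o in kept) / m,
                sum(o[1] for o in kept) / m,
                sum(o[2] for o in kept) / m,
            )
    return out


@pytest.fixture
def nodes5():
    return make_nodes(5)


@pytest.fixture
def runs10(nodes5):
    return random_runs(5, 10, seed=42, edge_prob=0.7)
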