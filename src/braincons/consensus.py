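"""Consensus braingraph construction from repeated tractography runs.

Probabilistic tractography gives a different graph on every run.  The
consensus procedure makes one robust graph per subject from k per-run
graphs:

1. collect, for every node pair, the per-run fiber counts, mean lengths
   and mean FAs of the runs in which the pair was connected;
2. keep only edges present in every run (configurable via
   ``required_presence``);
3. for each surviving edge, drop the runs attaining the minimal and the
   maximal fiber count (one of each by default) and average the
   remaining observations into the edge's three weights.

With the default policy on 10 runs this leaves 8 observations per edge,
so consensus fiber counts are typically non-integer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

from .exceptions import ConfigError, InputError
from .model import BrainGraph, EdgeRecord

__all__ = [
    "EdgeSamples",
    "EdgeSampleTable",
    "ConsensusPolicy",
    "collect_samples",
    "filter_consensus_edges",
    "trim_extremes",
    "aggregate_edge",
    "build_consensus",
]


@dataclass
class EdgeSamples:
    """Per-run observations of one node pair, ordered by run index."""

    run_ids: list[int] = field(default_factory=list)
    fiber_counts: list[float] = field(default_factory=list)
    lengths: list[float] = field(default_factory=list)
    fas: list[float] = field(default_factory=list)

    @property
    def runs_present(self) -> int:
        return len(self.run_ids)

    def append(self, run_id: int, count: float, length: float, fa: float) -> None:
        self.run_ids.append(run_id)
        self.fiber_counts.append(count)
        self.lengths.append(length)
        self.fas.append(fa)


# Table keyed by canonical unordered node pair.
EdgeSampleTable = dict[tuple[int, int], EdgeSamples]


@dataclass(frozen=True)
class ConsensusPolicy:
    """Edge-acceptance and trimming policy.

    ``required_presence=None`` means "present in all runs" (the default
    rule).  ``length_fa_population`` selects whether lengths and FA are
    averaged over the runs retained by the fiber-count trim (default) or
    over all runs in which the edge appeared.
    """

    required_presence: int | None = None
    n_trim_low: int = 1
    n_trim_high: int = 1
    length_fa_population: Literal["trimmed", "all"] = "trimmed"

    def resolve_presence(self, n_runs: int) -> int:
        req = n_runs if self.required_presence is None else self.required_presence
        if req < 1 or req > n_runs:
            raise ConfigError(
                f"required_presence={req} is outside [1, n_runs={n_runs}]"
            )
        if self.n_trim_low < 0 or self.n_trim_high < 0:
            raise ConfigError("trim counts must be non-negative")
        if self.n_trim_low + self.n_trim_high >= req:
            raise ConfigError(
                f"trimming {self.n_trim_low}+{self.n_trim_high} values from "
                f"{req} retained runs would leave nothing to average"
            )
        return req


def collect_samples(runs: Sequence[BrainGraph]) -> EdgeSampleTable:
    """Gather per-edge observation vectors across runs.

    All runs must share the same node set; the table has one entry for
    every edge occurring in at least one run, vectors ordered by run
    index.
    """
    if len(runs) < 2:
        raise InputError(f"need at least 2 runs, got {len(runs)}")
    reference = runs[0]
    for i, run in enumerate(runs[1:], start=1):
        if not reference.same_nodes_as(run):
            raise InputError(f"run {i} has a different node set than run 0")
    table: EdgeSampleTable = {}
    for run_id, run in enumerate(runs):
        for key, edge in run.edges.items():
            table.setdefault(key, EdgeSamples()).append(
                run_id, edge.fiber_count, edge.mean_length, edge.mean_fa
            )
    return table


def filter_consensus_edges(
    table: EdgeSampleTable, policy: ConsensusPolicy, n_runs: int
) -> EdgeSampleTable:
    """Keep only edges observed in at least ``required_presence`` runs
    (all runs by default)."""
    required = policy.resolve_presence(n_runs)
    return {key: s for key, s in table.items() if s.runs_present >= required}


def trim_extremes(
    values: Sequence[float], n_trim_low: int = 1, n_trim_high: int = 1
) -> tuple[list[float], tuple[int, ...]]:
    """Drop ``n_trim_low`` minimal and ``n_trim_high`` maximal values.

    Returns (retained values in original order, dropped indices).  Ties
    are broken deterministically: among equal values the lowest index is
    dropped for the minimum and the highest index for the maximum.
    """
    n = len(values)
    if n_trim_low < 0 or n_trim_high < 0:
        raise InputError("trim counts must be non-negative")
    if n <= n_trim_low + n_trim_high:
        raise InputError(
            f"cannot trim {n_trim_low}+{n_trim_high} values from a vector of length {n}"
        )
    order = sorted(range(n), key=lambda i: (values[i], i))
    dropped = tuple(order[:n_trim_low]) + tuple(order[n - n_trim_high :])
    dropped_set = set(dropped)
    retained = [values[i] for i in range(n) if i not in dropped_set]
    return retained, dropped


def aggregate_edge(samples: EdgeSamples, policy: ConsensusPolicy) -> tuple[float, float, float]:
    """Trimmed-average one edge's observations into its three weights.

    The trim applies to the fiber-count vector only; sample rows are
    ordered by (count, length, fa) so the result is invariant under
    run-order permutation even when counts tie.  Lengths and FA are
    averaged over the trim-surviving rows (default) or over all rows.
    """
    n = samples.runs_present
    if n <= policy.n_trim_low + policy.n_trim_high:
        raise InputError(
            f"edge observed in {n} runs; cannot trim "
            f"{policy.n_trim_low}+{policy.n_trim_high} values"
        )
    rows = sorted(zip(samples.fiber_counts, samples.lengths, samples.fas))
    lo, hi = policy.n_trim_low, n - policy.n_trim_high
    kept = rows[lo:hi]
    fiber = sum(r[0] for r in kept) / len(kept)
    if policy.length_fa_population == "trimmed":
        length = sum(r[1] for r in kept) / len(kept)
        fa = sum(r[2] for r in kept) / len(kept)
    else:
        length = sum(samples.lengths) / n
        fa = sum(samples.fas) / n
    return fiber, length, fa


def build_consensus(
    runs: Sequence[BrainGraph], policy: ConsensusPolicy | None = None
) -> BrainGraph:
    """Build the consensus braingraph of one subject from per-run graphs.

    Composition of :func:`collect_samples`, :func:`filter_consensus_edges`
    and :func:`aggregate_edge`; the node set is preserved and provenance
    records the run count and policy.
    """
    policy = policy or ConsensusPolicy()
    n_runs = len(runs)
    table = collect_samples(runs)
    surviving = filter_consensus_edges(table, policy, n_runs)
    out = BrainGraph(
        nodes=dict(runs[0].nodes),
        resolution_label=runs[0].resolution_label,
        provenance={
            "stage": "consensus",
            "n_runs": n_runs,
            "required_presence": policy.resolve_presence(n_runs),
            "n_trim_low": policy.n_trim_low,
            "n_trim_high": policy.n_trim_high,
            "length_fa_population": policy.length_fa_population,
        },
    )
    for (u, v), samples in sorted(surviving.items()):
        fiber, length, fa = aggregate_edge(samples, policy)
        out.add_edge(EdgeRecord(u=u, v=v, fiber_count=fiber, mean_length=length, mean_fa=fa))
    return out


def stage_counts(runs: Sequence[BrainGraph], policy: ConsensusPolicy | None = None) -> dict:
    """Per-stage edge counts (per-run, union, surviving) for audit logs."""
    policy = policy or ConsensusPolicy()
    table = collect_samples(runs)
    surviving = filter_consensus_edges(table, policy, len(runs))
    return {
        "per_run_edges": [run.n_edges for run in runs],
        "union_edges": len(table),
        "consensus_edges": len(surviving),
    }
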