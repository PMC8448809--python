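"""Stochastic tractography-output simulator.

Probabilistic tractography of a fixed brain yields a different graph on
every run.  This module emulates that: a latent ground-truth edge set in
which each run independently *detects* each true edge with probability
p and, when detected, reports

* a fiber count drawn from a zero-truncated Poisson(lambda) — an edge
  exists in a run only if at least one streamline was found, so the
  count noise is conditioned on >= 1 while p models detection
  separately;
* a mean streamline length from a positive-truncated Normal (mm);
* a mean FA from a Beta law parameterised by (mean, concentration), so
  the [0, 1] FA invariant holds by construction.

No false-positive edges are generated by default (keeping the noiseless
limit exact); an optional spurious-edge rate supports stress tests.  The
laws are test scaffolding for the consensus and sweep machinery, not a
claim about any particular tractography implementation.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .exceptions import ConfigError
from .model import (
    BrainGraph,
    EdgeRecord,
    Hemisphere,
    NodeRecord,
    ParcellationHierarchy,
    canonical_pair,
)

__all__ = [
    "EdgeParams",
    "GroundTruthModel",
    "SimulationConfig",
    "DEFAULT_PARAMETER_RANGES",
    "make_ground_truth",
    "simulate_run",
    "simulate_runs",
    "run_source_from_model",
    "make_hierarchy",
]

#: Study-condition defaults for randomly drawn edge parameters:
#: detection probability, fiber-count rate (log-uniform), streamline
#: length mean/sd in mm, FA mean and Beta concentration.
DEFAULT_PARAMETER_RANGES: dict[str, tuple[float, float]] = {
    "detection_probability": (0.8, 1.0),
    "count_rate": (3.0, 300.0),
    "length_mean": (20.0, 160.0),
    "length_sd": (2.0, 12.0),
    "fa_mean": (0.25, 0.65),
    "fa_concentration": (50.0, 200.0),
}


@dataclass(frozen=True)
class EdgeParams:
    """Latent parameters of one true edge."""

    detection_probability: float
    count_rate: float
    length_mean: float
    length_sd: float
    fa_mean: float
    fa_concentration: float

    def __post_init__(self) -> None:
        if not (0.0 < self.detection_probability <= 1.0):
            raise ConfigError(f"detection probability must be in (0, 1], got {self.detection_probability}")
        if self.count_rate <= 0 or self.length_mean <= 0 or self.length_sd < 0:
            raise ConfigError("count rate and length mean must be positive; length sd >= 0")
        if not (0.0 < self.fa_mean < 1.0) or self.fa_concentration <= 0:
            raise ConfigError("fa_mean must be in (0, 1) and fa_concentration positive")


@dataclass
class GroundTruthModel:
    """Latent node set and true edges with their noise parameters."""

    nodes: list[NodeRecord]
    true_edges: dict[tuple[int, int], EdgeParams]

    def __post_init__(self) -> None:
        ids = {n.node_id for n in self.nodes}
        for (u, v) in self.true_edges:
            if u == v or u not in ids or v not in ids:
                raise ConfigError(f"true edge ({u}, {v}) has invalid endpoints")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def edge_set(self) -> frozenset[tuple[int, int]]:
        return frozenset(self.true_edges)

    # -- JSON round trip for fixture reuse ---------------------------
    def to_json(self, path: str | Path) -> None:
        data = {
            "nodes": [
                {
                    "node_id": n.node_id,
                    "label": n.label,
                    "hemisphere": n.hemisphere.value,
                    "position": list(n.position),
                }
                for n in self.nodes
            ],
            "true_edges": {
                f"{u}-{v}": asdict(p) for (u, v), p in sorted(self.true_edges.items())
            },
        }
        Path(path).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruthModel":
        data = json.loads(Path(path).read_text())
        nodes = [
            NodeRecord(
                node_id=int(n["node_id"]),
                label=n["label"],
                hemisphere=Hemisphere.coerce(n.get("hemisphere")),
                position=tuple(n.get("position", (0.0, 0.0, 0.0))),
            )
            for n in data["nodes"]
        ]
        edges = {}
        for key, p in data["true_edges"].items():
            u, v = (int(x) for x in key.split("-"))
            edges[canonical_pair(u, v)] = EdgeParams(**p)
        return cls(nodes=nodes, true_edges=edges)


@dataclass(frozen=True)
class SimulationConfig:
    """One batch of repeated runs: seed, run count, model, noise switches."""

    seed: int
    n_runs: int
    model: GroundTruthModel
    noiseless: bool = False
    false_positive_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ConfigError(f"n_runs must be >= 1, got {self.n_runs}")
        if not (0.0 <= self.false_positive_rate < 1.0):
            raise ConfigError("false_positive_rate must be in [0, 1)")


def make_ground_truth(
    n_nodes: int,
    edge_density: float,
    parameter_ranges: Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
) -> GroundTruthModel:
    """Draw a random ground-truth model.

    ``floor(edge_density * C(n_nodes, 2))`` node pairs become true edges;
    each edge's parameters are drawn uniformly from the stated ranges
    (``count_rate`` log-uniformly, matching the orders-of-magnitude
    spread of real per-edge fiber counts).  Reproducible from ``seed``.
    """
    if n_nodes < 2:
        raise ConfigError(f"need at least 2 nodes, got {n_nodes}")
    if not (0.0 < edge_density <= 1.0):
        raise ConfigError(f"edge_density must be in (0, 1], got {edge_density}")
    ranges = dict(DEFAULT_PARAMETER_RANGES)
    if parameter_ranges:
        unknown = set(parameter_ranges) - set(ranges)
        if unknown:
            raise ConfigError(f"unknown parameter ranges: {sorted(unknown)}")
        ranges.update({k: (float(a), float(b)) for k, (a, b) in parameter_ranges.items()})

    rng = np.random.default_rng(seed)
    nodes = []
    for i in range(1, n_nodes + 1):
        hemi = Hemisphere.LEFT if i <= n_nodes // 2 else Hemisphere.RIGHT
        nodes.append(
            NodeRecord(
                node_id=i,
                label=f"roi_{i:04d}",
                hemisphere=hemi,
                position=tuple(rng.uniform(0.0, 100.0, size=3)),
            )
        )
    pairs = [(u, v) for u in range(1, n_nodes + 1) for v in range(u + 1, n_nodes + 1)]
    n_edges = int(edge_density * len(pairs))
    if n_edges < 1:
        raise ConfigError(
            f"edge_density {edge_density} on {n_nodes} nodes yields 0 true edges"
        )
    chosen = rng.choice(len(pairs), size=n_edges, replace=False)

    def u(lo: float, hi: float) -> float:
        return float(rng.uniform(lo, hi))

    edges: dict[tuple[int, int], EdgeParams] = {}
    for idx in sorted(chosen):
        lo, hi = ranges["count_rate"]
        edges[pairs[idx]] = EdgeParams(
            detection_probability=u(*ranges["detection_probability"]),
            count_rate=float(math.exp(rng.uniform(math.log(lo), math.log(hi)))),
            length_mean=u(*ranges["length_mean"]),
            length_sd=u(*ranges["length_sd"]),
            fa_mean=u(*ranges["fa_mean"]),
            fa_concentration=u(*ranges["fa_concentration"]),
        )
    return GroundTruthModel(nodes=nodes, true_edges=edges)


def _zero_truncated_poisson(rng: np.random.Generator, lam: float) -> int:
    # rejection of zero draws; expected iterations 1/(1 - e^-lam)
    x = int(rng.poisson(lam))
    while x == 0:
        x = int(rng.poisson(lam))
    return x


def _positive_truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    if sd == 0.0:
        return mean
    x = float(rng.normal(mean, sd))
    while x <= 0.0:
        x = float(rng.normal(mean, sd))
    return x


def simulate_run(
    model: GroundTruthModel,
    run_seed,
    noiseless: bool = False,
    false_positive_rate: float = 0.0,
) -> BrainGraph:
    """Simulate one tractography run as a per-run braingraph.

    Each true edge is included independently with its detection
    probability; included edges get noisy fiber count, length and FA.
    With ``noiseless=True`` every quantity collapses to its central
    value (count ``max(1, round(lambda))``, length mean, FA mean) and
    detection stays Bernoulli(p) — with p = 1 the run equals the ground
    truth exactly.
    """
    rng = np.random.default_rng(run_seed)
    g = BrainGraph(
        nodes={n.node_id: n for n in model.nodes},
        resolution_label="",
        provenance={"stage": "run", "seed": str(run_seed)},
    )
    for key, p in sorted(model.true_edges.items()):
        if p.detection_probability < 1.0 and rng.random() >= p.detection_probability:
            continue
        if noiseless:
            count: float = float(max(1, round(p.count_rate)))
            length = p.length_mean
            fa = p.fa_mean
        else:
            count = float(_zero_truncated_poisson(rng, p.count_rate))
            length = _positive_truncated_normal(rng, p.length_mean, p.length_sd)
            a = p.fa_mean * p.fa_concentration
            b = (1.0 - p.fa_mean) * p.fa_concentration
            fa = float(rng.beta(a, b))
        g.add_edge(EdgeRecord(u=key[0], v=key[1], fiber_count=count, mean_length=length, mean_fa=fa))
    if false_positive_rate > 0.0:
        truth = model.edge_set()
        ids = sorted(n.node_id for n in model.nodes)
        for i, u in enumerate(ids):
            for v in ids[i + 1 :]:
                if (u, v) in truth:
                    continue
                if rng.random() < false_positive_rate:
                    g.add_edge(
                        EdgeRecord(u=u, v=v, fiber_count=1.0, mean_length=50.0, mean_fa=0.3)
                    )
    return g


def simulate_runs(config: SimulationConfig) -> list[BrainGraph]:
    """Simulate ``n_runs`` independent runs; run i is reproducible from
    the seed pair (config.seed, i)."""
    return [
        simulate_run(
            config.model,
            run_seed=[config.seed, i],
            noiseless=config.noiseless,
            false_positive_rate=config.false_positive_rate,
        )
        for i in range(config.n_runs)
    ]


def run_source_from_model(
    model: GroundTruthModel, noiseless: bool = False, false_positive_rate: float = 0.0
):
    """Adapt a ground-truth model to the k-sweep's run-source interface:
    ``source(n, seed)`` yields n fresh independent runs."""

    def source(n: int, seed: int) -> list[BrainGraph]:
        return simulate_runs(
            SimulationConfig(
                seed=int(seed),
                n_runs=int(n),
                model=model,
                noiseless=noiseless,
                false_positive_rate=false_positive_rate,
            )
        )

    return source


def make_hierarchy(
    finest_labels: Sequence[str],
    coarser_sizes: Sequence[int],
    seed: int = 0,
    level_names: Sequence[str] | None = None,
) -> ParcellationHierarchy:
    """Build a random nested hierarchy over the given finest labels.

    ``coarser_sizes`` lists the label counts of the successively coarser
    levels (strictly decreasing, each < number of finest labels).  Labels
    of the current level are shuffled and chunked into the next level's
    groups, so every coarse label is used.
    """
    finest = [str(x) for x in finest_labels]
    sizes = [len(finest)] + [int(s) for s in coarser_sizes]
    if any(b >= a for a, b in zip(sizes, sizes[1:])) or any(s < 1 for s in sizes):
        raise ConfigError(f"level sizes must be positive and strictly decreasing, got {sizes}")
    names = list(level_names) if level_names else [f"scale{len(sizes) - i}" for i in range(len(sizes))]
    if len(names) != len(sizes):
        raise ConfigError("level_names length must match number of levels")
    rng = np.random.default_rng(seed)
    maps: dict[tuple[str, str], dict[str, str]] = {}
    current = list(finest)
    for li in range(1, len(sizes)):
        n_groups = sizes[li]
        perm = list(rng.permutation(len(current)))
        groups = np.array_split(perm, n_groups)
        m: dict[str, str] = {}
        coarse_labels = []
        for gi, grp in enumerate(groups, start=1):
            lab = f"{names[li]}_r{gi:03d}"
            coarse_labels.append(lab)
            for idx in grp:
                m[current[idx]] = lab
        maps[(names[li - 1], names[li])] = m
        current = coarse_labels
    return ParcellationHierarchy(levels=names, maps=maps)
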