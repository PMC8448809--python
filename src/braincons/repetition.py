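"""Repetition-count analysis: how many tractography runs are enough?

Averaging k probabilistic-tractography runs shrinks the run-to-run
variability of each edge's fiber count (the deviation of a run's count
from its expectation has mean zero, so averages converge).  To pick k,
build n (default 10) independent k-run-averaged replicate graphs per
candidate k, restrict to edges present in all replicates, and compute
the per-edge coefficient of variation (relative standard deviation)

    c_v(w) = sigma(w) / mu(w),

where mu is the arithmetic mean of the n replicate weights and sigma the
sample standard deviation with the n-1 denominator.  Summaries (median,
quartiles, min, max of c_v over edges) as a function of k show the
decay — approximately c_v(1)/sqrt(k) for i.i.d. run noise — and a
simple elbow rule recommends the smallest k past which the median stops
improving meaningfully.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError, InputError
from .model import BrainGraph, EdgeRecord

__all__ = [
    "KSweepConfig",
    "KSweepResult",
    "RunSource",
    "replicate_mean",
    "replicate_sd",
    "relative_sd",
    "build_averaged_replicate",
    "k_sweep",
    "recommend_k",
    "expected_deviation_check",
]

#: Callable producing ``n`` fresh independent per-run graphs from a seed.
RunSource = Callable[[int, int], list[BrainGraph]]


# ---------------------------------------------------------------------------
# scalar statistics
# ---------------------------------------------------------------------------

def replicate_mean(values: Sequence[float]) -> float:
    """Arithmetic mean of replicate weights."""
    if len(values) < 1:
        raise InputError("mean of an empty vector is undefined")
    return float(np.mean(values))


def replicate_sd(values: Sequence[float]) -> float:
    """Sample standard deviation with the n-1 (Bessel) denominator."""
    if len(values) < 2:
        raise InputError("sample sd needs at least 2 values")
    return float(np.std(values, ddof=1))


def relative_sd(values: Sequence[float]) -> float:
    """Coefficient of variation: sample sd divided by mean.

    Undefined (raises) at zero mean; consensus fiber means are >= some
    positive value, so a zero mean signals bad input.
    """
    mu = replicate_mean(values)
    if mu == 0.0:
        raise InputError("coefficient of variation undefined for zero mean")
    return replicate_sd(values) / mu


def expected_deviation_check(values: Sequence[float]) -> float:
    """Mean deviation from the sample mean, computed with compensated
    summation.  Algebraically zero; the return value exposes the
    numerical residual (|result| <= 1e-9 * max(1, |mean|) by contract).
    """
    vals = [float(v) for v in values]
    if not vals:
        raise InputError("empty vector")
    mu = math.fsum(vals) / len(vals)
    return math.fsum(v - mu for v in vals) / len(vals)


# ---------------------------------------------------------------------------
# sweep configuration and result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KSweepConfig:
    """Sweep design: candidate repetition counts, replicate ensemble size,
    master seed, and the presence semantics of a k-run-averaged graph.

    ``presence_rule='union'``: an edge belongs to an averaged graph when
    it appears in at least one of the k runs and its weight is the mean
    over all k runs with absences counted as zero.  ``'all'``: the edge
    must appear in every run and the mean is over those k observations.
    """

    k_values: tuple[int, ...] = tuple(range(1, 51))
    n_replicates: int = 10
    seed: int = 0
    presence_rule: Literal["union", "all"] = "union"

    def __post_init__(self) -> None:
        if not self.k_values or any(k < 1 for k in self.k_values):
            raise ConfigError("k_values must be non-empty with every k >= 1")
        if self.n_replicates < 2:
            raise ConfigError("need at least 2 replicates per k")
        object.__setattr__(self, "k_values", tuple(int(k) for k in self.k_values))


def _median_of_halves(sorted_vals: np.ndarray) -> tuple[float, float]:
    """Quartiles as medians of the lower/upper half (middle value
    excluded when n is odd)."""
    n = len(sorted_vals)
    half = n // 2
    lower = sorted_vals[:half]
    upper = sorted_vals[n - half :]
    if half == 0:
        return float(sorted_vals[0]), float(sorted_vals[-1])
    return float(np.median(lower)), float(np.median(upper))


@dataclass
class KSweepResult:
    """Per-edge replicate weights and c_v for every k, plus summaries."""

    config: KSweepConfig
    #: k -> edge -> replicate mean weights (length n_replicates)
    weights: dict[int, dict[tuple[int, int], np.ndarray]] = field(default_factory=dict)
    #: k -> edge -> coefficient of variation
    cv: dict[int, dict[tuple[int, int], float]] = field(default_factory=dict)

    def k_values(self) -> list[int]:
        return sorted(self.cv)

    def median_cv(self, k: int) -> float:
        return float(np.median(list(self.cv[k].values())))

    def edge_curve(self, edge: tuple[int, int]) -> pd.Series:
        """c_v of one edge as a function of k (the per-edge decay curve)."""
        ks = self.k_values()
        return pd.Series([self.cv[k][edge] for k in ks], index=ks, name=f"cv{edge}")

    def summary(self) -> pd.DataFrame:
        """Box-plot summary per k: median, quartiles, min, max of c_v."""
        rows = []
        for k in self.k_values():
            vals = np.sort(np.fromiter(self.cv[k].values(), dtype=float))
            q1, q3 = _median_of_halves(vals)
            rows.append(
                {
                    "k": k,
                    "n_edges": len(vals),
                    "median": float(np.median(vals)),
                    "q1": q1,
                    "q3": q3,
                    "min": float(vals[0]),
                    "max": float(vals[-1]),
                }
            )
        return pd.DataFrame(rows)

    def per_edge_frame(self) -> pd.DataFrame:
        rows = [
            {"k": k, "edge_u": u, "edge_v": v, "cv": c}
            for k in self.k_values()
            for (u, v), c in sorted(self.cv[k].items())
        ]
        return pd.DataFrame(rows, columns=["k", "edge_u", "edge_v", "cv"])


# ---------------------------------------------------------------------------
# averaged replicates and the sweep
# ---------------------------------------------------------------------------

def build_averaged_replicate(
    runs: Sequence[BrainGraph], presence_rule: Literal["union", "all"] = "union"
) -> BrainGraph:
    """Average k per-run graphs into one replicate graph G_k_i.

    Per-edge fiber weight is the mean fiber count over the k runs (see
    :class:`KSweepConfig` for the two presence semantics).  No trimming
    happens at this stage.  Length and FA are carried as plain means over
    the runs where the edge appeared; the sweep statistics use only the
    fiber weight.
    """
    if len(runs) < 1:
        raise InputError("need at least one run")
    k = len(runs)
    if k == 1:
        g = runs[0]
        out = BrainGraph(
            nodes=dict(g.nodes),
            edges=dict(g.edges),
            resolution_label=g.resolution_label,
            provenance={"stage": "averaged_replicate", "k": 1},
        )
        return out
    table: dict[tuple[int, int], list[tuple[float, float, float]]] = {}
    for run in runs:
        if not runs[0].same_nodes_as(run):
            raise InputError("runs with different node sets cannot be averaged")
        for key, e in run.edges.items():
            table.setdefault(key, []).append((e.fiber_count, e.mean_length, e.mean_fa))
    out = BrainGraph(
        nodes=dict(runs[0].nodes),
        resolution_label=runs[0].resolution_label,
        provenance={"stage": "averaged_replicate", "k": k, "presence_rule": presence_rule},
    )
    for key, obs in sorted(table.items()):
        if presence_rule == "all" and len(obs) < k:
            continue
        denom = k if presence_rule == "union" else len(obs)
        fiber = sum(o[0] for o in obs) / denom
        length = sum(o[1] for o in obs) / len(obs)
        fa = sum(o[2] for o in obs) / len(obs)
        out.add_edge(EdgeRecord(u=key[0], v=key[1], fiber_count=fiber, mean_length=length, mean_fa=fa))
    return out


def _replicate_seed(master: int, k: int, i: int) -> int:
    """Deterministic per-(k, replicate) substream seed below 2**31."""
    ss = np.random.SeedSequence(entropy=int(master), spawn_key=(int(k), int(i)))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def k_sweep(run_source: RunSource, config: KSweepConfig) -> KSweepResult:
    """Run the repetition sweep.

    For each k in ``config.k_values``, draw ``n_replicates`` independent
    ensembles of k fresh runs from ``run_source``, average each ensemble
    into a replicate graph, drop edges not present in all replicates, and
    compute the per-edge coefficient of variation of the replicate
    weights.  Fully reproducible from ``config.seed``.
    """
    result = KSweepResult(config=config)
    for k in config.k_values:
        replicates = [
            build_averaged_replicate(
                run_source(k, _replicate_seed(config.seed, k, i)), config.presence_rule
            )
            for i in range(config.n_replicates)
        ]
        common = frozenset.intersection(*(g.edge_set() for g in replicates))
        weights: dict[tuple[int, int], np.ndarray] = {}
        cvs: dict[tuple[int, int], float] = {}
        for edge in sorted(common):
            w = np.array([g.edges[edge].fiber_count for g in replicates], dtype=float)
            weights[edge] = w
            cvs[edge] = relative_sd(w)
        result.weights[k] = weights
        result.cv[k] = cvs
    return result


def plot_summary(summary: pd.DataFrame, path) -> None:
    """Box-style summary plot: per k, the median c_v (horizontal line),
    the inter-quartile box, and whiskers spanning the full range."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4.5))
    ks = summary["k"].to_numpy()
    width = 0.6 * (np.min(np.diff(ks)) if len(ks) > 1 else 1.0)
    for _, row in summary.iterrows():
        k = row["k"]
        ax.add_patch(
            plt.Rectangle(
                (k - width / 2, row["q1"]),
                width,
                max(row["q3"] - row["q1"], 1e-12),
                fill=False,
                edgecolor="black",
                linewidth=0.8,
            )
        )
        ax.hlines(row["median"], k - width / 2, k + width / 2, color="red", linewidth=1.5)
        ax.vlines(k, row["min"], row["q1"], color="black", linewidth=0.8)
        ax.vlines(k, row["q3"], row["max"], color="black", linewidth=0.8)
    ax.set_xlabel("repetitions k")
    ax.set_ylabel("relative standard deviation of edge weight")
    ax.set_xlim(ks.min() - 1, ks.max() + 1)
    ax.set_ylim(bottom=0)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def recommend_k(result: KSweepResult, rel_improvement_tol: float = 0.05) -> int:
    """Smallest k past which the median c_v stops improving meaningfully.

    Scans consecutive sampled k values and returns the first k whose
    relative median-c_v decrease to the next k falls below the tolerance
    (a trade-off between deviation and computation cost: each extra run
    is another full tractography).  If the median sequence is not
    monotone non-increasing — Monte-Carlo noise — a centered 3-point
    moving average is applied before scanning.  Returns the largest
    sampled k with a warning if the tolerance is never met.
    """
    ks = result.k_values()
    if len(ks) < 2:
        raise InputError("recommend_k needs at least 2 sampled k values")
    medians = np.array([result.median_cv(k) for k in ks], dtype=float)
    if np.any(np.diff(medians) > 0):
        smoothed = medians.copy()
        smoothed[1:-1] = (medians[:-2] + medians[1:-1] + medians[2:]) / 3.0
        medians = smoothed
    for j in range(len(ks) - 1):
        prev = medians[j]
        drop = (prev - medians[j + 1]) / prev if prev > 0 else 0.0
        if drop < rel_improvement_tol:
            return ks[j]
    warnings.warn(
        "median c_v kept improving beyond the sampled k grid; returning the largest k",
        stacklevel=2,
    )
    return ks[-1]
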