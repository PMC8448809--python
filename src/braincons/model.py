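"""Core data model: labeled brain graphs and parcellation hierarchies.

A *braingraph* is an undirected graph whose vertices are anatomically
labeled gray-matter regions (with scanner-space coordinates) and whose
edges carry three weights derived from tractography streamlines: the
fiber count, the mean streamline length in mm, and the mean fractional
anisotropy (FA, a diffusion measure in [0, 1]).

A *parcellation hierarchy* records how finest-level region labels nest
into coarser levels (e.g. the Lausanne2008 scheme's 1015 -> 463 -> 234
-> 129 -> 86 region levels); it drives vertex contraction in
:mod:`braincons.multiresolution`.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .exceptions import HierarchyError, MappingError, ValidationError

__all__ = [
    "Hemisphere",
    "NodeRecord",
    "EdgeRecord",
    "BrainGraph",
    "ParcellationHierarchy",
    "canonical_pair",
]


class Hemisphere(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"
    NONE = "none"

    @classmethod
    def coerce(cls, value: "str | Hemisphere | None") -> "Hemisphere":
        if value is None:
            return cls.NONE
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            raise ValidationError(
                f"hemisphere must be one of {[m.value for m in cls]}, got {value!r}"
            ) from None


def canonical_pair(u: int, v: int) -> tuple[int, int]:
    """Canonical unordered node pair: smaller id first."""
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class NodeRecord:
    """One parcellation region: 1-based integer id, anatomical label,
    hemisphere, and a scanner-space coordinate triple."""

    node_id: int
    label: str
    hemisphere: Hemisphere = Hemisphere.NONE
    position: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not isinstance(self.node_id, int) or self.node_id < 1:
            raise ValidationError(f"node_id must be a positive integer, got {self.node_id!r}")
        if not self.label:
            raise ValidationError(f"node {self.node_id}: anatomical label must be non-empty")
        object.__setattr__(self, "hemisphere", Hemisphere.coerce(self.hemisphere))
        pos = tuple(float(c) for c in self.position)
        if len(pos) != 3 or any(not math.isfinite(c) for c in pos):
            raise ValidationError(f"node {self.node_id}: position must be a finite (x, y, z) triple")
        object.__setattr__(self, "position", pos)


@dataclass(frozen=True)
class EdgeRecord:
    """One undirected edge with the three tractography-derived weights.

    ``fiber_count`` is an integer in a single-run graph but typically a
    non-integer after trimmed averaging, so it is stored as a float.
    """

    u: int
    v: int
    fiber_count: float
    mean_length: float
    mean_fa: float

    def __post_init__(self) -> None:
        if self.u == self.v:
            raise ValidationError(f"self-loop on node {self.u} is not allowed")
        a, b = canonical_pair(int(self.u), int(self.v))
        object.__setattr__(self, "u", a)
        object.__setattr__(self, "v", b)
        object.__setattr__(self, "fiber_count", float(self.fiber_count))
        object.__setattr__(self, "mean_length", float(self.mean_length))
        object.__setattr__(self, "mean_fa", float(self.mean_fa))
        if not math.isfinite(self.fiber_count) or self.fiber_count <= 0:
            raise ValidationError(
                f"edge ({a},{b}): fiber_count must be positive and finite, got {self.fiber_count}"
            )
        if not math.isfinite(self.mean_length) or self.mean_length <= 0:
            raise ValidationError(
                f"edge ({a},{b}): mean_length must be positive (mm), got {self.mean_length}"
            )
        if not (0.0 <= self.mean_fa <= 1.0):
            raise ValidationError(
                f"edge ({a},{b}): mean FA must lie in [0, 1], got {self.mean_fa}"
            )

    @property
    def endpoints(self) -> tuple[int, int]:
        return (self.u, self.v)


@dataclass
class BrainGraph:
    """An undirected, weighted, anatomically labeled brain graph.

    ``nodes`` maps node id -> :class:`NodeRecord`; ``edges`` maps the
    canonical unordered pair -> :class:`EdgeRecord`.  ``provenance`` is
    free-form metadata (subject id, pipeline stage, repetition count).
    """

    nodes: dict[int, NodeRecord] = field(default_factory=dict)
    edges: dict[tuple[int, int], EdgeRecord] = field(default_factory=dict)
    resolution_label: str = ""
    provenance: dict = field(default_factory=dict)

    # -- construction -------------------------------------------------
    def add_node(self, node: NodeRecord) -> None:
        if node.node_id in self.nodes:
            raise ValidationError(f"duplicate node id {node.node_id}")
        self.nodes[node.node_id] = node

    def add_edge(self, edge: EdgeRecord) -> None:
        key = edge.endpoints
        if key in self.edges:
            raise ValidationError(f"duplicate edge {key}")
        for n in key:
            if n not in self.nodes:
                raise ValidationError(f"edge {key} references unknown node {n}")
        self.edges[key] = edge

    # -- queries ------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_set(self) -> frozenset[tuple[int, int]]:
        return frozenset(self.edges)

    def total_fiber_mass(self) -> float:
        return float(sum(e.fiber_count for e in self.edges.values()))

    def validate(self, per_run: bool = False) -> None:
        """Re-check all structural invariants; ``per_run`` additionally
        requires integer fiber counts >= 1 (an edge exists in a single
        run only if at least one streamline was found)."""
        for key, edge in self.edges.items():
            if key != edge.endpoints:
                raise ValidationError(f"edge stored under non-canonical key {key}")
            for n in key:
                if n not in self.nodes:
                    raise ValidationError(f"edge {key} references unknown node {n}")
            if per_run:
                if edge.fiber_count < 1 or edge.fiber_count != int(edge.fiber_count):
                    raise ValidationError(
                        f"per-run edge {key}: fiber count must be an integer >= 1, "
                        f"got {edge.fiber_count}"
                    )

    def same_nodes_as(self, other: "BrainGraph") -> bool:
        return self.nodes == other.nodes

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BrainGraph):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and self.edges == other.edges
            and self.resolution_label == other.resolution_label
        )


@dataclass
class ParcellationHierarchy:
    """Nested parcellation levels, finest first.

    ``maps`` holds one total function per consecutive level pair
    (source label -> coarser label); arbitrary-level lookups compose
    these maps.  Level label-set sizes must be strictly decreasing.
    """

    levels: list[str]
    maps: dict[tuple[str, str], dict[str, str]]

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise HierarchyError("a hierarchy needs at least two levels")
        if len(set(self.levels)) != len(self.levels):
            raise HierarchyError("level names must be unique")
        sizes = self.level_sizes()
        for (a, sa), (b, sb) in zip(sizes.items(), list(sizes.items())[1:]):
            if sb >= sa:
                raise HierarchyError(
                    f"level sizes must strictly decrease: {a} has {sa} labels "
                    f"but coarser {b} has {sb}"
                )
        # totality: each consecutive map must cover exactly the source label set
        for src, dst in zip(self.levels, self.levels[1:]):
            m = self.maps.get((src, dst))
            if m is None:
                raise HierarchyError(f"missing map for consecutive levels {src} -> {dst}")
            if any(v is None or v == "" for v in m.values()):
                raise HierarchyError(f"map {src} -> {dst} has an empty coarse assignment")

    def level_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for src, dst in zip(self.levels, self.levels[1:]):
            m = self.maps[(src, dst)]
            sizes.setdefault(src, len(m))
            sizes[dst] = len(set(m.values()))
        return sizes

    def labels(self, level: str) -> frozenset[str]:
        self._check_level(level)
        i = self.levels.index(level)
        if i == 0:
            return frozenset(self.maps[(self.levels[0], self.levels[1])])
        return frozenset(self.maps[(self.levels[i - 1], level)].values())

    def _check_level(self, level: str) -> None:
        if level not in self.levels:
            raise MappingError(f"unknown level {level!r}; levels are {self.levels}")

    def map_label(self, label: str, source_level: str, target_level: str) -> str:
        """Map ``label`` at ``source_level`` to its ``target_level``
        ancestor by composing the consecutive-level maps."""
        self._check_level(source_level)
        self._check_level(target_level)
        i, j = self.levels.index(source_level), self.levels.index(target_level)
        if j < i:
            raise MappingError(
                f"cannot map from {source_level} to finer level {target_level}"
            )
        current = label
        for a, b in zip(self.levels[i:j], self.levels[i + 1 : j + 1]):
            m = self.maps[(a, b)]
            if current not in m:
                raise MappingError(f"label {current!r} not found at level {a}")
            current = m[current]
        return current

    def full_map(self, source_level: str, target_level: str) -> dict[str, str]:
        """The composed source -> target label map for any level pair."""
        self._check_level(source_level)
        if source_level == target_level:
            return {lab: lab for lab in self.labels(source_level)}
        return {
            lab: self.map_label(lab, source_level, target_level)
            for lab in self.labels(source_level)
        }

    @classmethod
    def from_table(
        cls, columns: Mapping[str, Iterable[str]], levels: Iterable[str]
    ) -> "ParcellationHierarchy":
        """Build from per-level label columns (one row per finest label).

        Raises :class:`HierarchyError` on duplicate finest labels, missing
        assignments, ill-defined consecutive maps, or non-decreasing sizes.
        """
        levels = list(levels)
        cols = {lvl: [str(x) for x in columns[lvl]] for lvl in levels}
        n = len(cols[levels[0]])
        finest = cols[levels[0]]
        if len(set(finest)) != n:
            dupes = sorted({x for x in finest if finest.count(x) > 1})
            raise HierarchyError(f"duplicate finest-level labels: {dupes}")
        for lvl in levels:
            if len(cols[lvl]) != n:
                raise HierarchyError(f"column {lvl!r} has {len(cols[lvl])} rows, expected {n}")
            for row, val in enumerate(cols[lvl]):
                if val in ("", "nan", "None"):
                    raise HierarchyError(
                        f"finest label {finest[row]!r} has no assignment at level {lvl!r}"
                    )
        maps: dict[tuple[str, str], dict[str, str]] = {}
        for src, dst in zip(levels, levels[1:]):
            m: dict[str, str] = {}
            for s, d in zip(cols[src], cols[dst]):
                if s in m and m[s] != d:
                    raise HierarchyError(
                        f"label {s!r} at level {src!r} maps to both {m[s]!r} and {d!r} "
                        f"at level {dst!r}"
                    )
                m[s] = d
            maps[(src, dst)] = m
        return cls(levels=levels, maps=maps)
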