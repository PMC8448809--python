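"""Multi-resolution coarsening of braingraphs by vertex contraction.

Consensus graphs are built at the finest parcellation level only; the
coarser resolutions are derived from it by contracting all vertices that
share a coarse-level label, summing the fiber counts of the merged
parallel edges.  Mean length and mean FA of a coarse edge are the
fiber-count-weighted means of the merged fine edges (each fine mean
represents that many streamlines).  Fine edges that fall inside a single
coarse region become self-loops and are dropped, with their fiber mass
reported so conservation stays auditable:

    mass_after + self_loop_mass_dropped == mass_before.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import MappingError
from .model import (
    BrainGraph,
    EdgeRecord,
    Hemisphere,
    NodeRecord,
    ParcellationHierarchy,
    canonical_pair,
)

__all__ = ["ContractionReport", "contract_graph", "contract_all_levels"]


@dataclass(frozen=True)
class ContractionReport:
    """Bookkeeping of one contraction step (fiber-mass conservation)."""

    source_level: str
    target_level: str
    n_nodes_before: int
    n_nodes_after: int
    n_edges_before: int
    n_edges_after: int
    fiber_mass_before: float
    fiber_mass_after: float
    self_loop_mass_dropped: float

    def mass_conservation_error(self) -> float:
        """Relative conservation defect; 0 for exact bookkeeping."""
        total = self.fiber_mass_after + self.self_loop_mass_dropped
        denom = max(abs(self.fiber_mass_before), 1.0)
        return abs(total - self.fiber_mass_before) / denom

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _graph_level(graph: BrainGraph, hierarchy: ParcellationHierarchy) -> str:
    if graph.resolution_label in hierarchy.levels:
        return graph.resolution_label
    return hierarchy.levels[0]


def contract_graph(
    graph: BrainGraph,
    hierarchy: ParcellationHierarchy,
    target_level: str,
    source_level: str | None = None,
) -> tuple[BrainGraph, ContractionReport]:
    """Contract a graph to ``target_level`` of the parcellation hierarchy.

    The source level is the graph's ``resolution_label`` when that names
    a hierarchy level, else the finest level.  Contracting to the source
    level itself is a no-op with an identity report.  Every node label of
    the graph must exist at the source level (:class:`MappingError`
    otherwise).
    """
    src = source_level or _graph_level(graph, hierarchy)
    hierarchy._check_level(src)
    hierarchy._check_level(target_level)

    label_map = {}
    for node in graph.nodes.values():
        label_map[node.node_id] = hierarchy.map_label(node.label, src, target_level)

    if target_level == src:
        report = ContractionReport(
            source_level=src,
            target_level=target_level,
            n_nodes_before=graph.n_nodes,
            n_nodes_after=graph.n_nodes,
            n_edges_before=graph.n_edges,
            n_edges_after=graph.n_edges,
            fiber_mass_before=graph.total_fiber_mass(),
            fiber_mass_after=graph.total_fiber_mass(),
            self_loop_mass_dropped=0.0,
        )
        return graph, report

    # coarse node ids: 1-based, in sorted order of coarse labels present
    coarse_labels = sorted(set(label_map.values()))
    coarse_id = {lab: i for i, lab in enumerate(coarse_labels, start=1)}

    # coarse node records: unweighted centroid position; hemisphere kept
    # only if all constituent fine nodes agree
    members: dict[str, list[NodeRecord]] = {lab: [] for lab in coarse_labels}
    for node in graph.nodes.values():
        members[label_map[node.node_id]].append(node)

    out = BrainGraph(
        resolution_label=target_level,
        provenance={
            **graph.provenance,
            "stage": "contracted",
            "contracted_from": src,
        },
    )
    for lab in coarse_labels:
        group = members[lab]
        cx = sum(n.position[0] for n in group) / len(group)
        cy = sum(n.position[1] for n in group) / len(group)
        cz = sum(n.position[2] for n in group) / len(group)
        hemis = {n.hemisphere for n in group}
        out.add_node(
            NodeRecord(
                node_id=coarse_id[lab],
                label=lab,
                hemisphere=hemis.pop() if len(hemis) == 1 else Hemisphere.NONE,
                position=(cx, cy, cz),
            )
        )

    # accumulate fine edges into coarse pairs; weighted sums for means
    fiber_sum: dict[tuple[int, int], float] = {}
    length_wsum: dict[tuple[int, int], float] = {}
    fa_wsum: dict[tuple[int, int], float] = {}
    self_loop_mass = 0.0
    for edge in graph.edges.values():
        cu = coarse_id[label_map[edge.u]]
        cv = coarse_id[label_map[edge.v]]
        if cu == cv:
            self_loop_mass += edge.fiber_count
            continue
        key = canonical_pair(cu, cv)
        fiber_sum[key] = fiber_sum.get(key, 0.0) + edge.fiber_count
        length_wsum[key] = length_wsum.get(key, 0.0) + edge.fiber_count * edge.mean_length
        fa_wsum[key] = fa_wsum.get(key, 0.0) + edge.fiber_count * edge.mean_fa

    for (cu, cv), mass in sorted(fiber_sum.items()):
        out.add_edge(
            EdgeRecord(
                u=cu,
                v=cv,
                fiber_count=mass,
                mean_length=length_wsum[(cu, cv)] / mass,
                mean_fa=min(1.0, fa_wsum[(cu, cv)] / mass),
            )
        )

    report = ContractionReport(
        source_level=src,
        target_level=target_level,
        n_nodes_before=graph.n_nodes,
        n_nodes_after=out.n_nodes,
        n_edges_before=graph.n_edges,
        n_edges_after=out.n_edges,
        fiber_mass_before=graph.total_fiber_mass(),
        fiber_mass_after=out.total_fiber_mass(),
        self_loop_mass_dropped=self_loop_mass,
    )
    return out, report


def contract_all_levels(
    graph: BrainGraph, hierarchy: ParcellationHierarchy
) -> dict[str, tuple[BrainGraph, ContractionReport]]:
    """Contract the finest-level graph to every hierarchy level.

    Returns one (graph, report) per level; the finest entry is the input
    itself with an identity report.  All coarse levels are derived
    directly from the input graph.
    """
    src = _graph_level(graph, hierarchy)
    if src != hierarchy.levels[0]:
        raise MappingError(
            f"contract_all_levels expects a finest-level graph, got level {src!r}"
        )
    out: dict[str, tuple[BrainGraph, ContractionReport]] = {}
    for level in hierarchy.levels:
        out[level] = contract_graph(graph, hierarchy, level, source_level=src)
    return out
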