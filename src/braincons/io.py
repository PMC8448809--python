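"""GraphML braingraph I/O and parcellation-hierarchy table reading.

Braingraphs are exchanged in the CMTK GraphML dialect: a key-definition
section, then nodes carrying an anatomical label and x/y/z coordinates,
then undirected edges carrying the fiber count, mean streamline length
and mean FA.  The exact attribute key strings are site-specific, so they
are configurable through :class:`AttributeMap` (defaults follow the CMTK
convention).

Hierarchy tables are delimited text, one row per finest-level label, one
column per level (header row = level names, finest first).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from .exceptions import HierarchyError, SchemaError, ValidationError
from .model import BrainGraph, EdgeRecord, Hemisphere, NodeRecord, ParcellationHierarchy

__all__ = ["AttributeMap", "read_braingraph", "write_braingraph", "read_hierarchy"]

_GRAPH_META_KEYS = ("resolution_label", "provenance")


@dataclass(frozen=True)
class AttributeMap:
    """GraphML attribute key names for the braingraph dialect.

    Defaults are the CMTK key names; override any field (or load a JSON
    object with the same field names) to read files from other pipelines.
    """

    label: str = "dn_name"
    hemisphere: str = "dn_hemisphere"
    position_x: str = "dn_position_x"
    position_y: str = "dn_position_y"
    position_z: str = "dn_position_z"
    fiber_count: str = "number_of_fibers"
    mean_length: str = "fiber_length_mean"
    mean_fa: str = "FA_mean"

    @classmethod
    def from_json(cls, path: str | Path) -> "AttributeMap":
        data = json.loads(Path(path).read_text())
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise SchemaError(f"unknown attribute_map fields: {sorted(unknown)}")
        return cls(**data)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def _require(attrs: dict, key: str, what: str) -> object:
    if key not in attrs:
        raise SchemaError(f"{what}: missing attribute key {key!r}")
    return attrs[key]


def _parse_node_id(raw: object) -> int:
    s = str(raw)
    if s and s[0] in "nv" and s[1:].isdigit():  # tolerate "n12"-style ids
        s = s[1:]
    try:
        return int(s)
    except ValueError:
        raise SchemaError(f"node id {raw!r} is not an integer") from None


def read_braingraph(
    path: str | Path, attribute_map: AttributeMap | None = None
) -> BrainGraph:
    """Read a GraphML braingraph file.

    Raises :class:`SchemaError` for missing attribute keys or a directed
    graph, :class:`ValidationError` for self-loops, duplicate edges or
    out-of-range weights; malformed XML propagates as a parse error.
    """
    amap = attribute_map or AttributeMap()
    g = nx.read_graphml(str(path))
    if g.is_directed():
        raise SchemaError(f"{path}: braingraphs are undirected; directed input rejected")
    if g.is_multigraph():
        # networkx promotes to a MultiGraph only when parallel edges exist
        raise ValidationError(f"{path}: duplicate edges present in file")

    graph = BrainGraph(
        resolution_label=str(g.graph.get("resolution_label", "")),
        provenance=json.loads(g.graph["provenance"]) if "provenance" in g.graph else {},
    )
    for raw_id, attrs in g.nodes(data=True):
        nid = _parse_node_id(raw_id)
        where = f"{path}: node {raw_id}"
        node = NodeRecord(
            node_id=nid,
            label=str(_require(attrs, amap.label, where)),
            hemisphere=Hemisphere.coerce(attrs.get(amap.hemisphere)),
            position=(
                float(_require(attrs, amap.position_x, where)),
                float(_require(attrs, amap.position_y, where)),
                float(_require(attrs, amap.position_z, where)),
            ),
        )
        graph.add_node(node)
    for ru, rv, attrs in g.edges(data=True):
        u, v = _parse_node_id(ru), _parse_node_id(rv)
        where = f"{path}: edge ({ru}, {rv})"
        if u == v:
            raise ValidationError(f"{where}: self-loop not allowed")
        graph.add_edge(
            EdgeRecord(
                u=u,
                v=v,
                fiber_count=float(_require(attrs, amap.fiber_count, where)),
                mean_length=float(_require(attrs, amap.mean_length, where)),
                mean_fa=float(_require(attrs, amap.mean_fa, where)),
            )
        )
    graph.validate()
    return graph


def write_braingraph(
    graph: BrainGraph, path: str | Path, attribute_map: AttributeMap | None = None
) -> None:
    """Write a braingraph as GraphML (attribute keys first, then nodes
    with coordinates and labels, then edges with the three weights).

    Floats are serialised with full round-trip precision, so averaged
    (non-integer) fiber counts survive a write/read cycle exactly.
    """
    amap = attribute_map or AttributeMap()
    graph.validate()
    g = nx.Graph()
    g.graph["resolution_label"] = graph.resolution_label
    if graph.provenance:
        g.graph["provenance"] = json.dumps(graph.provenance, sort_keys=True)
    for node in graph.nodes.values():
        g.add_node(
            str(node.node_id),
            **{
                amap.label: node.label,
                amap.hemisphere: node.hemisphere.value,
                amap.position_x: float(node.position[0]),
                amap.position_y: float(node.position[1]),
                amap.position_z: float(node.position[2]),
            },
        )
    for edge in graph.edges.values():
        g.add_edge(
            str(edge.u),
            str(edge.v),
            **{
                amap.fiber_count: float(edge.fiber_count),
                amap.mean_length: float(edge.mean_length),
                amap.mean_fa: float(edge.mean_fa),
            },
        )
    nx.write_graphml(g, str(path))


def read_hierarchy(path: str | Path, sep: str | None = None) -> ParcellationHierarchy:
    """Read a parcellation-hierarchy table (CSV/TSV, header = level names,
    finest level in the first column, one row per finest label).

    The delimiter is sniffed unless ``sep`` is given.  Raises
    :class:`HierarchyError` on duplicate finest labels, missing coarse
    assignments, or level sizes that do not strictly decrease.
    """
    try:
        df = pd.read_csv(path, sep=sep, engine="python", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise HierarchyError(f"cannot parse hierarchy table {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise HierarchyError(f"{path}: need at least two level columns, got {df.shape[1]}")
    if df.isna().any().any():
        bad = df[df.isna().any(axis=1)].index[0]
        raise HierarchyError(f"{path}: row {bad} has a missing coarse assignment")
    return ParcellationHierarchy.from_table(
        {c: df[c].tolist() for c in df.columns}, list(df.columns)
    )


def write_hierarchy(hierarchy: ParcellationHierarchy, path: str | Path, sep: str = ",") -> None:
    """Write a hierarchy back to delimited text (finest labels sorted)."""
    finest = sorted(hierarchy.labels(hierarchy.levels[0]))
    data = {
        lvl: [hierarchy.map_label(lab, hierarchy.levels[0], lvl) for lab in finest]
        for lvl in hierarchy.levels
    }
    pd.DataFrame(data).to_csv(path, sep=sep, index=False)
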