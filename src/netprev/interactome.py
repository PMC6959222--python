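"""Multi-evidence undirected interactome.

The disease module is grown on a simple undirected graph over protein
identifiers.  Edges carry evidence-type tags (physical interaction,
regulatory, complex co-localization, metabolic coupling, signaling,
kinase-substrate) but the graph itself is simple: parallel evidence rows
collapse onto one edge with merged tags, and self-loops are dropped at
ingest.  Built on :mod:`networkx`.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

EVIDENCE_TYPES = frozenset(
    {
        "ppi",
        "regulatory",
        "complex_colocalization",
        "metabolic_coupled",
        "signaling",
        "kinase_substrate",
    }
)


@dataclass
class LoadReport:
    """Bookkeeping from an edge-list ingest."""

    rows_read: int = 0
    self_loops_dropped: int = 0
    duplicates_merged: int = 0

    def __str__(self) -> str:  # log line
        return (
            f"read {self.rows_read} rows: "
            f"{self.self_loops_dropped} self-loops dropped, "
            f"{self.duplicates_merged} duplicate rows merged"
        )


def new_interactome() -> nx.Graph:
    return nx.Graph()


def add_interaction(graph: nx.Graph, a: str, b: str, etype: str | None = None) -> bool:
    """Add one evidence row; returns False for a (dropped) self-loop.

    Tags accumulate on the edge's ``types`` set.
    """
    if a == b:
        return False
    if graph.has_edge(a, b):
        if etype:
            graph.edges[a, b]["types"].add(etype)
    else:
        graph.add_edge(a, b, types={etype} if etype else set())
    return True


def load_edge_list(path: str | Path) -> tuple[nx.Graph, LoadReport]:
    """Read a 3-column TSV edge list ``idA  idB  type``.

    Parallel rows collapse onto one tagged edge; self-loop rows are dropped
    and counted in the load report.  Malformed rows raise with their line
    number.
    """
    graph = nx.Graph()
    report = LoadReport()
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 2:
                a, b, etype = parts[0], parts[1], None
            elif len(parts) == 3:
                a, b, etype = parts
            else:
                raise ValueError(f"{path}:{lineno}: expected 2-3 columns, got {len(parts)}")
            if not a or not b:
                raise ValueError(f"{path}:{lineno}: empty identifier")
            report.rows_read += 1
            if a == b:
                report.self_loops_dropped += 1
                graph.add_node(a)
                continue
            if graph.has_edge(a, b):
                report.duplicates_merged += 1
            add_interaction(graph, a, b, etype)
    return graph, report


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for a, b, data in sorted(graph.edges(data=True)):
            types = sorted(data.get("types") or {""})
            for t in types:
                fh.write(f"{a}\t{b}\t{t}\n")


def restrict_seeds(graph: nx.Graph, seeds: Iterable[str]) -> tuple[set[str], set[str]]:
    """Partition a seed set into (present in network, absent)."""
    seeds = set(seeds)
    present = {s for s in seeds if graph.has_node(s)}
    return present, seeds - present


def largest_connected_component(graph: nx.Graph) -> nx.Graph:
    """Induced subgraph of the largest component.

    Size ties are broken toward the component containing the
    lexicographically smallest node, so the result is deterministic.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph has no components")
    comps = sorted(nx.connected_components(graph), key=lambda c: (-len(c), min(c)))
    return graph.subgraph(comps[0]).copy()


# ---------------------------------------------------------------------------
# XGMML / GraphML export


def export_xgmml(
    graph: nx.Graph,
    node_attributes: Mapping[str, Mapping[str, object]] | None,
    path: str | Path,
    label: str = "module",
) -> None:
    """Write the graph as XGMML, loadable by Cytoscape-compatible readers.

    ``node_attributes`` maps node id -> {attribute name: value}; values are
    serialized as typed XGMML ``att`` elements (integer / real / string /
    boolean).  Edge evidence tags are written as a comma-joined string.
    """
    node_attributes = node_attributes or {}
    root = ET.Element(
        "graph",
        attrib={
            "label": label,
            "directed": "1" if graph.is_directed() else "0",
            "xmlns": "http://www.cs.rpi.edu/XGMML",
        },
    )
    ids = {n: str(i) for i, n in enumerate(sorted(graph.nodes()), start=1)}
    for node in sorted(graph.nodes()):
        el = ET.SubElement(root, "node", attrib={"id": ids[node], "label": str(node)})
        for key, value in sorted((node_attributes.get(node) or {}).items()):
            el.append(_att(key, value))
    for a, b, data in sorted(graph.edges(data=True)):
        el = ET.SubElement(
            root,
            "edge",
            attrib={"source": ids[a], "target": ids[b], "label": f"{a}-{b}"},
        )
        types = data.get("types")
        if types:
            el.append(_att("types", ",".join(sorted(types))))
        for key in ("sign", "directness"):
            if key in data:
                el.append(_att(key, data[key]))
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(str(path), xml_declaration=True, encoding="unicode")


def _att(name: str, value: object) -> ET.Element:
    if isinstance(value, bool):
        typ, sval = "boolean", ("1" if value else "0")
    elif isinstance(value, int):
        typ, sval = "integer", str(value)
    elif isinstance(value, float):
        typ, sval = "real", repr(value)
    else:
        typ, sval = "string", str(value)
    return ET.Element("att", attrib={"name": name, "type": typ, "value": sval})


def _att_value(el: ET.Element) -> object:
    typ, sval = el.get("type", "string"), el.get("value", "")
    if typ == "integer":
        return int(sval)
    if typ == "real":
        return float(sval)
    if typ == "boolean":
        return sval == "1"
    return sval


def load_xgmml(path: str | Path) -> tuple[nx.Graph, dict[str, dict[str, object]]]:
    """Read back a graph written by :func:`export_xgmml`.

    Returns the graph and the node-attribute mapping; used for round-trip
    checks and for re-importing exported modules.
    """
    tree = ET.parse(str(path))
    root = tree.getroot()
    directed = root.get("directed") == "1"
    graph: nx.Graph = nx.DiGraph() if directed else nx.Graph()
    ns = ""
    if root.tag.startswith("{"):
        ns = root.tag[: root.tag.index("}") + 1]
    labels: dict[str, str] = {}
    attrs: dict[str, dict[str, object]] = {}
    for el in root.findall(f"{ns}node"):
        label = el.get("label", el.get("id", ""))
        labels[el.get("id", label)] = label
        graph.add_node(label)
        node_attrs = {a.get("name", ""): _att_value(a) for a in el.findall(f"{ns}att")}
        if node_attrs:
            attrs[label] = node_attrs
    for el in root.findall(f"{ns}edge"):
        a = labels[el.get("source", "")]
        b = labels[el.get("target", "")]
        data: dict[str, object] = {}
        for att in el.findall(f"{ns}att"):
            name, value = att.get("name", ""), _att_value(att)
            if name == "types":
                data["types"] = set(str(value).split(",")) if value else set()
            else:
                data[name] = value
        graph.add_edge(a, b, **data)
    return graph, attrs


def export_graphml(
    graph: nx.Graph,
    node_attributes: Mapping[str, Mapping[str, object]] | None,
    path: str | Path,
) -> None:
    """GraphML export under the same contract as :func:`export_xgmml`."""
    g = graph.copy()
    for node, attrs in (node_attributes or {}).items():
        if g.has_node(node):
            g.nodes[node].update(attrs)
    for _, _, data in g.edges(data=True):
        if isinstance(data.get("types"), set):
            data["types"] = ",".join(sorted(data["types"]))
    nx.write_graphml(g, str(path))
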