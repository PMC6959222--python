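"""Signed signaling-path tracing from candidate targets to disease proteins.

A candidate intervention (inhibiting or activating a target) is
mechanistically plausible when its effect, propagated along directed
activation/inhibition edges, opposes the direction in which each reached
disease protein is altered.  Paths of at most two edges (direct, or
through one intermediate) are enumerated; a path's net sign is the
product of its edge signs, the predicted effect on the endpoint is the
intervention sign times that product, and the path is consistent when
the predicted effect is the negative of the endpoint's disease
direction.  Conflicting-sign parallel paths to the same endpoint are
reported side by side, never averaged away.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

ACTIVATING = 1
INHIBITING = -1

# Mechanism-name words mapped to an intervention sign.
_INTERVENTION_WORDS = {
    "inhibitor": -1,
    "antagonist": -1,
    "blocker": -1,
    "agonist": +1,
    "activator": +1,
    "stimulator": +1,
}


def intervention_sign(mechanism: str) -> int:
    """Intervention sign from a mechanism-of-action name.

    Inhibitors/antagonists/blockers push the target down (-1);
    agonists/activators (and expression-raising interventions) push it up
    (+1).
    """
    low = mechanism.lower()
    for word, sign in _INTERVENTION_WORDS.items():
        if word in low:
            return sign
    if "expression up" in low or "up expression" in low:
        return +1
    raise ValueError(f"cannot infer intervention sign from {mechanism!r}")


def new_signed_digraph() -> nx.MultiDiGraph:
    return nx.MultiDiGraph()


def add_signed_edge(
    graph: nx.MultiDiGraph, source: str, target: str, sign: int, directness: str = "direct"
) -> None:
    if sign not in (ACTIVATING, INHIBITING):
        raise ValueError(f"sign must be +1 or -1, got {sign}")
    if directness not in ("direct", "transcriptional"):
        raise ValueError(f"unknown directness {directness!r}")
    existing = graph.get_edge_data(source, target) or {}
    if any(d.get("sign") == -sign for d in existing.values()):
        warnings.warn(f"parallel opposite-sign edges between {source} and {target}")
    graph.add_edge(source, target, sign=sign, directness=directness)


def load_signed_edges(path: str | Path) -> nx.MultiDiGraph:
    """Read a signed-edge TSV ``source  target  sign  directness``.

    Sign may be +1/-1 or the words activate(s)/inhibit(s); directness
    defaults to ``direct``.
    """
    graph = nx.MultiDiGraph()
    with Path(path).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["source", "target"]:
            raise ValueError(f"{path}: expected header starting 'source\\ttarget'")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 columns")
            source, target, sign_cell = parts[0], parts[1], parts[2].strip().lower()
            directness = parts[3].strip() if len(parts) > 3 and parts[3].strip() else "direct"
            if sign_cell in ("1", "+1", "activate", "activates", "activating"):
                sign = ACTIVATING
            elif sign_cell in ("-1", "inhibit", "inhibits", "inhibiting"):
                sign = INHIBITING
            else:
                raise ValueError(f"{path}:{lineno}: unknown sign {parts[2]!r}")
            add_signed_edge(graph, source, target, sign, directness)
    return graph


def load_alteration_map(path: str | Path) -> dict[str, int]:
    """Read a disease-alteration TSV ``protein  direction`` (+1/-1 or
    increased/decreased)."""
    out: dict[str, int] = {}
    with Path(path).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "protein":
            raise ValueError(f"{path}: expected header starting 'protein'")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            protein, cell = line.split("\t")[:2]
            cell = cell.strip().lower()
            if cell in ("1", "+1", "increased", "up"):
                out[protein] = +1
            elif cell in ("-1", "decreased", "down"):
                out[protein] = -1
            else:
                raise ValueError(f"{path}:{lineno}: unknown direction {cell!r}")
    return out


@dataclass(frozen=True)
class MechanismPath:
    """A minimal-length signed path from a target to a disease protein."""

    nodes: tuple[str, ...]
    edge_signs: tuple[int, ...]
    directness: tuple[str, ...] = ()

    @property
    def endpoint(self) -> str:
        return self.nodes[-1]

    @property
    def net_sign(self) -> int:
        sign = 1
        for s in self.edge_signs:
            sign *= s
        return sign

    def __len__(self) -> int:
        return len(self.edge_signs)


def shortest_signed_paths(
    graph: nx.MultiDiGraph,
    target: str,
    disease_proteins: Iterable[str],
    max_edges: int = 2,
) -> list[MechanismPath]:
    """All minimal-length directed paths (<= ``max_edges`` edges, no
    repeated nodes) from ``target`` to each reachable disease protein.

    Parallel edges of different sign yield distinct paths.  For each
    endpoint only the paths of the minimal reachable length are returned.
    """
    if not graph.has_node(target):
        raise KeyError(f"target {target!r} not in graph")
    disease_proteins = set(disease_proteins)
    by_endpoint: dict[str, list[MechanismPath]] = {}

    def extend(nodes: tuple[str, ...], signs: tuple[int, ...], direct: tuple[str, ...]):
        head = nodes[-1]
        if head in disease_proteins and len(signs) >= 1:
            by_endpoint.setdefault(head, []).append(
                MechanismPath(nodes=nodes, edge_signs=signs, directness=direct)
            )
        if len(signs) >= max_edges:
            return
        for _, nxt, data in graph.out_edges(head, data=True):
            if nxt in nodes:
                continue
            extend(nodes + (nxt,), signs + (data["sign"],), direct + (data.get("directness", "direct"),))

    extend((target,), (), ())
    out: list[MechanismPath] = []
    for endpoint in sorted(by_endpoint):
        paths = by_endpoint[endpoint]
        min_len = min(len(p) for p in paths)
        out.extend(sorted((p for p in paths if len(p) == min_len), key=lambda p: p.nodes))
    return out


def path_net_effect(intervention: int, path: MechanismPath) -> int:
    """Predicted effect on the endpoint: intervention sign times the
    product of edge signs."""
    if intervention not in (+1, -1):
        raise ValueError("intervention sign must be +1 or -1")
    return intervention * path.net_sign


@dataclass
class ConsistencyReport:
    """Per-path consistency of an intervention with disease alterations."""

    entries: list[tuple[MechanismPath, int, bool]]  # (path, predicted effect, consistent)
    excluded_endpoints: list[str]

    @property
    def consistent_fraction(self) -> float | None:
        if not self.entries:
            return None
        return sum(1 for _, _, ok in self.entries if ok) / len(self.entries)

    def conflicting_endpoints(self) -> list[str]:
        """Endpoints reached by minimal paths that disagree in predicted
        effect (reported, never averaged)."""
        effects: dict[str, set[int]] = {}
        for path, eff, _ in self.entries:
            effects.setdefault(path.endpoint, set()).add(eff)
        return sorted(e for e, s in effects.items() if len(s) > 1)


def consistency_report(
    paths: Sequence[MechanismPath],
    alteration_map: Mapping[str, int],
    intervention: int,
) -> ConsistencyReport:
    """Score each path: consistent iff the predicted effect is the negative
    of the endpoint's disease direction (the intervention opposes the
    disease alteration).  Paths to unannotated endpoints are excluded
    with a warning."""
    entries = []
    excluded = []
    for path in paths:
        direction = alteration_map.get(path.endpoint)
        if direction is None:
            excluded.append(path.endpoint)
            continue
        effect = path_net_effect(intervention, path)
        entries.append((path, effect, effect == -direction))
    if excluded:
        warnings.warn(
            f"{len(excluded)} path endpoint(s) lack disease annotation: "
            f"{sorted(set(excluded))}"
        )
    return ConsistencyReport(entries=entries, excluded_endpoints=sorted(set(excluded)))


def build_mechanism_subnetwork(paths: Sequence[MechanismPath]) -> nx.MultiDiGraph:
    """Union of the edges of the given paths; shared edges appear once."""
    g = nx.MultiDiGraph()
    seen: set[tuple[str, str, int, str]] = set()
    for path in paths:
        for i, sign in enumerate(path.edge_signs):
            a, b = path.nodes[i], path.nodes[i + 1]
            directness = path.directness[i] if path.directness else "direct"
            key = (a, b, sign, directness)
            if key in seen:
                continue
            seen.add(key)
            g.add_edge(a, b, sign=sign, directness=directness)
        g.add_nodes_from(path.nodes)
    return g
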