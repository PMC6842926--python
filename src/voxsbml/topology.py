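"""Domain adjacency, membrane creation, and biological consistency.

Two domains are adjacent when their voxels share a face (6-neighbourhood):
a zero-thickness membrane needs a shared face to have nonzero area, so
diagonal-only contact never produces an edge, even though domains themselves
are 26-connected.  One membrane is created per adjacent pair of volume
domains; with a strictly nested chain of *n* volume types this yields exactly
*n − 1* membranes, instead of the O(n²) candidate pairs a user would otherwise
have to consider by hand.

Membrane domain types are shared per *type* pair (two nuclei touching one
cytosol give two NM membrane domains under the single NM type).  The canonical
names ``PM`` (plasma membrane, cytosol|extracellular) and ``NM`` (nuclear
membrane, nucleus|cytosol) are applied where they fit; any other pair gets the
systematic ``"<inner>_<outer>_membrane"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .geometry_builder import (
    EC_NAME,
    Domain,
    DomainTypeSpec,
    LabeledGeometry,
    _components,
)

__all__ = [
    "AdjacencyGraph",
    "Membrane",
    "detect_adjacency",
    "create_membranes",
    "check_biology",
    "membrane_name",
    "to_dot",
]

#: Canonical membrane names for (inner type, outer type) pairs.
CANONICAL_MEMBRANES = {("Nuc", "Cyt"): "NM", ("Cyt", EC_NAME): "PM"}


def membrane_name(inner_type: str, outer_type: str) -> str:
    """Membrane domain-type name for a (deeper, shallower) volume-type pair."""
    return CANONICAL_MEMBRANES.get(
        (inner_type, outer_type), f"{inner_type}_{outer_type}_membrane"
    )


@dataclass(frozen=True)
class Membrane:
    """One zero-thickness membrane domain between two adjacent volume domains.

    Membranes have no voxels and no sampled value; they exist purely through
    their two adjacency records (membrane-inner, membrane-outer).
    """

    id: str
    domain_type: str
    inner: str  # inner (deeper) volume domain id
    outer: str  # outer volume domain id


@dataclass
class AdjacencyGraph:
    """Domains as nodes, face-sharing contacts as edges, membranes on top.

    ``graph`` is an undirected :class:`networkx.Graph`; each node carries its
    ``domain_type`` and each edge a ``faces`` attribute counting voxel-face
    contacts.  Edges are irreflexive by construction and each edge between
    volume domains corresponds to exactly one membrane after
    :func:`create_membranes`.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)
    membranes: list[Membrane] = field(default_factory=list)
    membrane_types: dict[str, tuple[str, str]] = field(default_factory=dict)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(e)) for e in self.graph.edges)

    def faces(self, a: str, b: str) -> int:
        return int(self.graph.edges[a, b]["faces"])


def detect_adjacency(geom: LabeledGeometry, domains: list[Domain]) -> AdjacencyGraph:
    """Build the adjacency graph: edge (A, B) iff some voxel of A shares a face
    with some voxel of B, annotated with the shared-face count."""
    recomputed, index_grid = _components(geom)
    ids = [d.id for d in recomputed]
    if [d.id for d in domains] != ids:
        raise ValueError("domain list does not match this geometry")

    g = nx.Graph()
    for d in domains:
        g.add_node(d.id, domain_type=d.domain_type)

    pair_counts: dict[tuple[int, int], int] = {}
    for axis in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        a = index_grid[tuple(lo)].ravel()
        b = index_grid[tuple(hi)].ravel()
        diff = a != b
        if not diff.any():
            continue
        pairs = np.sort(np.stack([a[diff], b[diff]], axis=1), axis=1)
        uniq, counts = np.unique(pairs, axis=0, return_counts=True)
        for (i, j), c in zip(uniq, counts):
            key = (int(i), int(j))
            pair_counts[key] = pair_counts.get(key, 0) + int(c)

    for (i, j), c in pair_counts.items():
        g.add_edge(ids[i], ids[j], faces=c)
    return AdjacencyGraph(graph=g)


def create_membranes(graph: AdjacencyGraph, depth_order: list[str]) -> AdjacencyGraph:
    """Create one membrane domain per volume-volume edge, plus the shared
    membrane domain types.

    For an edge between domain types T_in (deeper in ``depth_order``) and T_out
    (shallower), the membrane type is :func:`membrane_name`'s ``(T_in, T_out)``
    name with spatial dimension 2; per-edge membrane domains get 0-based
    ordinals in deterministic (inner id, outer id) sort order.
    """
    pos = {name: i for i, name in enumerate(depth_order)}
    g = graph.graph
    mem_edges = []
    for a, b in g.edges:
        ta = g.nodes[a]["domain_type"]
        tb = g.nodes[b]["domain_type"]
        # deeper type = inner; equal depth broken by id for determinism
        if (pos.get(ta, -1), a) >= (pos.get(tb, -1), b):
            inner, outer, t_in, t_out = a, b, ta, tb
        else:
            inner, outer, t_in, t_out = b, a, tb, ta
        mem_edges.append((membrane_name(t_in, t_out), (t_in, t_out), inner, outer))

    mem_edges.sort(key=lambda t: (t[0], t[2], t[3]))
    membranes: list[Membrane] = []
    membrane_types: dict[str, tuple[str, str]] = {}
    ordinal: dict[str, int] = {}
    for mname, type_pair, inner, outer in mem_edges:
        membrane_types.setdefault(mname, type_pair)
        k = ordinal.get(mname, 0)
        ordinal[mname] = k + 1
        membranes.append(Membrane(id=f"{mname}{k}", domain_type=mname, inner=inner, outer=outer))
    return AdjacencyGraph(graph=g, membranes=membranes, membrane_types=membrane_types)


def membrane_type_specs(graph: AdjacencyGraph) -> list[DomainTypeSpec]:
    """Domain-type records (dimension 2, no sampled value) for all membranes."""
    return [DomainTypeSpec(name=n, dimension=2) for n in sorted(graph.membrane_types)]


def check_biology(
    graph: AdjacencyGraph, hierarchy: list[str] | dict[str, int]
) -> list[str]:
    """Warn about adjacencies that skip a containment level.

    In a biologically consistent model every contact is between a region and
    its direct parent (nucleus–cytosol, cytosol–extracellular); a nucleus
    touching the extracellular space means the cytosol segmentation has a
    breach.  One warning is emitted per offending edge; warnings never block
    export.

    ``hierarchy`` is either the depth-ordered name list (exact for nesting
    chains) or a name -> containment-depth mapping (needed when sibling types
    share a depth).
    """
    if isinstance(hierarchy, dict):
        depth = dict(hierarchy)
    else:
        depth = {name: i for i, name in enumerate(hierarchy)}
    g = graph.graph
    warnings: list[str] = []
    for a, b in sorted(g.edges):
        ta = g.nodes[a]["domain_type"]
        tb = g.nodes[b]["domain_type"]
        da, db = depth.get(ta), depth.get(tb)
        if da is None or db is None:
            continue
        if abs(da - db) != 1:
            shallow, deep = (ta, tb) if da < db else (tb, ta)
            warnings.append(
                f"{deep} adjacent to {shallow}: containment depths differ by "
                f"{abs(da - db)} (expected 1); check the segmentation of the "
                "intervening region"
            )
    return warnings


def to_dot(graph: AdjacencyGraph) -> str:
    """Render the domain adjacency (and membranes) as a DOT graph."""
    lines = ["graph adjacency {"]
    for node in sorted(graph.graph.nodes):
        lines.append(f'  "{node}" [shape=box];')
    for a, b in sorted(tuple(sorted(e)) for e in graph.graph.edges):
        faces = graph.graph.edges[a, b]["faces"]
        lines.append(f'  "{a}" -- "{b}" [label="{faces}"];')
    for m in graph.membranes:
        lines.append(f'  "{m.id}" [shape=ellipse, style=dashed];')
    lines.append("}")
    return "\n".join(lines)
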