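"""Scar lineage-tree reconstruction and cell placement.

Scars created early in development are inherited by large clades and
therefore co-occur with many later scars inside single cells. The
reconstruction exploits this: build a co-occurrence graph over scar
alleles, then repeatedly extract the most-connected allele as the next
ancestor; when removal disconnects the graph, the components become
sibling branches. Cells are finally placed at the lowest tree position
consistent with their detected scars.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import networkx as nx

from .filtering import CellScarProfile

__all__ = [
    "LineageTree",
    "TreeNode",
    "build_cooccurrence_graph",
    "infer_scar_tree",
    "place_cells",
    "build_tree",
]


@dataclass
class TreeNode:
    id: int
    scar: str | None  # None only for the virtual root
    parent: int | None
    children: list[int] = field(default_factory=list)
    cells: list[str] = field(default_factory=list)


class LineageTree:
    """Rooted scar tree with cells attached to nodes.

    The root is virtual (no scar label) so that scar-free cells have a
    home and disconnected scar clades can live side by side.
    """

    def __init__(self, replicate: str = "R1", timepoint: str = "") -> None:
        self.nodes: dict[int, TreeNode] = {0: TreeNode(0, None, None)}
        self.root = 0
        self.replicate = replicate
        self.timepoint = timepoint
        self._next_id = 1

    def add_node(self, scar: str | None, parent: int) -> int:
        nid = self._next_id
        self._next_id += 1
        self.nodes[nid] = TreeNode(nid, scar, parent)
        self.nodes[parent].children.append(nid)
        return nid

    def depth(self, nid: int) -> int:
        d = 0
        while self.nodes[nid].parent is not None:
            nid = self.nodes[nid].parent
            d += 1
        return d

    def path_scars(self, nid: int) -> frozenset[str]:
        """Scar labels on the root path to ``nid`` (inclusive)."""
        scars = []
        while nid is not None:
            node = self.nodes[nid]
            if node.scar is not None:
                scars.append(node.scar)
            nid = node.parent
        return frozenset(scars)

    def leaves(self) -> list[int]:
        return [nid for nid, n in self.nodes.items() if not n.children]

    def iter_preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            nid = stack.pop()
            node = self.nodes[nid]
            yield node
            stack.extend(reversed(node.children))

    def n_cells(self) -> int:
        return sum(len(n.cells) for n in self.nodes.values())

    def scar_to_node(self) -> dict[str, int]:
        return {n.scar: n.id for n in self.nodes.values() if n.scar is not None}

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "replicate": self.replicate,
            "timepoint": self.timepoint,
            "root": self.root,
            "nodes": [
                {
                    "id": n.id,
                    "scar": n.scar,
                    "parent": n.parent,
                    "children": list(n.children),
                    "cells": list(n.cells),
                }
                for n in self.nodes.values()
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LineageTree":
        t = cls(replicate=d.get("replicate", "R1"), timepoint=d.get("timepoint", ""))
        t.nodes = {}
        for nd in d["nodes"]:
            t.nodes[nd["id"]] = TreeNode(
                nd["id"], nd["scar"], nd["parent"], list(nd["children"]), list(nd["cells"])
            )
        t.root = d["root"]
        t._next_id = max(t.nodes) + 1
        return t

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "LineageTree":
        return cls.from_dict(json.loads(s))

    def to_newick(self) -> str:
        """Newick export; node comments carry the placed-cell counts."""

        def render(nid: int) -> str:
            node = self.nodes[nid]
            label = node.scar if node.scar is not None else "root"
            comment = f"[&cells={len(node.cells)}]"
            if not node.children:
                return f"{label}{comment}"
            inner = ",".join(render(c) for c in node.children)
            return f"({inner}){label}{comment}"

        return render(self.root) + ";"


def build_cooccurrence_graph(
    profiles: dict[str, CellScarProfile], min_cells: int = 1
) -> nx.Graph:
    """Graph over scar alleles; edge weight = cells carrying both alleles.

    Node attribute ``support`` counts cells carrying the allele. Doublet-
    flagged profiles are excluded. Edges below ``min_cells`` co-occurring
    cells are dropped.
    """
    g = nx.Graph()
    pair_counts: dict[tuple[str, str], int] = {}
    any_scar = False
    for p in profiles.values():
        if p.doublet_flag:
            continue
        alleles = sorted(p.scars)
        for a in alleles:
            any_scar = True
            if g.has_node(a):
                g.nodes[a]["support"] += 1
            else:
                g.add_node(a, support=1)
        for i in range(len(alleles)):
            for j in range(i + 1, len(alleles)):
                key = (alleles[i], alleles[j])
                pair_counts[key] = pair_counts.get(key, 0) + 1
    if not any_scar:
        raise ValueError("no scars in any retained cell; cannot build a scar graph")
    for (a, b), w in pair_counts.items():
        if w >= min_cells:
            g.add_edge(a, b, weight=w)
    return g


def _most_connected(g: nx.Graph, nodes: Iterable[str]) -> str:
    """Highest degree; ties by total edge weight, then cell support, then
    lexicographically smallest allele."""

    def key(n: str):
        return (
            -g.degree(n),
            -sum(d["weight"] for _, _, d in g.edges(n, data=True)),
            -g.nodes[n]["support"],
            n,
        )

    return min(nodes, key=key)


def infer_scar_tree(
    graph: nx.Graph, replicate: str = "R1", timepoint: str = ""
) -> LineageTree:
    """Iterative root extraction on the co-occurrence graph.

    Repeatedly remove the most-connected allele, appending it below the
    current position; when the remaining subgraph splits, each component
    becomes a sibling branch. A virtual unlabelled root sits above the
    components of the full graph.
    """
    tree = LineageTree(replicate=replicate, timepoint=timepoint)
    work = graph.copy()
    # stack of (component node set, parent tree-node id)
    stack: list[tuple[set[str], int]] = [
        (set(c), tree.root) for c in sorted(nx.connected_components(graph), key=sorted)
    ]
    while stack:
        comp, parent = stack.pop()
        sub = work.subgraph(comp)
        top = _most_connected(sub, comp)
        nid = tree.add_node(top, parent)
        rest = comp - {top}
        if rest:
            for c in sorted(nx.connected_components(work.subgraph(rest)), key=sorted):
                stack.append((set(c), nid))
    return tree


def place_cells(
    tree: LineageTree,
    profiles: dict[str, CellScarProfile],
    log_conflicts: bool = True,
) -> tuple[LineageTree, list[str]]:
    """Attach each non-doublet cell at its lowest consistent position.

    A position is consistent when its root-path scar set is contained in
    the cell's scar set and covers every cell scar present in the tree;
    scar-free cells go to the root. When no consistent position exists
    (dropout noise, recurrent alleles: scars spanning disjoint branches),
    the cell goes to the scar node explaining the most scar molecules
    (ties to the shallower node) and is reported as a conflict.
    """
    allele_node = tree.scar_to_node()
    pathsets = {nid: tree.path_scars(nid) for nid in tree.nodes}
    depths = {nid: tree.depth(nid) for nid in tree.nodes}
    conflicts: list[str] = []

    for bc in sorted(profiles):
        p = profiles[bc]
        if p.doublet_flag:
            continue
        in_tree = {s for s in p.scars if s in allele_node}
        unknown = set(p.scars) - in_tree
        if not in_tree:
            tree.nodes[tree.root].cells.append(bc)
            if unknown and log_conflicts:
                conflicts.append(bc)
            continue
        # candidate anchors: the nodes of the cell's own scars
        candidates = {allele_node[s] for s in in_tree}
        consistent = [
            nid
            for nid in candidates
            if pathsets[nid] <= set(p.scars) and in_tree <= pathsets[nid]
        ]
        if consistent:
            best = max(consistent, key=lambda nid: (depths[nid], -nid))
            if unknown and log_conflicts:
                conflicts.append(bc)
        else:
            # conflict: maximize explained scar molecules, tie -> shallower
            def score(nid: int) -> tuple[int, int, int]:
                explained = sum(p.scars[s] for s in pathsets[nid] & in_tree)
                return (explained, -depths[nid], -nid)

            best = max(sorted(candidates), key=score)
            if log_conflicts:
                conflicts.append(bc)
        tree.nodes[best].cells.append(bc)
    return tree, conflicts


def build_tree(
    profiles: dict[str, CellScarProfile],
    min_cells: int = 1,
    replicate: str = "R1",
    timepoint: str = "",
) -> tuple[LineageTree, list[str]]:
    """Co-occurrence graph -> scar tree -> cell placement, in one call."""
    graph = build_cooccurrence_graph(profiles, min_cells=min_cells)
    tree = infer_scar_tree(graph, replicate=replicate, timepoint=timepoint)
    return place_cells(tree, profiles)
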