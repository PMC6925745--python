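"""Directed acyclic graphs over survey variables."""

from __future__ import annotations

import networkx as nx


class DagError(ValueError):
    """Raised on cyclic, duplicate or otherwise invalid graph edits."""


class Dag:
    """A DAG with stable node order and parent/child lookups.

    Nodes are variable ids; edges are (parent, child) pairs. Acyclicity
    is enforced on every edit.
    """

    def __init__(self, nodes, edges=()):
        self._nodes = list(nodes)
        if len(set(self._nodes)) != len(self._nodes):
            raise DagError("duplicate nodes")
        self._parents = {n: [] for n in self._nodes}
        self._children = {n: [] for n in self._nodes}
        for u, v in edges:
            self.add_edge(u, v)

    @property
    def nodes(self) -> list:
        return list(self._nodes)

    @property
    def edges(self) -> list[tuple]:
        return [(u, v) for v in self._nodes for u in self._parents[v]]

    def parents(self, node) -> list:
        self._check(node)
        return list(self._parents[node])

    def children(self, node) -> list:
        self._check(node)
        return list(self._children[node])

    def neighbors(self, node) -> set:
        """Parents union children (the node's direct links)."""
        self._check(node)
        return set(self._parents[node]) | set(self._children[node])

    def has_edge(self, u, v) -> bool:
        return u in self._parents.get(v, ())

    def _check(self, node) -> None:
        if node not in self._parents:
            raise DagError(f"unknown node {node!r}")

    def _reaches(self, src, dst) -> bool:
        """True when dst is reachable from src along directed edges."""
        stack, seen = [src], set()
        while stack:
            cur = stack.pop()
            if cur == dst:
                return True
            if cur in seen:
                continue
            seen.add(cur)
            stack.extend(self._children[cur])
        return False

    def would_cycle(self, u, v) -> bool:
        return u == v or self._reaches(v, u)

    def add_edge(self, u, v) -> None:
        self._check(u)
        self._check(v)
        if self.has_edge(u, v):
            raise DagError(f"duplicate edge {u}->{v}")
        if self.would_cycle(u, v):
            raise DagError(f"edge {u}->{v} would create a cycle")
        self._parents[v].append(u)
        self._children[u].append(v)

    def remove_edge(self, u, v) -> None:
        if not self.has_edge(u, v):
            raise DagError(f"no edge {u}->{v}")
        self._parents[v].remove(u)
        self._children[u].remove(v)

    def copy(self) -> "Dag":
        return Dag(self._nodes, self.edges)

    def topological_order(self) -> list:
        order = list(nx.topological_sort(self.to_networkx()))
        return order

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self._nodes)
        g.add_edges_from(self.edges)
        return g

    def skeleton(self) -> set[frozenset]:
        """Undirected edge set."""
        return {frozenset((u, v)) for u, v in self.edges}

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Dag)
            and self._nodes == other._nodes
            and set(self.edges) == set(other.edges)
        )

    def __repr__(self) -> str:
        return f"Dag({len(self._nodes)} nodes, {len(self.edges)} edges)"
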