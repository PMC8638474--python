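"""Region adjacency graphs for spatial GMRF priors.

A :class:`RegionGraph` is a connected, undirected, simple graph over labelled
regions.  It is the structural input to the ICAR and PCAR spatial models: the
graph Laplacian (degree matrix minus adjacency) is the ICAR precision
structure, and ``D - rho*A`` is the proper CAR structure.

Two fixture families ship with the package:

* ``"namibia13"`` — the 13 political regions of Namibia prior to the August
  2013 split of Kavango, digitised once from the national map and stored as a
  plain edge list.  Analyses should only rely on this graph being symmetric
  and connected, not on any particular border.
* ``"ring<k>"`` — a k-cycle, handy for small exact tests.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import networkx as nx
import numpy as np
import scipy.sparse as sp

__all__ = ["RegionGraph", "build_region_graph", "read_edge_list", "write_edge_list"]


@dataclass(frozen=True)
class RegionGraph:
    """Symmetric, connected, self-loop-free adjacency over labelled regions."""

    nodes: tuple[str, ...]
    edges: frozenset[frozenset[str]] = field(repr=False)

    def __post_init__(self) -> None:
        seen = set(self.nodes)
        if len(seen) != len(self.nodes):
            raise ValueError("duplicate region labels")
        for e in self.edges:
            if len(e) != 2:
                raise ValueError(f"self-loop or malformed edge: {set(e)}")
            if not e <= seen:
                raise ValueError(f"edge {set(e)} references unknown node")
        if not nx.is_connected(self.to_networkx()):
            raise ValueError("region graph must be connected")

    @classmethod
    def from_edges(
        cls, edges: list[tuple[str, str]], nodes: list[str] | None = None
    ) -> "RegionGraph":
        if nodes is None:
            ordered: list[str] = []
            for a, b in edges:
                for v in (a, b):
                    if v not in ordered:
                        ordered.append(v)
            nodes = ordered
        return cls(tuple(nodes), frozenset(frozenset(e) for e in edges))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(tuple(sorted(e)) for e in self.edges)
        return g

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def index(self, label: str) -> int:
        return self.nodes.index(label)

    def adjacency(self) -> sp.csr_matrix:
        """Binary adjacency in the graph's fixed node order."""
        idx = {v: i for i, v in enumerate(self.nodes)}
        rows, cols = [], []
        for e in self.edges:
            a, b = tuple(e)
            rows += [idx[a], idx[b]]
            cols += [idx[b], idx[a]]
        data = np.ones(len(rows))
        return sp.csr_matrix(
            (data, (rows, cols)), shape=(self.n_nodes, self.n_nodes)
        )

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency().sum(axis=1)).ravel()


def read_edge_list(path: str | Path) -> RegionGraph:
    """Read a tab-separated ``regionA<TAB>regionB`` edge list."""
    edges = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"malformed edge line: {line!r}")
        edges.append((parts[0], parts[1]))
    return RegionGraph.from_edges(edges)


def write_edge_list(graph: RegionGraph, path: str | Path) -> Path:
    path = Path(path)
    lines = sorted("\t".join(sorted(e)) for e in graph.edges)
    path.write_text("\n".join(lines) + "\n")
    return path


def _ring(k: int) -> RegionGraph:
    if k < 3:
        raise ValueError("ring needs at least 3 nodes")
    names = [f"R{i+1}" for i in range(k)]
    edges = [(names[i], names[(i + 1) % k]) for i in range(k)]
    return RegionGraph.from_edges(edges, names)


def build_region_graph(fixture_name: str) -> RegionGraph:
    """Return a named fixture graph.

    ``"namibia13"`` loads the shipped 13-region Namibia edge list;
    ``"ring<k>"`` builds a k-cycle (k >= 3).
    """
    if fixture_name == "namibia13":
        ref = resources.files("qintreg.data") / "namibia13.tsv"
        with resources.as_file(ref) as p:
            return read_edge_list(p)
    m = re.fullmatch(r"ring(\d+)", fixture_name)
    if m:
        return _ring(int(m.group(1)))
    raise ValueError(f"unknown graph fixture {fixture_name!r}")
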