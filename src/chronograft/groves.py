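"""Grove detection and supertree construction.

A grove is a set of trees with enough pairwise taxon overlap to be combined
into a single supertree.  The n-overlap condition is operationalized as
connectivity of the graph whose vertices are trees and whose edges join
pairs sharing at least ``n`` taxa; groves are its connected components.
This is the standard sufficient condition and an approximation of the
stricter combinatorial definition in the groves literature.

The supertree of a grove is built by summarizing the members' patristic
matrices with the variance-minimizing SDM summary and clustering the result
with missing-value-aware average linkage; only the topology is returned.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

from .trees import Tree, parse_newick, patristic_matrix

__all__ = ["Grove", "find_groves", "pick_grove", "supertree", "GroveError"]


class GroveError(ValueError):
    pass


@dataclass(frozen=True)
class Grove:
    members: tuple[int, ...]  # indices into the input tree list
    taxa: frozenset[str]

    @property
    def n_trees(self) -> int:
        return len(self.members)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def report(self) -> dict:
        return {
            "members": list(self.members),
            "n_trees": self.n_trees,
            "n_taxa": self.n_taxa,
            "taxa": sorted(self.taxa),
        }


def find_groves(tip_sets: Sequence[set[str]], n: int = 2) -> list[Grove]:
    """Connected components of the pairwise n-overlap graph.

    Groves partition the input: every tree belongs to exactly one grove
    (isolated trees form singleton groves).
    """
    if n < 1:
        raise GroveError("overlap threshold n must be >= 1")
    graph = nx.Graph()
    graph.add_nodes_from(range(len(tip_sets)))
    for i in range(len(tip_sets)):
        for j in range(i + 1, len(tip_sets)):
            if len(set(tip_sets[i]) & set(tip_sets[j])) >= n:
                graph.add_edge(i, j)
    groves = []
    for component in nx.connected_components(graph):
        members = tuple(sorted(component))
        taxa = frozenset().union(*(tip_sets[i] for i in members))
        groves.append(Grove(members, taxa))
    return sorted(groves, key=lambda g: g.members)


def pick_grove(groves: Sequence[Grove], criterion: str = "taxa") -> Grove:
    """Choose the grove with the most taxa (default) or the most trees
    (``criterion="trees"``); ties break on the other criterion, then on the
    smallest member index."""
    if not groves:
        raise GroveError("no groves to choose from")
    if criterion not in {"taxa", "trees"}:
        raise GroveError(f"unknown criterion {criterion!r}")
    if criterion == "taxa":
        key = lambda g: (-g.n_taxa, -g.n_trees, g.members)
    else:
        key = lambda g: (-g.n_trees, -g.n_taxa, g.members)
    return sorted(groves, key=key)[0]


def _average_linkage_topology(labels: Sequence[str], dist: np.ndarray) -> Tree:
    """Missing-value-aware average-linkage agglomeration; returns the rooted
    topology (no branch lengths).  Cluster-to-cluster distance is the mean
    over available (non-NaN) tip pairs."""
    clusters: list[list[int]] = [[i] for i in range(len(labels))]
    newicks: list[str] = [_quote(l) for l in labels]
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                cells = dist[np.ix_(clusters[i], clusters[j])]
                if np.all(np.isnan(cells)):
                    continue
                d = float(np.nanmean(cells))
                if best is None or d < best[0]:
                    best = (d, i, j)
        if best is None:
            raise GroveError(
                "summary matrix is disconnected; cannot assemble a supertree"
            )
        _, i, j = best
        clusters[i] = clusters[i] + clusters[j]
        newicks[i] = f"({newicks[i]},{newicks[j]})"
        del clusters[j], newicks[j]
    return parse_newick(newicks[0] + ";", underscores_to_spaces=False)


def _quote(label: str) -> str:
    if any(ch in label for ch in "()[]{},;:= \t'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def supertree(records: Sequence) -> Tree:
    """Summary supertree topology of a grove of chronogram records.

    ``records`` are chronogram-bearing objects (``.chronogram`` attribute,
    e.g. :class:`chronograft.chronodb.ChronogramRecord`) or plain
    chronograms.  Fails if the records do not form a single grove.
    """
    from .summarize import sdm_summary

    chronos = [getattr(r, "chronogram", r) for r in records]
    tip_sets = [set(c.tip_labels) for c in chronos]
    groves = find_groves(tip_sets, n=2)
    if len(groves) > 1:
        raise GroveError(
            "records do not form a grove; supertree reconstruction fails "
            "(pick one grove first)"
        )
    if len(chronos) == 1:
        clone = chronos[0].dendropy_tree.clone(depth=1)
        for node in clone.preorder_node_iter():
            node.edge.length = None
        return Tree(clone)
    matrices = [patristic_matrix(c) for c in chronos]
    summary = sdm_summary(matrices)
    return _average_linkage_topology(summary.labels, summary.values.copy())
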