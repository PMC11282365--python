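"""Congruification: map source node ages onto congruent nodes of a target.

A source chronogram (held as a patristic matrix of total tip-to-tip time)
calibrates an internal node ``v`` of the target topology when the clade is
congruent: the shared tips descending from ``v`` in the target are exactly
the shared tips descending from their MRCA in the source, and ``v`` is the
target MRCA of that set.  The age contributed is half the matrix entry of a
witness taxon pair spanning the source MRCA, because the matrices store
total distance, tip to tip, under the assumption that terminal taxa are
coeval at the present.

The source-side clade structure is read directly off the patristic matrix:
in an ultrametric matrix, the tips below the MRCA of a set ``S`` are exactly
the tips whose distance to every member of ``S`` is at most the diameter of
``S``.  No tree reconstruction is required.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import dendropy
import numpy as np
import pandas as pd

from .chronodb import SearchResult
from .trees import PatristicMatrix, Tree

__all__ = [
    "CalibrationPoint",
    "CalibrationTable",
    "congruify_one",
    "build_calibration_table",
    "assign_node_names",
]

#: relative tolerance for agreeing pairwise entries across one source node
ENTRY_RTOL = 1e-6

NO_OVERLAP_MESSAGE = "no source chronogram overlaps the target topology by >= 2 taxa"


@dataclass(frozen=True)
class CalibrationPoint:
    node: str  # stable node name on the target (n1 = root, preorder)
    taxon_a: str
    taxon_b: str
    age: float  # Myr; = source matrix entry(taxon_a, taxon_b) / 2
    record_id: str = ""
    citation: str = ""


def assign_node_names(target: Tree) -> dict[dendropy.Node, str]:
    """Stable names for the target's internal nodes: ``n1`` is the root,
    then root-down preorder visiting children by smallest descendant tip
    label in descending order.  The traversal is canonical -- it depends
    only on the tree's structure and labels, never on the child order of
    the newick it was read from."""
    min_label: dict[dendropy.Node, str] = {}
    for node in target.dendropy_tree.postorder_node_iter():
        if node.is_leaf():
            min_label[node] = node.taxon.label
        else:
            min_label[node] = min(min_label[c] for c in node.child_nodes())
    names: dict[dendropy.Node, str] = {}

    def visit(node: dendropy.Node) -> None:
        if node.is_leaf():
            return
        names[node] = f"n{len(names) + 1}"
        for child in sorted(node.child_nodes(), key=lambda c: min_label[c], reverse=True):
            visit(child)

    visit(target.root)
    return names


def congruify_one(
    target: Tree,
    source: PatristicMatrix,
    node_names: Optional[dict[dendropy.Node, str]] = None,
    record_id: str = "",
    citation: str = "",
) -> list[CalibrationPoint]:
    """Calibration points contributed by one source matrix.

    Incongruent nodes simply yield no row.  Within one congruent source
    node, all traversing pairwise entries must agree within the ultrametric
    tolerance (guaranteed for matrices derived from validated chronograms).
    """
    if node_names is None:
        node_names = assign_node_names(target)
    shared = set(source.labels) & set(target.tip_labels)
    if len(shared) < 2:
        return []

    shared_sorted = sorted(shared)
    idx = {l: source.labels.index(l) for l in shared_sorted}
    d = source.values

    target_tip_sets = {v: target.tip_set(v) for v in target.internal_nodes()}

    points = []
    for v in target.internal_nodes():
        S = sorted(target_tip_sets[v] & shared)
        if len(S) < 2:
            continue
        # v must itself be the target MRCA of S, otherwise the calibration
        # belongs to a shallower node (clades collapse when tips are absent
        # from the source)
        if target.mrca(S) is not v:
            continue
        rows = [idx[s] for s in S]
        sub = d[np.ix_(rows, rows)]
        height = float(sub.max())  # diameter of S = 2 x source MRCA age
        if height <= 0:
            continue
        # source-side descendant closure of MRCA(S): every shared tip within
        # `height` of all members of S
        closure = {
            t
            for t in shared_sorted
            if all(d[idx[t], idx[s]] <= height * (1 + ENTRY_RTOL) for s in S)
        }
        if closure != set(S):
            continue  # source disagrees about this clade: no calibration
        # pairs traversing the source MRCA are those achieving the diameter;
        # they must agree within tolerance (max vs min of the spanning set)
        spanning = [
            (S[i], S[j])
            for i in range(len(S))
            for j in range(i + 1, len(S))
            if sub[i, j] >= height * (1 - ENTRY_RTOL)
        ]
        witness_a, witness_b = min(spanning)
        points.append(
            CalibrationPoint(
                node=node_names[v],
                taxon_a=witness_a,
                taxon_b=witness_b,
                age=source.entry(witness_a, witness_b) / 2.0,
                record_id=record_id,
                citation=citation,
            )
        )
    return points


@dataclass
class CalibrationTable:
    """Congruified (node, age, source) rows plus the target topology."""

    points: list[CalibrationPoint]
    target: Tree
    node_names: dict[dendropy.Node, str] = field(default_factory=dict)
    message: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.node_names:
            self.node_names = assign_node_names(self.target)
        seen = set()
        for p in self.points:
            key = (p.node, p.age, p.record_id or p.citation, p.taxon_a, p.taxon_b)
            if key in seen:
                raise ValueError(f"duplicate calibration row {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.points)

    def ages_by_node(self) -> dict[str, list[float]]:
        out: dict[str, list[float]] = {}
        for p in self.points:
            out.setdefault(p.node, []).append(p.age)
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "node_name": p.node,
                    "taxon_a": p.taxon_a,
                    "taxon_b": p.taxon_b,
                    "node_age": p.age,
                    "study_reference": p.citation or p.record_id,
                }
                for p in self.points
            ],
            columns=["node_name", "taxon_a", "taxon_b", "node_age", "study_reference"],
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, target: Tree) -> "CalibrationTable":
        df = pd.read_csv(path)
        points = [
            CalibrationPoint(
                node=row.node_name,
                taxon_a=row.taxon_a,
                taxon_b=row.taxon_b,
                age=float(row.node_age),
                citation=str(row.study_reference),
            )
            for row in df.itertuples()
        ]
        return cls(points, target)


def build_calibration_table(target: Tree, result: SearchResult) -> CalibrationTable:
    """Concatenate :func:`congruify_one` over all records of a search result."""
    node_names = assign_node_names(target)
    points: list[CalibrationPoint] = []
    any_overlap = False
    for match in result.matches:
        if len(set(match.matrix.labels) & set(target.tip_labels)) >= 2:
            any_overlap = True
        points.extend(
            congruify_one(
                target,
                match.matrix,
                node_names=node_names,
                record_id=match.record_id,
                citation=match.citation,
            )
        )
    message = None if any_overlap else NO_OVERLAP_MESSAGE
    return CalibrationTable(points, target, node_names, message=message)
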