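"""Rooted-tree data model: newick I/O, pruning, MRCA queries, patristic matrices.

Trees are thin wrappers around :class:`dendropy.Tree`; parsing is delegated
to dendropy while writing is done here so that output is canonical (children
ordered by their smallest descendant tip label), which makes round-trips
bit-stable.  A :class:`Chronogram` is a tree whose branch lengths are absolute
times (Myr): it must be ultrametric, and every node then carries an age (time
before present; tips are at 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import dendropy
import numpy as np

__all__ = [
    "Tree",
    "Chronogram",
    "PatristicMatrix",
    "TreeError",
    "NewickParseError",
    "NotUltrametricError",
    "parse_newick",
    "write_newick",
    "chronogram_from_node_ages",
]

#: relative tolerance on root-to-tip path sums when accepting a chronogram
ULTRAMETRIC_RTOL = 1e-6


class TreeError(ValueError):
    """Structural problem with a tree (labels, topology, lengths)."""


class NewickParseError(TreeError):
    """Malformed newick input."""


class NotUltrametricError(TreeError):
    """Tree cannot be interpreted as a chronogram."""


class Tree:
    """A rooted tree with uniquely labelled tips.

    Branch lengths are optional; internal labels, if present, are preserved
    but never used for matching.  Polytomies are allowed everywhere.
    """

    def __init__(self, dtree: dendropy.Tree):
        dtree.is_rooted = True  # unrooted trees are out of scope
        self._dtree = dtree
        self._validate()

    # -- construction ---------------------------------------------------

    @classmethod
    def from_newick(cls, text: str, underscores_to_spaces: bool = True) -> "Tree":
        return cls(_read_dendropy(text, underscores_to_spaces))

    def copy(self) -> "Tree":
        return type(self)(self._dtree.clone(depth=1))

    # -- basic queries --------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._dtree

    @property
    def root(self) -> dendropy.Node:
        return self._dtree.seed_node

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._dtree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return sum(1 for _ in self._dtree.preorder_node_iter())

    @property
    def has_branch_lengths(self) -> bool:
        return all(
            node.edge.length is not None
            for node in self._dtree.preorder_node_iter()
            if node.parent_node is not None
        )

    def internal_nodes(self) -> list[dendropy.Node]:
        """Internal nodes in root-down preorder, following input child order."""
        return [n for n in self._dtree.preorder_node_iter() if not n.is_leaf()]

    def tip_set(self, node: dendropy.Node) -> frozenset[str]:
        return frozenset(leaf.taxon.label for leaf in node.leaf_iter())

    def mrca(self, tips: Iterable[str]) -> dendropy.Node:
        """Deepest node whose descendant tip set contains ``tips``."""
        tips = list(tips)
        if not tips:
            raise TreeError("mrca of an empty tip set is undefined")
        known = set(self.tip_labels)
        missing = [t for t in tips if t not in known]
        if missing:
            raise TreeError(f"unknown tip label(s): {missing}")
        if len(set(tips)) == 1:
            (label,) = set(tips)
            return next(
                leaf for leaf in self._dtree.leaf_node_iter() if leaf.taxon.label == label
            )
        return self._dtree.mrca(taxon_labels=list(set(tips)))

    # -- manipulation ---------------------------------------------------

    def prune(self, keep: Iterable[str]) -> "Tree":
        """Induced subtree on ``keep``; unifurcations are suppressed with
        branch lengths summed, so tip-to-tip path lengths are preserved."""
        keep = set(keep) & set(self.tip_labels)
        if len(keep) < 2:
            raise TreeError(
                f"pruning must retain at least 2 tips; got {len(keep)}"
            )
        sub = self._dtree.extract_tree_with_taxa_labels(keep)
        return type(self)(sub)

    def rename_tips(self, mapping: Mapping[str, str]) -> "Tree":
        """Return a copy with tip labels replaced per ``mapping`` (missing
        labels are left as-is)."""
        clone = self._dtree.clone(depth=1)
        ns = dendropy.TaxonNamespace()
        for leaf in clone.leaf_node_iter():
            old = leaf.taxon.label
            leaf.taxon = dendropy.Taxon(label=mapping.get(old, old))
            ns.add_taxon(leaf.taxon)
        clone.taxon_namespace = ns
        return type(self)(clone)

    # -- output ---------------------------------------------------------

    def write_newick(
        self, include_lengths: bool = True, spaces_to_underscores: bool = True
    ) -> str:
        return _write_canonical(
            self._dtree, include_lengths, spaces_to_underscores
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<{type(self).__name__} {self.n_tips} tips>"

    # -- validation -----------------------------------------------------

    def _validate(self) -> None:
        labels = []
        for leaf in self._dtree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise TreeError("every tip must carry a non-empty label")
            labels.append(leaf.taxon.label)
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise TreeError(f"duplicate tip label(s): {sorted(dupes)}")


class Chronogram(Tree):
    """An ultrametric tree with branch lengths in Myr and derived node ages.

    Construction fails if any branch length is missing or if root-to-tip
    path sums differ by more than ``ULTRAMETRIC_RTOL`` (relative); published
    files carry rounding noise, so small deviations are absorbed into the
    node ages (age = mean depth-complement over descendant tips' paths is
    not needed -- we use max distance-to-tip, which is exact for clean input).
    """

    def __init__(self, dtree: dendropy.Tree):
        super().__init__(dtree)
        self._ages = self._compute_ages()

    @property
    def root_age(self) -> float:
        return self._ages[self.root]

    def age_of(self, node: dendropy.Node) -> float:
        return self._ages[node]

    def node_ages(self) -> dict[dendropy.Node, float]:
        return dict(self._ages)

    def _compute_ages(self) -> dict[dendropy.Node, float]:
        for node in self._dtree.preorder_node_iter():
            if node.parent_node is not None and node.edge.length is None:
                raise NotUltrametricError(
                    "chronogram has missing branch lengths"
                )
        depths = {}
        for node in self._dtree.preorder_node_iter():
            if node.parent_node is None:
                depths[node] = 0.0
            else:
                depths[node] = depths[node.parent_node] + node.edge.length
        tip_depths = [depths[l] for l in self._dtree.leaf_node_iter()]
        height = max(tip_depths)
        if height > 0 and (height - min(tip_depths)) / height > ULTRAMETRIC_RTOL:
            raise NotUltrametricError(
                "root-to-tip path sums differ beyond relative tolerance "
                f"{ULTRAMETRIC_RTOL:g}: min={min(tip_depths)!r} max={height!r}"
            )
        ages = {}
        # age = distance to any descendant tip; computed from max subtree
        # depth below each node so rounding noise cannot produce negatives
        for node in self._dtree.postorder_node_iter():
            if node.is_leaf():
                ages[node] = 0.0
            else:
                ages[node] = max(
                    ages[c] + c.edge.length for c in node.child_nodes()
                )
        return ages


@dataclass(frozen=True)
class PatristicMatrix:
    """Symmetric tip x tip matrix of total path length (time, tip to tip).

    For an ultrametric source, ``entry(a, b) = 2 * age(MRCA(a, b))`` -- node
    ages are half the stored values.
    """

    labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(v, v.T):
            raise ValueError("patristic matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("patristic matrix must have a zero diagonal")
        if np.any(v < 0):
            raise ValueError("patristic distances must be non-negative")
        object.__setattr__(self, "values", v)

    def entry(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    @property
    def max_entry(self) -> float:
        return float(self.values.max())

    def subset(self, keep: Iterable[str]) -> "PatristicMatrix":
        keep = [l for l in self.labels if l in set(keep)]
        idx = [self.labels.index(l) for l in keep]
        return PatristicMatrix(tuple(keep), self.values[np.ix_(idx, idx)])

    def as_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


# ---------------------------------------------------------------------------
# module-level operations


def parse_newick(text: str, underscores_to_spaces: bool = True) -> Tree:
    """Parse a single ``;``-terminated newick string into a :class:`Tree`.

    Unquoted underscores decode to spaces by default (binomials are commonly
    underscore-encoded in newick); pass ``underscores_to_spaces=False`` to
    keep them verbatim.
    """
    return Tree.from_newick(text, underscores_to_spaces)


def write_newick(tree: Tree, include_lengths: bool = True) -> str:
    return tree.write_newick(include_lengths=include_lengths)


def patristic_matrix(chronogram: Chronogram) -> PatristicMatrix:
    """Tip-pair total time matrix of an ultrametric chronogram."""
    if not isinstance(chronogram, Chronogram):
        chronogram = as_chronogram(chronogram)
    labels = sorted(chronogram.tip_labels)
    index = {l: i for i, l in enumerate(labels)}
    n = len(labels)
    out = np.zeros((n, n))
    # fill via each internal node's age: pairs split across its children
    for node in chronogram.internal_nodes():
        age = chronogram.age_of(node)
        child_sets = [sorted(chronogram.tip_set(c)) for c in node.child_nodes()]
        for a_i in range(len(child_sets)):
            for b_i in range(a_i + 1, len(child_sets)):
                for a in child_sets[a_i]:
                    for b in child_sets[b_i]:
                        out[index[a], index[b]] = out[index[b], index[a]] = 2 * age
    return PatristicMatrix(tuple(labels), out)


def as_chronogram(tree: Tree) -> Chronogram:
    """Reinterpret a tree as a chronogram (validating ultrametricity)."""
    if isinstance(tree, Chronogram):
        return tree
    return Chronogram(tree.dendropy_tree.clone(depth=1))


def chronogram_from_node_ages(
    topology: Tree, ages: Mapping[dendropy.Node, float] | Mapping[frozenset, float]
) -> Chronogram:
    """Build a chronogram on ``topology`` from per-internal-node ages.

    ``ages`` maps either dendropy nodes of ``topology`` or frozensets of tip
    labels (clades) to ages in Myr.  Every internal node must be covered and
    ages must strictly decrease root-to-tip.
    """
    clone = topology.dendropy_tree.clone(depth=1)
    wrapped = Tree(clone)

    def age_for(node: dendropy.Node) -> float:
        if node in ages:
            return float(ages[node])
        key = wrapped.tip_set(node)
        if key in ages:
            return float(ages[key])
        raise TreeError(f"no age provided for internal node {sorted(key)}")

    node_age: dict[dendropy.Node, float] = {}
    for node in clone.preorder_node_iter():
        if node.is_leaf():
            node_age[node] = 0.0
        else:
            node_age[node] = age_for(node)
            parent = node.parent_node
            if parent is not None and node_age[node] >= node_age[parent]:
                raise TreeError(
                    "node ages must strictly decrease root-to-tip: "
                    f"{node_age[node]} under {node_age[parent]}"
                )
    for node in clone.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = node_age[node.parent_node] - node_age[node]
    return Chronogram(clone)


# ---------------------------------------------------------------------------
# newick plumbing


def _read_dendropy(text: str, underscores_to_spaces: bool) -> dendropy.Tree:
    if not text or not text.strip():
        raise NewickParseError("empty newick string")
    try:
        return dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=not underscores_to_spaces,
            suppress_internal_node_taxa=True,
        )
    except dendropy.utility.error.DataParseError as exc:
        raise NewickParseError(str(exc)) from exc


def _needs_quoting(label: str) -> bool:
    special = set("()[]{}/\\,;:=*'\"`<>^ \t\n")
    return any(ch in special for ch in label)


def _format_label(label: str, spaces_to_underscores: bool) -> str:
    if spaces_to_underscores and " " in label and "_" not in label:
        label = label.replace(" ", "_")
    if _needs_quoting(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _write_canonical(
    dtree: dendropy.Tree, include_lengths: bool, spaces_to_underscores: bool
) -> str:
    min_label: dict[dendropy.Node, str] = {}
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            min_label[node] = node.taxon.label
        else:
            min_label[node] = min(min_label[c] for c in node.child_nodes())

    def render(node: dendropy.Node) -> str:
        if node.is_leaf():
            out = _format_label(node.taxon.label, spaces_to_underscores)
        else:
            children = sorted(node.child_nodes(), key=lambda c: min_label[c])
            out = "(" + ",".join(render(c) for c in children) + ")"
            if node.label:
                out += _format_label(node.label, spaces_to_underscores)
        if include_lengths and node.parent_node is not None and node.edge.length is not None:
            out += f":{node.edge.length:.10g}"
        return out

    return render(dtree.seed_node) + ";"
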