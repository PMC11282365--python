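"""Dating a topology from summarized node ages.

The pipeline here turns per-node age summaries into a consistent set of
fixed calibrations (discarding ages that conflict with the nesting of
clades), resolves a root age, and interpolates the remaining node ages with
the BLADJ even-spacing rule: every uncalibrated node is placed by dividing
the time between its nearest calibrated ancestor and a calibrated
descendant evenly along the connecting path, which minimizes age variance
among the interpolated nodes.  Tips count as calibrated at age zero, so a
fully uncalibrated subtree still dates cleanly below its ancestor.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .chronodb import ChronogramDB, SearchResult, search
from .congruify import CalibrationTable, assign_node_names, build_calibration_table
from .names import ResolvedQuery
from .summarize import NodeAgeSummary, summarize_node_ages
from .trees import Chronogram, Tree, chronogram_from_node_ages

__all__ = [
    "CalibrationSet",
    "filter_calibrations",
    "resolve_root_age",
    "bladj",
    "date_topology",
    "DatingError",
    "RandomRootWarning",
    "external_dater_config",
]

logger = logging.getLogger(__name__)

#: multiplier applied to the oldest retained calibration when no root age
#: is known (deterministic default; randomization is opt-in via a seed)
DEFAULT_ROOT_FACTOR = 1.1

USED = "used"
DISCARDED_OLDER = "discarded:older-than-ancestor"
DISCARDED_YOUNGER = "discarded:younger-than-descendant"


class DatingError(ValueError):
    pass


class RandomRootWarning(UserWarning):
    """The root age was invented because no data covered the root."""


@dataclass
class CalibrationSet:
    """Fixed node ages (by stable node name) plus per-node provenance."""

    ages: dict[str, float]  # retained calibrations only
    root_age: Optional[float] = None
    provenance: dict[str, str] = field(default_factory=dict)
    root_policy: str = "unset"

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"node_name": n, "age": a, "status": self.provenance.get(n, USED)}
            for n, a in sorted(self.ages.items(), key=lambda kv: int(kv[0].lstrip("n")))
        ]
        for node, status in sorted(self.provenance.items()):
            if status != USED and node not in self.ages:
                rows.append({"node_name": node, "age": float("nan"), "status": status})
        return pd.DataFrame(rows, columns=["node_name", "age", "status"])

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def filter_calibrations(
    summaries: Sequence[NodeAgeSummary],
    target: Tree,
    stat: str = "median",
) -> CalibrationSet:
    """Resolve age conflicts against the nesting of the target's clades.

    Two passes: root-down, discarding any age >= the age of its nearest
    retained ancestor; then tip-up, discarding any age <= the age of a
    retained descendant.  The pass order matters when chains conflict and
    is part of the contract (deeper, more inclusive nodes win first).
    """
    if stat not in {"median", "mean"}:
        raise DatingError(f"unsupported summary statistic {stat!r}")
    node_names = assign_node_names(target)
    by_name = {s.node: getattr(s, stat) for s in summaries}
    unknown = set(by_name) - set(node_names.values())
    if unknown:
        raise DatingError(f"summaries name nodes absent from the target: {sorted(unknown)}")

    retained: dict[str, float] = {}
    provenance: dict[str, str] = {}

    # pass 1: root-down against nearest retained ancestor
    ancestor_age: dict[dendropy.Node, Optional[float]] = {}
    for node in target.internal_nodes():  # preorder
        name = node_names[node]
        parent = node.parent_node
        inherited = ancestor_age.get(parent) if parent is not None else None
        if name in by_name:
            age = by_name[name]
            if inherited is not None and age >= inherited:
                provenance[name] = DISCARDED_OLDER
                logger.info(
                    "calibration %s (%.3f) discarded: older than nearest "
                    "retained ancestor (%.3f)", name, age, inherited,
                )
                ancestor_age[node] = inherited
            else:
                retained[name] = age
                provenance[name] = USED
                ancestor_age[node] = age
        else:
            ancestor_age[node] = inherited

    # pass 2: tip-up against oldest retained descendant
    max_desc: dict[dendropy.Node, float] = {}
    for node in reversed(target.internal_nodes()):  # postorder over internals
        desc = 0.0
        for child in node.child_nodes():
            if not child.is_leaf():
                child_name = node_names[child]
                child_age = retained.get(child_name, 0.0)
                desc = max(desc, max_desc.get(child, 0.0), child_age)
        name = node_names[node]
        if name in retained and desc > 0 and retained[name] <= desc:
            logger.info(
                "calibration %s (%.3f) discarded: younger than a retained "
                "descendant (%.3f)", name, retained[name], desc,
            )
            del retained[name]
            provenance[name] = DISCARDED_YOUNGER
        max_desc[node] = desc

    if not retained:
        raise DatingError("all calibrations were discarded as conflicting")

    root_name = node_names[target.internal_nodes()[0]]
    return CalibrationSet(
        ages=retained,
        root_age=retained.get(root_name),
        provenance=provenance,
        root_policy="summary" if root_name in retained else "unset",
    )


def resolve_root_age(
    cal_set: CalibrationSet,
    user_root: Optional[float] = None,
    rng_seed: Optional[int] = None,
) -> float:
    """Pick the root age: user-supplied value wins; else the root's own
    summary age; else a default of ``1.1 x`` the oldest retained calibration
    with a conspicuous warning (or, with ``rng_seed``, a uniform draw between
    1x and 2x the oldest calibration, mirroring a randomized-root policy)."""
    if user_root is not None:
        if user_root <= 0:
            raise DatingError("root age must be positive")
        cal_set.root_age = float(user_root)
        cal_set.root_policy = "user"
        return cal_set.root_age
    if cal_set.root_age is not None:
        cal_set.root_policy = "summary"
        return cal_set.root_age
    if not cal_set.ages:
        raise DatingError("no calibrations and no user root age")
    oldest = max(cal_set.ages.values())
    if rng_seed is not None:
        rng = np.random.default_rng(rng_seed)
        root = float(oldest * rng.uniform(1.0, 2.0))
        policy = f"random(seed={rng_seed})"
    else:
        root = oldest * DEFAULT_ROOT_FACTOR
        policy = f"default({DEFAULT_ROOT_FACTOR}x oldest calibration)"
    warnings.warn(
        "No age data covered the root: the root age was set to "
        f"{root:.3f} Myr by policy {policy}. Provide a root age from the "
        "literature for a defensible chronogram.",
        RandomRootWarning,
        stacklevel=2,
    )
    cal_set.root_age = root
    cal_set.root_policy = policy
    return root


def bladj(target: Tree, cal_set: CalibrationSet) -> Chronogram:
    """Date ``target`` by even-spacing interpolation between fixed ages.

    Fixed nodes get exactly their calibration ages and tips get zero.  Every
    unfixed internal node is placed top-down between its (already dated)
    parent and a chosen fixed descendant D -- the fixed descendant with the
    largest age, ties broken by fewest intervening unfixed nodes, then by
    smallest descendant label -- at the first step of an even division of
    the parent-to-D interval.  On a chain of m unfixed nodes between fixed
    ages a and d this reduces to ages ``a - (a - d) * k / (m + 1)``.
    The output is exactly ultrametric.
    """
    if cal_set.root_age is None:
        raise DatingError("root age is unresolved; call resolve_root_age first")
    node_names = assign_node_names(target)
    internals = target.internal_nodes()
    root = internals[0]
    fixed: dict[dendropy.Node, float] = {root: float(cal_set.root_age)}
    for node in internals[1:]:
        name = node_names[node]
        if name in cal_set.ages:
            fixed[node] = float(cal_set.ages[name])
    root_name = node_names[root]
    if root_name in cal_set.ages and cal_set.ages[root_name] != cal_set.root_age:
        raise DatingError("root calibration disagrees with the resolved root age")
    for node, age in fixed.items():
        parent = node.parent_node
        while parent is not None:
            if parent in fixed and fixed[parent] <= age:
                raise DatingError(
                    "fixed ages do not decrease root-to-tip; filter "
                    "calibrations before dating"
                )
            parent = parent.parent_node

    # per-node: best fixed descendant (age, -unfixed-count, label) and the
    # number of unfixed internal nodes on the path down to it
    min_label: dict[dendropy.Node, str] = {}
    best: dict[dendropy.Node, tuple] = {}  # (-age, n_unfixed, label, age)
    for node in reversed(internals + [n for n in target.dendropy_tree.leaf_node_iter()]):
        if node.is_leaf():
            min_label[node] = node.taxon.label
            best[node] = (0.0, 0, node.taxon.label, 0.0)
            continue
        min_label[node] = min(min_label[c] for c in node.child_nodes())
        candidates = []
        for child in node.child_nodes():
            if child in fixed:
                candidates.append((-fixed[child], 0, min_label[child], fixed[child]))
            elif child.is_leaf():
                candidates.append((0.0, 0, child.taxon.label, 0.0))
            else:
                neg_age, hops, label, age = best[child]
                candidates.append((neg_age, hops + 1, label, age))
        best[node] = min(candidates)

    ages: dict[dendropy.Node, float] = {}
    for node in internals:
        if node in fixed:
            ages[node] = fixed[node]
            continue
        parent_age = ages[node.parent_node]
        neg_age, hops, _label, d_age = best[node]
        # `hops` = unfixed internal nodes strictly between node and D;
        # node itself is the first of hops+1 evenly spaced nodes
        ages[node] = parent_age - (parent_age - d_age) / (hops + 2)
    for leaf in target.dendropy_tree.leaf_node_iter():
        ages[leaf] = 0.0

    keyed = {target.tip_set(node): age for node, age in ages.items() if not node.is_leaf()}
    return chronogram_from_node_ages(target, keyed)


def external_dater_config(
    target: Tree, cal_set: CalibrationSet, program: str
) -> str:
    """Emit native calibration input for an external dating program
    (format-only adapter; nothing is executed).

    ``treepl``: a smoothing config with one ``mrca``/``min``/``max`` block
    per calibrated node.  ``mrbayes``: a calibration command block fixing
    node ages via ``calibrate`` statements.
    """
    node_names = assign_node_names(target)
    by_name = {name: node for node, name in node_names.items()}
    lines: list[str] = []
    if program == "treepl":
        lines.append("treefile = target.tre")
        lines.append("numsites = 1")
        lines.append("smooth = 100")
        for name, age in sorted(cal_set.ages.items()):
            tips = sorted(target.tip_set(by_name[name]))
            lines.append(f"mrca = {name} " + " ".join(t.replace(" ", "_") for t in tips))
            lines.append(f"min = {name} {age}")
            lines.append(f"max = {name} {age}")
        lines.append("outfile = dated.tre")
    elif program == "mrbayes":
        lines.append("begin mrbayes;")
        for name, age in sorted(cal_set.ages.items()):
            tips = sorted(target.tip_set(by_name[name]))
            taxa = " ".join(t.replace(" ", "_") for t in tips)
            lines.append(f"  constraint {name} = {taxa};")
            lines.append(f"  calibrate {name} = fixed({age});")
        lines.append("end;")
    else:
        raise DatingError(f"unknown external dater {program!r}")
    return "\n".join(lines) + "\n"


@dataclass
class DatingResult:
    """Full provenance bundle of an end-to-end dating run."""

    chronogram: Chronogram
    calibration_table: CalibrationTable
    summaries: list[NodeAgeSummary]
    calibration_set: CalibrationSet
    search_result: SearchResult
    target: Tree
    provenance: dict


def date_topology(
    query: ResolvedQuery,
    db: ChronogramDB,
    target: Optional[Tree] = None,
    method: str = "bladj",
    stat: str = "median",
    root_age: Optional[float] = None,
    rng_seed: Optional[int] = None,
) -> DatingResult:
    """End-to-end convenience: search -> congruify -> summarize -> filter ->
    BLADJ.  ``target`` defaults to the query's own topology."""
    if method != "bladj":
        raise DatingError(f"unsupported dating method {method!r}")
    if target is None:
        target = query.topology
    if target is None:
        raise DatingError("no target topology: provide one or query with a tree")
    result = search(query, db)
    if not result.matches:
        raise DatingError(result.message or "empty search result")
    table = build_calibration_table(target, result)
    if not table.points:
        raise DatingError(table.message or "no congruent calibrations found")
    summaries = summarize_node_ages(table)
    cal_set = filter_calibrations(summaries, target, stat=stat)
    resolve_root_age(cal_set, user_root=root_age, rng_seed=rng_seed)
    chrono = bladj(target, cal_set)
    provenance = {
        "db_version": db.version,
        "taxonomy_version": query.taxonomy_version,
        "summary_stat": stat,
        "method": method,
        "root_age": cal_set.root_age,
        "root_policy": cal_set.root_policy,
        "n_calibration_points": len(table),
        "discarded_calibrations": {
            n: s for n, s in cal_set.provenance.items() if s != USED
        },
    }
    return DatingResult(chrono, table, summaries, cal_set, result, target, provenance)
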