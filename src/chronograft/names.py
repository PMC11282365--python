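"""Taxon-name standardization against a pluggable local taxonomy.

Implements a fully local name-resolution cascade (exact canonical match,
then nomenclatural synonym, then fuzzy edit-distance match) and expansion
of inclusive taxon names (genus, family, ...) to species lists.  No network
services are involved: the taxonomy is a plain table of records with parent
links and synonym lists, so results are reproducible against a pinned
taxonomy version.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import edlib

from .trees import Tree, parse_newick

__all__ = [
    "TaxonRecord",
    "Taxonomy",
    "NameResolution",
    "ResolvedQuery",
    "resolve_names",
    "expand_taxon",
    "make_query",
    "NameError_",
]

#: ranks at or below the species level; subspecific variants are excluded
#: from taxon expansion
SPECIES_RANK = "species"
SUBSPECIFIC_RANKS = frozenset({"subspecies", "variety", "form", "strain"})

#: minimum normalized similarity (1 - edits / max length) for a fuzzy match
FUZZY_THRESHOLD = 0.90


class NameError_(ValueError):
    """Name cannot be resolved / taxonomy is malformed."""


@dataclass(frozen=True)
class TaxonRecord:
    id: int
    name: str
    rank: str
    parent_id: Optional[int]
    synonyms: tuple[str, ...] = ()


class Taxonomy:
    """A local reference taxonomy: records, a name index, and a version tag."""

    def __init__(self, records: Iterable[TaxonRecord], version: str = "unversioned"):
        self.version = version
        self.records: dict[int, TaxonRecord] = {}
        self._canonical: dict[str, int] = {}
        self._synonyms: dict[str, int] = {}
        for rec in records:
            if rec.id in self.records:
                raise NameError_(f"duplicate taxon id {rec.id}")
            if rec.name in self._canonical:
                raise NameError_(f"duplicate canonical name {rec.name!r}")
            self.records[rec.id] = rec
            self._canonical[rec.name] = rec.id
        for rec in self.records.values():
            for syn in rec.synonyms:
                if syn in self._synonyms and self._synonyms[syn] != rec.id:
                    raise NameError_(f"synonym {syn!r} maps to multiple taxa")
                self._synonyms[syn] = rec.id
        self._check_parent_links()

    def _check_parent_links(self) -> None:
        roots = 0
        for rec in self.records.values():
            if rec.parent_id is None:
                roots += 1
                continue
            if rec.parent_id not in self.records:
                raise NameError_(
                    f"record {rec.id} has unknown parent {rec.parent_id}"
                )
            # cycle check by walking up with a visited set
            seen = {rec.id}
            cur = rec.parent_id
            while cur is not None:
                if cur in seen:
                    raise NameError_(f"cycle in parent links at id {cur}")
                seen.add(cur)
                cur = self.records[cur].parent_id
        if roots != 1:
            raise NameError_(f"taxonomy must have exactly one root, found {roots}")

    # -- lookups --------------------------------------------------------

    def get(self, taxon_id: int) -> TaxonRecord:
        return self.records[taxon_id]

    def id_of_canonical(self, name: str) -> Optional[int]:
        return self._canonical.get(name)

    def id_of_synonym(self, name: str) -> Optional[int]:
        return self._synonyms.get(name)

    def canonicalize(self, name: str) -> str:
        """Map a (possibly synonymous) name to its canonical form; unknown
        names pass through unchanged."""
        if name in self._canonical:
            return name
        tid = self._synonyms.get(name)
        return self.records[tid].name if tid is not None else name

    def children_of(self, taxon_id: int) -> list[TaxonRecord]:
        return [r for r in self.records.values() if r.parent_id == taxon_id]

    def lineage_depth(self, taxon_id: int) -> int:
        depth = 0
        cur = self.records[taxon_id]
        while cur.parent_id is not None:
            depth += 1
            cur = self.records[cur.parent_id]
        return depth

    def tree_distance(self, a: int, b: int) -> int:
        """Path length between two records through the parent-link tree."""
        anc_a = {}
        cur, d = self.records[a], 0
        while True:
            anc_a[cur.id] = d
            if cur.parent_id is None:
                break
            cur, d = self.records[cur.parent_id], d + 1
        cur, d = self.records[b], 0
        while cur.id not in anc_a:
            cur, d = self.records[cur.parent_id], d + 1
        return d + anc_a[cur.id]

    def all_names(self) -> list[tuple[str, int, bool]]:
        """(name, id, is_canonical) over canonical names and synonyms."""
        out = [(n, i, True) for n, i in self._canonical.items()]
        out += [(n, i, False) for n, i in self._synonyms.items()]
        return out

    # -- serialization --------------------------------------------------

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Taxonomy":
        """Read the tabular format: a ``#taxonomy-version:`` header line, a
        column header, then ``id<TAB>parent_id<TAB>name<TAB>rank<TAB>synonyms``
        rows with pipe-separated synonyms."""
        lines = Path(path).read_text().splitlines()
        if not lines or not lines[0].startswith("#taxonomy-version:"):
            raise NameError_("taxonomy file must start with '#taxonomy-version:'")
        version = lines[0].split(":", 1)[1].strip()
        records = []
        for line in lines[2:]:  # skip version + column header
            if not line.strip():
                continue
            tid, parent, name, rank, syns = line.split("\t")
            records.append(
                TaxonRecord(
                    id=int(tid),
                    parent_id=None if parent == "" else int(parent),
                    name=name,
                    rank=rank,
                    synonyms=tuple(s for s in syns.split("|") if s),
                )
            )
        return cls(records, version=version)

    def to_tsv(self, path: str | Path) -> None:
        lines = [f"#taxonomy-version: {self.version}"]
        lines.append("id\tparent_id\tname\trank\tsynonyms")
        for rec in sorted(self.records.values(), key=lambda r: r.id):
            parent = "" if rec.parent_id is None else str(rec.parent_id)
            lines.append(
                f"{rec.id}\t{parent}\t{rec.name}\t{rec.rank}\t{'|'.join(rec.synonyms)}"
            )
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class NameResolution:
    input: str
    matched: str
    taxon_id: Optional[int]
    kind: str  # exact | synonym | fuzzy | unmatched


@dataclass
class ResolvedQuery:
    """Standardized query: per-name resolutions plus an optional topology."""

    resolutions: list[NameResolution]
    topology: Optional[Tree] = None
    taxonomy_version: str = "unversioned"

    @property
    def names(self) -> list[str]:
        """Search names, input order preserved: canonical where matched,
        the raw input string otherwise."""
        return [r.matched if r.kind != "unmatched" else r.input for r in self.resolutions]

    @property
    def unmatched(self) -> list[str]:
        return [r.input for r in self.resolutions if r.kind == "unmatched"]

    def to_json(self) -> str:
        return json.dumps(
            {
                "taxonomy_version": self.taxonomy_version,
                "topology": self.topology.write_newick() if self.topology else None,
                "resolutions": [
                    {
                        "input": r.input,
                        "matched": r.matched,
                        "taxon_id": r.taxon_id,
                        "kind": r.kind,
                    }
                    for r in self.resolutions
                ],
            },
            indent=2,
        )


def _similarity(a: str, b: str) -> float:
    dist = edlib.align(a, b)["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


def _genus(name: str) -> str:
    return name.split()[0] if name.split() else name


def _fuzzy_match(
    name: str, taxonomy: Taxonomy, threshold: float
) -> Optional[tuple[str, int]]:
    best: list[tuple[str, int]] = []
    best_sim = threshold
    for cand, tid, _ in taxonomy.all_names():
        sim = _similarity(name, cand)
        if sim > best_sim + 1e-12:
            best, best_sim = [(cand, tid)], sim
        elif abs(sim - best_sim) <= 1e-12 and sim >= threshold:
            best.append((cand, tid))
    if not best:
        return None
    if len(best) > 1:
        # ties: same-genus candidate preferred, then lexicographic
        same_genus = [c for c in best if _genus(c[0]) == _genus(name)]
        pool = same_genus or best
        best = [min(pool, key=lambda c: c[0])]
    cand, tid = best[0]
    canonical = taxonomy.records[tid].name
    return canonical, tid


def resolve_names(
    names: Iterable[str],
    taxonomy: Taxonomy,
    use_tnrs: bool = True,
    fuzzy_threshold: float = FUZZY_THRESHOLD,
) -> ResolvedQuery:
    """Standardize each input name: exact -> synonym -> fuzzy cascade.

    With ``use_tnrs`` off only exact canonical matches are attempted.
    Unmatched names are reported in the result, never fatal.
    """
    names = [n.strip() for n in names]
    names = [n for n in names if n]
    if not names:
        raise NameError_("no taxon names provided")
    resolutions = []
    for name in names:
        tid = taxonomy.id_of_canonical(name)
        if tid is not None:
            resolutions.append(NameResolution(name, name, tid, "exact"))
            continue
        if not use_tnrs:
            resolutions.append(NameResolution(name, name, None, "unmatched"))
            continue
        tid = taxonomy.id_of_synonym(name)
        if tid is not None:
            canonical = taxonomy.records[tid].name
            resolutions.append(NameResolution(name, canonical, tid, "synonym"))
            continue
        hit = _fuzzy_match(name, taxonomy, fuzzy_threshold)
        if hit is not None:
            canonical, tid = hit
            resolutions.append(NameResolution(name, canonical, tid, "fuzzy"))
        else:
            resolutions.append(NameResolution(name, name, None, "unmatched"))
    return ResolvedQuery(resolutions, taxonomy_version=taxonomy.version)


def expand_taxon(
    name: str, taxonomy: Taxonomy, get_species: bool = True
) -> tuple[list[str], Optional[str]]:
    """Expand an inclusive taxon name to its species-rank descendants.

    Returns ``(species_names, notice)``.  Species/subspecific inputs pass
    through as provided.  With ``get_species`` off, inclusive names are
    excluded from the query (empty expansion plus an exclusion notice).
    Subspecific variants are never included in an expansion.
    """
    resolved = resolve_names([name], taxonomy).resolutions[0]
    if resolved.kind == "unmatched":
        raise NameError_(f"cannot resolve taxon name {name!r}")
    record = taxonomy.get(resolved.taxon_id)
    if record.rank == SPECIES_RANK or record.rank in SUBSPECIFIC_RANKS:
        return [record.name], None
    if not get_species:
        return [], (
            f"inclusive taxon {record.name!r} (rank {record.rank}) excluded "
            "from the query; pass get_species to expand it"
        )
    out: list[str] = []
    stack = [record.id]
    while stack:
        current = stack.pop()
        for child in taxonomy.children_of(current):
            if child.rank == SPECIES_RANK:
                out.append(child.name)
                stack.append(child.id)  # species may still nest subspecies
            elif child.rank in SUBSPECIFIC_RANKS:
                continue
            else:
                stack.append(child.id)
    return sorted(set(out)), None


def make_query(
    query: str,
    taxonomy: Taxonomy,
    use_tnrs: bool = True,
    get_species: bool = False,
) -> ResolvedQuery:
    """Build a resolved query from a comma-separated name string or a newick
    tree (tip labels are harvested; the topology is retained)."""
    text = query.strip()
    topology = None
    if text.startswith("("):
        topology = parse_newick(text)  # parse errors propagate
        names = topology.tip_labels
    else:
        names = [part.strip() for part in text.split(",") if part.strip()]
        if not names:
            raise NameError_("query parses as neither a name list nor a tree")
    if get_species:
        expanded: list[str] = []
        for n in names:
            species, _notice = expand_taxon(n, taxonomy, get_species=True)
            expanded.extend(species)
        names = list(dict.fromkeys(expanded))
    result = resolve_names(names, taxonomy, use_tnrs=use_tnrs)
    result.topology = topology
    return result
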