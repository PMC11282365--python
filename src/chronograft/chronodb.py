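"""Versioned local chronogram store and name-based search.

A database is a list of chronogram records, each a published ultrametric
tree (branch lengths in Myr) with its study citation.  On-disk layout is a
directory of one newick file per record plus a ``manifest.json`` carrying
ids, citations and version strings.  Record tip labels are canonicalized
against a taxonomy at load time so that studies published under synonymous
names still match a standardized query.

A search returns, for every record sharing at least two names with the
query, the record pruned to the matched taxa and converted to a patristic
distance matrix (total tip-to-tip time; node ages are half these values).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .names import ResolvedQuery, Taxonomy
from .trees import Chronogram, PatristicMatrix, parse_newick, as_chronogram, patristic_matrix

__all__ = [
    "ChronogramRecord",
    "ChronogramDB",
    "SearchResult",
    "SearchMatch",
    "search",
    "summary_report",
    "load_db",
    "save_db",
    "DBError",
]

NO_DATA_MESSAGE = "no age data found in the chronogram database for the queried taxa"

_CHRONOGRAM_SUFFIX = re.compile(r"\s*-\s*chronogram\s+\d+\s*$")


def study_of(citation: str) -> str:
    """Study identity of a record: its citation minus any trailing
    ``- chronogram N`` marker (studies may publish several chronograms)."""
    return _CHRONOGRAM_SUFFIX.sub("", citation)


class DBError(ValueError):
    """Malformed database archive or record."""


@dataclass
class ChronogramRecord:
    record_id: str
    citation: str
    chronogram: Chronogram

    def __post_init__(self) -> None:
        if not self.citation:
            raise DBError(f"record {self.record_id!r} is missing a citation")
        if self.chronogram.n_tips < 2:
            raise DBError(f"record {self.record_id!r} has fewer than 2 tips")

    @property
    def tip_names(self) -> frozenset[str]:
        return frozenset(self.chronogram.tip_labels)


@dataclass
class ChronogramDB:
    records: list[ChronogramRecord]
    version: str = "unversioned"
    taxonomy_version: str = "unversioned"

    def __post_init__(self) -> None:
        ids = [r.record_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise DBError("duplicate record ids in database")

    def __len__(self) -> int:
        return len(self.records)

    def get(self, record_id: str) -> ChronogramRecord:
        for rec in self.records:
            if rec.record_id == record_id:
                return rec
        raise KeyError(record_id)

    def canonicalized(self, taxonomy: Taxonomy) -> "ChronogramDB":
        """Return a copy with every record's tip labels standardized to the
        taxonomy's canonical names (synonym-bearing studies then match)."""
        recs = []
        for rec in self.records:
            mapping = {l: taxonomy.canonicalize(l) for l in rec.chronogram.tip_labels}
            renamed = rec.chronogram.rename_tips(mapping)
            recs.append(ChronogramRecord(rec.record_id, rec.citation, as_chronogram(renamed)))
        return ChronogramDB(recs, version=self.version, taxonomy_version=taxonomy.version)


@dataclass
class SearchMatch:
    record_id: str
    citation: str
    matrix: PatristicMatrix
    matched_names: tuple[str, ...]

    @property
    def root_age(self) -> float:
        """Age of the root of the pruned source chronogram (max entry / 2)."""
        return self.matrix.max_entry / 2.0


@dataclass
class SearchResult:
    matches: list[SearchMatch]
    query: ResolvedQuery
    db_version: str = "unversioned"
    message: Optional[str] = None

    def __len__(self) -> int:
        return len(self.matches)

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format export: one row per record and taxon pair."""
        rows = []
        for m in self.matches:
            labels = m.matrix.labels
            for i, a in enumerate(labels):
                for b in labels[i + 1 :]:
                    rows.append(
                        {
                            "record_id": m.record_id,
                            "citation": m.citation,
                            "taxon_a": a,
                            "taxon_b": b,
                            "total_distance_myr": m.matrix.entry(a, b),
                        }
                    )
        return pd.DataFrame(
            rows,
            columns=["record_id", "citation", "taxon_a", "taxon_b", "total_distance_myr"],
        )


def search(query: ResolvedQuery, db: ChronogramDB) -> SearchResult:
    """Find records sharing >= 2 names with the query; prune each to the
    matched taxa and store its patristic matrix.  An empty result is valid
    and carries an explicit lack-of-data message."""
    names = set(query.names)
    if not names:
        raise DBError("query has no resolved names")
    matches = []
    for rec in db.records:
        shared = sorted(names & rec.tip_names)
        if len(shared) < 2:
            continue
        pruned = rec.chronogram.prune(shared)
        matches.append(
            SearchMatch(
                record_id=rec.record_id,
                citation=rec.citation,
                matrix=patristic_matrix(as_chronogram(pruned)),
                matched_names=tuple(shared),
            )
        )
    message = NO_DATA_MESSAGE if not matches else None
    return SearchResult(matches, query, db_version=db.version, message=message)


def summary_report(result: SearchResult) -> dict:
    """Per-record root ages and citations, the match report, and the
    record(s) covering the most query names."""
    if not result.matches:
        return {
            "message": result.message or NO_DATA_MESSAGE,
            "db_version": result.db_version,
            "records": [],
            "best_records": [],
        }
    records = [
        {
            "record_id": m.record_id,
            "citation": m.citation,
            "root_age_myr": m.root_age,
            "n_matched": len(m.matched_names),
            "matched_names": list(m.matched_names),
        }
        for m in result.matches
    ]
    best_n = max(r["n_matched"] for r in records)
    return {
        "db_version": result.db_version,
        "taxonomy_version": result.query.taxonomy_version,
        "n_records": len(records),
        "n_studies": len({study_of(r["citation"]) for r in records}),
        "records": records,
        "best_records": [r["record_id"] for r in records if r["n_matched"] == best_n],
        "name_match_report": {
            name: [m.record_id for m in result.matches if name in m.matched_names]
            for name in result.query.names
        },
    }


# ---------------------------------------------------------------------------
# persistence: directory of .nwk files + manifest.json


def save_db(db: ChronogramDB, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {"version": db.version, "taxonomy_version": db.taxonomy_version, "records": []}
    for rec in db.records:
        fname = f"{rec.record_id}.nwk"
        (path / fname).write_text(rec.chronogram.write_newick() + "\n")
        manifest["records"].append(
            {
                "id": rec.record_id,
                "citation": rec.citation,
                "file": fname,
                "n_tips": rec.chronogram.n_tips,
            }
        )
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_db(path: str | Path, taxonomy: Optional[Taxonomy] = None) -> ChronogramDB:
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise DBError(f"no manifest.json under {path}")
    manifest = json.loads(manifest_path.read_text())
    records = []
    for entry in manifest.get("records", []):
        for key in ("id", "citation", "file"):
            if key not in entry or entry[key] in ("", None):
                raise DBError(f"manifest record is missing field {key!r}: {entry}")
        tree = parse_newick((path / entry["file"]).read_text())
        records.append(
            ChronogramRecord(entry["id"], entry["citation"], as_chronogram(tree))
        )
    db = ChronogramDB(
        records,
        version=manifest.get("version", "unversioned"),
        taxonomy_version=manifest.get("taxonomy_version", "unversioned"),
    )
    if taxonomy is not None:
        db = db.canonicalized(taxonomy)
    return db
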