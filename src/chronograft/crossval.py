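"""Leave-one-study-out cross-validation of dated node ages.

For a held-out study, every one of its chronograms is stripped to a bare
topology and re-dated using only age data congruified from the *other*
studies (mean summary ages, conflict-filtered, BLADJ-interpolated).  Each
congruent node then yields a pair (original age, cross-validated age); a
well-populated database should recover the original ages closely, with the
largest scatter around topologically deep nodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chronodb import ChronogramDB, search, study_of
from .congruify import assign_node_names, build_calibration_table
from .dating import DatingError, bladj, filter_calibrations, resolve_root_age
from .names import NameResolution, ResolvedQuery
from .summarize import summarize_node_ages
from .trees import Tree

__all__ = ["CrossValRow", "cross_validate_study", "crossval_report", "CrossValError"]


class CrossValError(ValueError):
    pass


@dataclass(frozen=True)
class CrossValRow:
    study: str  # held-out study citation
    record_id: str  # held-out chronogram
    node: str
    original_age: float
    crossval_age: float
    depth: int  # number of descendant tips of the node


def _query_for(labels: Sequence[str], taxonomy_version: str) -> ResolvedQuery:
    return ResolvedQuery(
        [NameResolution(l, l, None, "exact") for l in labels],
        taxonomy_version=taxonomy_version,
    )


def cross_validate_study(
    db: ChronogramDB, study: str, stat: str = "mean"
) -> list[CrossValRow]:
    """Re-date each chronogram of ``study`` (matched by study name, full
    citation, or record id) from all other studies' age data.

    Exclusion is at study granularity: every chronogram published by the
    held-out study is removed from the calibration pool, so its own ages
    can never leak into its cross-validated estimates.  The
    cross-validation summary statistic is the mean.
    """
    held = [
        r
        for r in db.records
        if study in (r.citation, r.record_id, study_of(r.citation))
    ]
    if not held:
        raise CrossValError(f"study {study!r} not found in database")
    held_studies = {study_of(r.citation) for r in held}
    rest = [r for r in db.records if study_of(r.citation) not in held_studies]
    if not rest:
        raise CrossValError("database holds no other study to calibrate from")
    rest_db = ChronogramDB(rest, version=db.version, taxonomy_version=db.taxonomy_version)

    rows: list[CrossValRow] = []
    for rec in held:
        target = Tree(rec.chronogram.dendropy_tree.clone(depth=1))
        query = _query_for(target.tip_labels, db.taxonomy_version)
        result = search(query, rest_db)
        if not result.matches:
            continue
        table = build_calibration_table(target, result)
        if not table.points:
            continue
        summaries = summarize_node_ages(table)
        try:
            cal_set = filter_calibrations(summaries, target, stat=stat)
            resolve_root_age(cal_set)
            dated = bladj(target, cal_set)
        except DatingError:
            continue
        node_names = assign_node_names(target)
        dated_names = assign_node_names(dated)
        dated_by_name = {name: node for node, name in dated_names.items()}
        calibrated = {s.node for s in summaries}
        for node, name in node_names.items():
            if name not in calibrated:
                continue
            original = rec.chronogram.age_of(
                rec.chronogram.mrca(target.tip_set(node))
            )
            estimated = dated.age_of(dated_by_name[name])
            rows.append(
                CrossValRow(
                    study=rec.citation,
                    record_id=rec.record_id,
                    node=name,
                    original_age=original,
                    crossval_age=estimated,
                    depth=len(target.tip_set(node)),
                )
            )
    if not rows:
        raise CrossValError(
            "held-out study shares too few taxa with the rest of the database"
        )
    return rows


def rows_to_dataframe(rows: Sequence[CrossValRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "study": r.study,
                "record_id": r.record_id,
                "node": r.node,
                "original_age": r.original_age,
                "crossval_age": r.crossval_age,
                "depth": r.depth,
            }
            for r in rows
        ]
    )


def crossval_report(rows: Sequence[CrossValRow]) -> dict:
    """Pearson correlation of original vs cross-validated ages (overall and
    per held-out record) and per-depth-bin mean signed error, to expose any
    systematic under/over-estimation by node depth."""
    if len(rows) < 3:
        raise CrossValError("need at least 3 rows to summarize")
    df = rows_to_dataframe(rows)

    def corr(frame: pd.DataFrame) -> Optional[float]:
        x, y = frame["original_age"].to_numpy(), frame["crossval_age"].to_numpy()
        if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
            return None  # undefined for degenerate (constant) columns
        return float(np.corrcoef(x, y)[0, 1])

    per_record = {
        rid: corr(group) for rid, group in df.groupby("record_id", sort=True)
    }
    df = df.assign(signed_error=df["crossval_age"] - df["original_age"])
    bins = [0, 2, 4, 8, 16, 32, np.inf]
    df = df.assign(
        depth_bin=pd.cut(df["depth"], bins=bins).astype(str)
    )
    by_depth = {
        str(b): float(g["signed_error"].mean())
        for b, g in df.groupby("depth_bin", sort=True)
        if len(g)
    }
    return {
        "n_rows": int(len(df)),
        "overall_correlation": corr(df),
        "per_record_correlation": per_record,
        "mean_signed_error_by_depth": by_depth,
    }
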