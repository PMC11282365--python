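"""Summaries of congruified age data.

Two complementary summaries are provided:

* per-node summary statistics over calibration ages (min, quartiles, median,
  mean, max, sample variance and SD), the table consumed by the conflict
  filter and the dating step; and
* pairwise summary matrices over a collection of patristic matrices, either
  cellwise classic statistics or the super-distance-method (SDM) summary,
  which rescales each matrix by a positive factor chosen to minimize the
  between-matrix variance of shared cells (subject to the factors averaging
  to one) before taking the cellwise mean.

Quantiles use linear interpolation at ``h = (n - 1) p + 1`` (numpy/R type-7)
and the variance uses the sample (n - 1) denominator.  Cells with no data
stay missing (NaN); no imputation is performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .trees import PatristicMatrix
from .congruify import CalibrationTable

__all__ = [
    "NodeAgeSummary",
    "SummaryMatrix",
    "summarize_node_ages",
    "summaries_to_dataframe",
    "summary_matrix",
    "sdm_summary",
    "sdm_scale_factors",
    "SummaryError",
]

#: convergence tolerance for the SDM scale factors
SDM_RTOL = 1e-8


class SummaryError(ValueError):
    pass


@dataclass(frozen=True)
class NodeAgeSummary:
    node: str
    n: int
    min: float
    q1: float
    median: float
    mean: float
    q3: float
    max: float
    variance: float  # NaN when n == 1
    sd: float  # NaN when n == 1


def _summary_of(node: str, ages: Sequence[float]) -> NodeAgeSummary:
    a = np.asarray(sorted(ages), dtype=float)
    n = a.size
    variance = float(np.var(a, ddof=1)) if n > 1 else float("nan")
    return NodeAgeSummary(
        node=node,
        n=int(n),
        min=float(a.min()),
        q1=float(np.percentile(a, 25)),
        median=float(np.percentile(a, 50)),
        mean=float(a.mean()),
        q3=float(np.percentile(a, 75)),
        max=float(a.max()),
        variance=variance,
        sd=float(np.sqrt(variance)),
    )


def summarize_node_ages(table: CalibrationTable) -> list[NodeAgeSummary]:
    """Per-node summary statistics over a calibration table's ages."""
    by_node = table.ages_by_node()
    if not by_node:
        raise SummaryError("calibration table is empty")
    order = sorted(by_node, key=lambda name: int(name.lstrip("n")))
    return [_summary_of(node, by_node[node]) for node in order]


def summaries_to_dataframe(summaries: Iterable[NodeAgeSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "node_name": s.node,
                "n": s.n,
                "min_age": s.min,
                "q1": s.q1,
                "median_age": s.median,
                "mean_age": s.mean,
                "q3": s.q3,
                "max_age": s.max,
                "variance": s.variance,
                "sd": s.sd,
            }
            for s in summaries
        ]
    )


@dataclass(frozen=True)
class SummaryMatrix:
    """A single pairwise total-distance matrix summarizing several sources."""

    labels: tuple[str, ...]
    values: np.ndarray
    method: str  # mean | median | min | max | sdm

    def entry(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path: str | Path) -> None:
        self.as_dataframe().to_csv(path)


def _stack(matrices: Sequence[PatristicMatrix]) -> tuple[tuple[str, ...], np.ndarray]:
    """Align matrices on the union of tips; absent cells are NaN.
    Returns (labels, array of shape (n_matrices, n_tips, n_tips))."""
    labels = tuple(sorted(set().union(*(set(m.labels) for m in matrices))))
    index = {l: i for i, l in enumerate(labels)}
    n = len(labels)
    out = np.full((len(matrices), n, n), np.nan)
    for k, m in enumerate(matrices):
        rows = [index[l] for l in m.labels]
        out[np.ix_([k], rows, rows)] = m.values
    return labels, out


def summary_matrix(
    matrices: Sequence[PatristicMatrix], stat: str = "median"
) -> SummaryMatrix:
    """Cellwise classic summary over matrices containing both tips."""
    if not matrices:
        raise SummaryError("need at least one matrix to summarize")
    if stat not in {"mean", "median", "min", "max"}:
        raise SummaryError(f"unknown summary statistic {stat!r}")
    labels, stack = _stack(matrices)
    func = {
        "mean": np.nanmean,
        "median": np.nanmedian,
        "min": np.nanmin,
        "max": np.nanmax,
    }[stat]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        values = func(stack, axis=0)
    np.fill_diagonal(values, 0.0)
    return SummaryMatrix(labels, values, stat)


def sdm_scale_factors(matrices: Sequence[PatristicMatrix]) -> np.ndarray:
    """Positive per-matrix scale factors minimizing the summed squared
    deviation of scaled shared cells from their cellwise mean, subject to
    the factors summing to the number of matrices.

    The objective is quadratic in the factors, so the constrained minimum is
    the solution of a (Lagrangian) linear system; degenerate systems (e.g.
    identical matrices, where any common factor works) fall back to the
    least-squares solution, which keeps all factors equal.
    """
    P = len(matrices)
    if P < 2:
        raise SummaryError("SDM needs at least 2 matrices")
    labels, stack = _stack(matrices)
    n = len(labels)
    # quadratic form A: sum over upper-triangle cells with >= 2 observations
    A = np.zeros((P, P))
    for i in range(n):
        for j in range(i + 1, n):
            obs = np.where(~np.isnan(stack[:, i, j]))[0]
            if obs.size < 2:
                continue
            dvec = stack[obs, i, j]
            m = obs.size
            # sum_p (x_p - mean(x))^2 with x_p = alpha_p d_p
            block = np.diag(dvec**2) - np.outer(dvec, dvec) / m
            A[np.ix_(obs, obs)] += block
    kkt = np.zeros((P + 1, P + 1))
    kkt[:P, :P] = 2 * A
    kkt[:P, P] = 1.0
    kkt[P, :P] = 1.0
    rhs = np.zeros(P + 1)
    rhs[P] = float(P)
    sol, *_ = np.linalg.lstsq(kkt, rhs, rcond=None)
    alpha = sol[:P]
    if np.any(alpha <= 0):
        raise SummaryError(
            "SDM produced a non-positive scale factor; the matrices are too "
            "discordant to deform by scaling"
        )
    return alpha


def sdm_objective(matrices: Sequence[PatristicMatrix], alpha: np.ndarray) -> float:
    """Summed squared deviation of scaled shared cells from their mean."""
    _, stack = _stack(matrices)
    scaled = stack * np.asarray(alpha)[:, None, None]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(scaled, axis=0)
    dev = scaled - mu[None, :, :]
    counts = np.sum(~np.isnan(stack), axis=0)
    dev[:, counts < 2] = np.nan
    iu = np.triu_indices(stack.shape[1], k=1)
    return float(np.nansum(dev[:, iu[0], iu[1]] ** 2))


def sdm_summary(matrices: Sequence[PatristicMatrix]) -> SummaryMatrix:
    """Variance-minimizing SDM summary: rescale, then cellwise mean.

    The matrices must form a single grove (every pair connected through
    >= 2 shared taxa), otherwise a single common time scale cannot be
    established and the summary fails.
    """
    from .groves import find_groves  # local import to avoid a cycle

    tip_sets = [set(m.labels) for m in matrices]
    groves = find_groves(tip_sets, n=2)
    if len(groves) > 1:
        raise SummaryError(
            "source matrices do not form a grove (insufficient taxon "
            "overlap); run grove detection and summarize one grove at a time"
        )
    alpha = sdm_scale_factors(matrices)
    labels, stack = _stack(matrices)
    scaled = stack * alpha[:, None, None]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        values = np.nanmean(scaled, axis=0)
    np.fill_diagonal(values, 0.0)
    return SummaryMatrix(labels, values, "sdm")
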