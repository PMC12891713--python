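"""Strict Pareto dominance and non-dominated set extraction.

The feasible set is a finite list of treatments scored on a handful of
objectives (here typically quality score, yield, and water productivity, all
to be maximized). Treatment a dominates b when a is at least as good in every
objective and strictly better in at least one; the Pareto frontier P* is the
set of treatments dominated by none. Dominance is checked by an O(n^2)
all-pairs scan — exact, order-independent, and entirely adequate for the
dozens of candidates a trial produces.

Minimize-sense objectives are handled by negation before comparison, so the
frontier is invariant under any strictly increasing per-column transform,
including the 0-100 min-max normalization used for reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DomainError, FixtureLookupError, ValidationError

logger = logging.getLogger(__name__)

SENSES = ("maximize", "minimize")


@dataclass
class ObjectiveMatrix:
    """Treatments x objectives table with a direction per objective.

    ``values`` holds raw objective values (rows: treatment labels). ``senses``
    maps each column to 'maximize' or 'minimize' (default maximize).
    ``normalized`` is filled by :func:`minmax_normalize`.
    """

    values: pd.DataFrame
    senses: Mapping[str, str] = field(default_factory=dict)
    normalized: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValidationError("objective matrix contains missing values")
        senses = {c: self.senses.get(c, "maximize") for c in self.values.columns}
        bad = {c: s for c, s in senses.items() if s not in SENSES}
        if bad:
            raise ValidationError(f"unknown sense(s): {bad}")
        self.senses = senses

    def oriented(self) -> np.ndarray:
        """Values with minimize-sense columns negated (all maximize-sense)."""
        arr = self.values.to_numpy(dtype=float).copy()
        for j, c in enumerate(self.values.columns):
            if self.senses[c] == "minimize":
                arr[:, j] = -arr[:, j]
        return arr


@dataclass(frozen=True)
class ParetoResult:
    """Frontier membership plus per-row dominance bookkeeping."""

    frontier_indices: tuple  # row labels of P*, in input order
    dominance_count: pd.Series  # rows dominating each row
    dominated_by: Mapping  # row label -> tuple of dominating row labels

    def is_on_frontier(self, label) -> bool:
        return label in set(self.frontier_indices)


def dominates(a: Sequence[float], b: Sequence[float]) -> bool:
    """Strict Pareto dominance of a over b (both all maximize-sense)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError(f"objective vectors must match in length, got {a.shape} vs {b.shape}")
    return bool(np.all(a >= b) and np.any(a > b))


def minmax_normalize(matrix: ObjectiveMatrix) -> ObjectiveMatrix:
    """Fill ``normalized`` with per-column 0-100 min-max scores.

    Minimize-sense columns are negated first, so 100 is always "best". A
    degenerate column (max equals min) normalizes to all zeros with a logged
    warning.
    """
    if len(matrix.values) == 0:
        raise DomainError("objective matrix has no rows")
    arr = matrix.oriented()
    lo = arr.min(axis=0)
    hi = arr.max(axis=0)
    span = hi - lo
    out = np.zeros_like(arr)
    for j, col in enumerate(matrix.values.columns):
        if span[j] == 0:
            logger.warning("objective %r is constant; normalized scores set to 0", col)
        else:
            out[:, j] = (arr[:, j] - lo[j]) / span[j] * 100.0
    matrix.normalized = pd.DataFrame(
        out, index=matrix.values.index, columns=matrix.values.columns
    )
    return matrix


def pareto_front(matrix: ObjectiveMatrix) -> ParetoResult:
    """Non-dominated rows of the matrix (all-pairs scan, input row order)."""
    n = len(matrix.values)
    if n == 0:
        raise DomainError("objective matrix has no rows")
    arr = matrix.oriented()
    labels = list(matrix.values.index)
    dominated_by: dict = {lab: [] for lab in labels}
    for i in range(n):
        for j in range(n):
            if i != j and dominates(arr[j], arr[i]):
                dominated_by[labels[i]].append(labels[j])
    frontier = tuple(lab for lab in labels if not dominated_by[lab])
    counts = pd.Series(
        {lab: len(doms) for lab, doms in dominated_by.items()}, name="dominated_by_count"
    )
    return ParetoResult(
        frontier_indices=frontier,
        dominance_count=counts,
        dominated_by={lab: tuple(v) for lab, v in dominated_by.items()},
    )


def group_frontiers(matrix: ObjectiveMatrix, groups: Mapping) -> dict:
    """Pareto frontier within each group of rows (e.g. per cultivar).

    ``groups`` maps each row label to a group key; returns group -> frontier
    labels. A strategy can be group-optimal yet globally dominated.
    """
    out: dict = {}
    for key in dict.fromkeys(groups.values()):
        labels = [lab for lab in matrix.values.index if groups[lab] == key]
        sub = ObjectiveMatrix(values=matrix.values.loc[labels], senses=dict(matrix.senses))
        out[key] = pareto_front(sub).frontier_indices
    return out


def frontier_projection(
    matrix: ObjectiveMatrix, result: ParetoResult, axes: tuple[str, str]
) -> pd.DataFrame:
    """2-D projection of the candidate set with frontier-membership flags."""
    for ax in axes:
        if ax not in matrix.values.columns:
            raise FixtureLookupError(f"unknown objective {ax!r}")
    frontier = set(result.frontier_indices)
    out = matrix.values.loc[:, list(axes)].copy()
    out["on_frontier"] = [lab in frontier for lab in matrix.values.index]
    return out
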