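"""Sensitivity / specificity / accuracy of HRM haplotype discrimination.

Replicates of sequenced haplotypes are amplified many times and clustered
from their melt curves; discrimination is then scored per haplotype from the
replicate-by-cluster count matrix.  Each haplotype's *modal* cluster (the
cluster holding most of its replicates; ties resolve to the lowest cluster
label) plays the role of its positive call:

    TP  replicates of the focal haplotype in its modal cluster
    FN  its remaining replicates
    FP  other haplotypes' replicates in that modal cluster
    TN  other haplotypes' remaining replicates

    sensitivity = TP / (TP + FN)        (true positive rate)
    specificity = TN / (TN + FP)        (true negative rate)
    accuracy    = (TP + TN) / (TP + FP + TN + FN)

Two haplotypes may share a modal cluster; that is exactly the
specificity-below-100% case.  A haplotype's declared replicate total ``n``
is treated as authoritative when it disagrees with the sum of its cluster
cells (the discrepancy is flagged on the summary).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd

from .melt_clustering import ClusterAssignment

__all__ = [
    "ConfusionCounts",
    "ConfusionSummary",
    "ReplicateMatrix",
    "confusion_from_matrix",
    "score_discrimination",
    "evaluate_run",
]


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    fp: int
    tn: int
    modal_cluster: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class ConfusionSummary:
    """Per-haplotype discrimination metrics, exact and rounded.

    Percentages are kept as exact rationals (``*_exact``) alongside
    round-half-up integers matching the conventional reporting style.
    """

    haplotype: str
    n: int
    counts: ConfusionCounts
    n_discrepant: bool = False

    @property
    def sensitivity_exact(self) -> Fraction:
        return Fraction(100 * self.counts.tp, self.counts.tp + self.counts.fn)

    @property
    def specificity_exact(self) -> Fraction:
        return Fraction(100 * self.counts.tn, self.counts.tn + self.counts.fp)

    @property
    def accuracy_exact(self) -> Fraction:
        return Fraction(100 * (self.counts.tp + self.counts.tn), self.counts.total)

    @property
    def sensitivity(self) -> int:
        return _round_half_up(float(self.sensitivity_exact))

    @property
    def specificity(self) -> int:
        return _round_half_up(float(self.specificity_exact))

    @property
    def accuracy(self) -> int:
        return _round_half_up(float(self.accuracy_exact))


class ReplicateMatrix:
    """Haplotype-by-cluster replicate counts for one primer pair.

    Rows are haplotypes, columns cluster labels (1..k).  ``n`` gives the
    declared number of successfully amplified replicates per haplotype,
    defaulting to the row sums.
    """

    def __init__(
        self,
        counts: Mapping[str, Mapping[int, int]] | pd.DataFrame,
        n: Mapping[str, int] | None = None,
        name: str = "",
    ) -> None:
        if isinstance(counts, pd.DataFrame):
            df = counts.astype(int)
        else:
            df = pd.DataFrame(counts).T.fillna(0).astype(int)
        if df.empty:
            raise ValueError("replicate matrix must be non-empty")
        if (df.values < 0).any():
            raise ValueError("replicate counts must be non-negative")
        df = df.reindex(sorted(df.columns), axis=1)
        self.table = df
        self.name = name
        row_sums = df.sum(axis=1)
        self.n = {h: int((n or {}).get(h, row_sums[h])) for h in df.index}

    @property
    def haplotypes(self) -> list[str]:
        return list(self.table.index)

    @property
    def clusters(self) -> list[int]:
        return list(self.table.columns)

    def count(self, haplotype: str, cluster: int) -> int:
        return int(self.table.loc[haplotype].get(cluster, 0))

    @classmethod
    def from_assignment(
        cls,
        assignment: ClusterAssignment,
        truth: Mapping[Hashable, str],
        name: str = "",
    ) -> "ReplicateMatrix":
        missing = [w for w in assignment.labels if w not in truth]
        if missing:
            raise ValueError(
                f"no truth haplotype for clustered wells: {sorted(map(str, missing))[:5]}"
            )
        cells: dict[str, dict[int, int]] = {}
        for well, lab in assignment.labels.items():
            hap = truth[well]
            cells.setdefault(hap, {})
            cells[hap][lab] = cells[hap].get(lab, 0) + 1
        return cls(cells, name=name)

    def to_frame(self) -> pd.DataFrame:
        """Serializable layout: one haplotype row, N then cluster columns."""
        df = self.table.copy()
        df.insert(0, "N", [self.n[h] for h in df.index])
        return df


def confusion_from_matrix(matrix: ReplicateMatrix, haplotype: str) -> ConfusionCounts:
    """Modal-cluster confusion counts for one haplotype."""
    if haplotype not in matrix.table.index:
        raise KeyError(f"haplotype {haplotype!r} not in matrix")
    row = matrix.table.loc[haplotype]
    if int(row.sum()) == 0:
        raise ValueError(f"haplotype {haplotype!r} has no passed replicates")
    modal = int(row.index[int(np.argmax(row.values))])  # ties -> lowest label
    tp = int(row[modal])
    fn = matrix.n[haplotype] - tp
    others = [h for h in matrix.haplotypes if h != haplotype]
    fp = int(sum(matrix.count(h, modal) for h in others))
    tn = int(sum(matrix.n[h] for h in others)) - fp
    return ConfusionCounts(tp=tp, fn=fn, fp=fp, tn=tn, modal_cluster=modal)


def score_discrimination(matrix: ReplicateMatrix) -> list[ConfusionSummary]:
    """Score every haplotype of a replicate matrix.

    Requires at least two haplotypes so specificity has a denominator.
    """
    if len(matrix.haplotypes) < 2:
        raise ValueError("need >= 2 haplotypes for meaningful specificity")
    out = []
    for hap in matrix.haplotypes:
        counts = confusion_from_matrix(matrix, hap)
        discrepant = matrix.n[hap] != int(matrix.table.loc[hap].sum())
        out.append(
            ConfusionSummary(haplotype=hap, n=matrix.n[hap], counts=counts, n_discrepant=discrepant)
        )
    return out


def evaluate_run(
    assignment: ClusterAssignment,
    truth: Mapping[Hashable, str],
    name: str = "",
) -> tuple[ReplicateMatrix, list[ConfusionSummary]]:
    """Build the replicate matrix from a live clustering and score it."""
    matrix = ReplicateMatrix.from_assignment(assignment, truth, name=name)
    return matrix, score_discrimination(matrix)


def summaries_to_frame(summaries: Sequence[ConfusionSummary]) -> pd.DataFrame:
    """Tabular summary with exact and integer-rounded percentages."""
    return pd.DataFrame(
        {
            "haplotype": [s.haplotype for s in summaries],
            "n": [s.n for s in summaries],
            "sensitivity": [s.sensitivity for s in summaries],
            "specificity": [s.specificity for s in summaries],
            "accuracy": [s.accuracy for s in summaries],
            "sensitivity_exact": [float(s.sensitivity_exact) for s in summaries],
            "specificity_exact": [float(s.specificity_exact) for s in summaries],
            "accuracy_exact": [float(s.accuracy_exact) for s in summaries],
            "n_discrepant": [s.n_discrepant for s in summaries],
        }
    )
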