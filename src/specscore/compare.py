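"""Hypnogram agreement statistics.

Two hypnograms on the same epoch grid are cross-tabulated into a 5 x 5
confusion matrix (rows = reference stages, e.g. visual wake/N1/N2/N3/REM;
columns = spectral stages).  The matrix is read in both directions by
converting counts to percentages along rows and along columns, and
per-subject percentage matrices are pooled with cell-wise medians (plus
quartiles for box plots).  When one subject contributes matrices from two
channels, their epoch counts are averaged cell-wise before percentising.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hypnogram import Hypnogram
from .stages import SPECTRAL_STAGES, VISUAL_STAGES

__all__ = [
    "ConfusionMatrix",
    "confusion",
    "percentize",
    "pool_medians",
    "average_counts",
    "stage_durations",
]


@dataclass
class ConfusionMatrix:
    counts: np.ndarray        # (n_ref, n_test) non-negative
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape must match labels")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.row_labels), columns=list(self.col_labels)
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def _vocabulary(stages: list[str]) -> tuple[str, ...]:
    present = set(stages)
    if present <= set(VISUAL_STAGES) and not present <= set(SPECTRAL_STAGES):
        return VISUAL_STAGES
    return SPECTRAL_STAGES


def confusion(ref: Hypnogram, test: Hypnogram) -> ConfusionMatrix:
    """Tally aligned epoch pairs; the shorter hypnogram truncates the longer."""
    if ref.epoch_len != test.epoch_len:
        raise ValueError(
            f"epoch lengths differ: {ref.epoch_len} vs {test.epoch_len} s"
        )
    n = min(ref.n_epochs, test.n_epochs)
    rows = _vocabulary(ref.stages)
    cols = _vocabulary(test.stages)
    r_idx = {s: i for i, s in enumerate(rows)}
    c_idx = {s: i for i, s in enumerate(cols)}
    counts = np.zeros((len(rows), len(cols)))
    for rs, ts in zip(ref.stages[:n], test.stages[:n]):
        counts[r_idx[rs], c_idx[ts]] += 1
    return ConfusionMatrix(counts=counts, row_labels=rows, col_labels=cols)


def percentize(cm: ConfusionMatrix, direction: str = "rows") -> pd.DataFrame:
    """Convert counts to percentages along rows or columns.

    Each row (or column) sums to 100; a row (column) with zero epochs is
    undefined and reported as NaN.
    """
    frame = cm.to_frame()
    if direction == "rows":
        sums = frame.sum(axis=1)
        out = frame.div(sums.replace(0, np.nan), axis=0) * 100.0
    elif direction == "columns":
        sums = frame.sum(axis=0)
        out = frame.div(sums.replace(0, np.nan), axis=1) * 100.0
    else:
        raise ValueError("direction must be 'rows' or 'columns'")
    return out


def pool_medians(
    per_subject: list[pd.DataFrame], quartiles: bool = False
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Cell-wise median across subjects, ignoring absent (NaN) cells.

    With ``quartiles=True`` also returns the cell-wise 25th and 75th
    percentiles (the box edges of range plots).
    """
    if not per_subject:
        raise ValueError("need at least one matrix to pool")
    first = per_subject[0]
    for m in per_subject[1:]:
        if not (m.index.equals(first.index) and m.columns.equals(first.columns)):
            raise ValueError("all matrices must share row/column labels")
    stack = np.stack([m.to_numpy(dtype=float) for m in per_subject])
    with np.errstate(all="ignore"):
        med = np.nanmedian(stack, axis=0)
    med_df = pd.DataFrame(med, index=first.index, columns=first.columns)
    if not quartiles:
        return med_df
    with np.errstate(all="ignore"):
        q1 = np.nanpercentile(stack, 25, axis=0)
        q3 = np.nanpercentile(stack, 75, axis=0)
    return (
        med_df,
        pd.DataFrame(q1, index=first.index, columns=first.columns),
        pd.DataFrame(q3, index=first.index, columns=first.columns),
    )


def average_counts(cms: list[ConfusionMatrix]) -> ConfusionMatrix:
    """Cell-wise mean of epoch counts (e.g. pooling the two forehead channels)."""
    if not cms:
        raise ValueError("need at least one matrix")
    first = cms[0]
    for cm in cms[1:]:
        if cm.row_labels != first.row_labels or cm.col_labels != first.col_labels:
            raise ValueError("all matrices must share labels")
    mean = np.mean([cm.counts for cm in cms], axis=0)
    return ConfusionMatrix(
        counts=mean, row_labels=first.row_labels, col_labels=first.col_labels
    )


def stage_durations(hyp: Hypnogram) -> dict[str, float]:
    """Hours spent in each stage: count(stage) * epoch_len / 3600."""
    vocab = _vocabulary(hyp.stages)
    arr = np.asarray(hyp.stages)
    return {s: float((arr == s).sum() * hyp.epoch_len / 3600.0) for s in vocab}
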