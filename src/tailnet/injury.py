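"""Tail-injury scoring: maximal tail score, victimization, class tables.

Tail damage is scored on an ordinal 0-4 scale (0 = no observable damage,
1 = healed lesions or minor scabs, 2 = chewing/puncture wounds with
blood, 3 = wounds with signs of infection, 4 = partial or complete loss
of the tail).  A pig's **maximal tail score (MTS)** is the highest score
it received at any assessment over the study; pigs with MTS >= 2 are
classed as victims of tail biting.  For group comparisons pigs are
binned into MTS classes {0, 1, >=2} and the treatment x class contingency
table is tested with Pearson's chi-square.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import TailScoreRecord, ValidationError

__all__ = [
    "MTSRecord",
    "ContingencyTable",
    "max_tail_score",
    "classify_victim",
    "mts_class",
    "mts_records",
    "class_table",
    "pearson_chi_square",
    "median_iqr",
]

VICTIM_THRESHOLD = 2
CLASS_LABELS = ("0", "1", ">=2")


@dataclass(frozen=True)
class MTSRecord:
    """Per-pig maximal tail score with its class and victim flag."""

    pig_id: str
    mts: int
    mts_class: str
    victim: bool

    def __post_init__(self) -> None:
        if self.mts not in (0, 1, 2, 3, 4):
            raise ValidationError(f"MTS must be in 0..4, got {self.mts}")
        if self.victim != (self.mts >= VICTIM_THRESHOLD):
            raise ValidationError("victim flag inconsistent with MTS >= 2 rule")
        if self.mts_class != mts_class(self.mts):
            raise ValidationError("mts_class inconsistent with mts")


@dataclass(frozen=True)
class ContingencyTable:
    """Treatment x MTS-class counts."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValidationError("counts shape inconsistent with labels")
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            raise ValidationError("counts must be non-negative integers")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.row_labels), columns=list(self.col_labels)
        )


def max_tail_score(records: Iterable[TailScoreRecord | int]) -> int:
    """Greatest score a pig received at any assessment."""
    scores = [r.score if isinstance(r, TailScoreRecord) else int(r) for r in records]
    if not scores:
        raise ValidationError("cannot take the maximal tail score of no assessments")
    for s in scores:
        if s not in (0, 1, 2, 3, 4):
            raise ValidationError(f"score {s} outside the 0-4 scale")
    return max(scores)


def classify_victim(mts: int) -> bool:
    """Victim of tail biting iff MTS >= 2."""
    if mts not in (0, 1, 2, 3, 4):
        raise ValidationError(f"MTS must be in 0..4, got {mts}")
    return mts >= VICTIM_THRESHOLD


def mts_class(mts: int) -> str:
    """Bin an MTS into the classes {0, 1, >=2}."""
    if mts not in (0, 1, 2, 3, 4):
        raise ValidationError(f"MTS must be in 0..4, got {mts}")
    return CLASS_LABELS[min(mts, 2)]


def mts_records(score_records: Iterable[TailScoreRecord]) -> list[MTSRecord]:
    """Per-pig MTS records from the long score table."""
    by_pig: dict[str, list[TailScoreRecord]] = {}
    for r in score_records:
        by_pig.setdefault(r.pig_id, []).append(r)
    out = []
    for pig_id in sorted(by_pig):
        mts = max_tail_score(by_pig[pig_id])
        out.append(
            MTSRecord(
                pig_id=pig_id,
                mts=mts,
                mts_class=mts_class(mts),
                victim=classify_victim(mts),
            )
        )
    return out


def class_table(
    records: Sequence[MTSRecord],
    treatments: Mapping[str, str],
    treatment_order: Sequence[str] | None = None,
) -> ContingencyTable:
    """Treatment x MTS-class contingency table.

    ``treatments`` maps pig_id -> treatment label; a scored pig without a
    treatment raises.
    """
    if treatment_order is None:
        treatment_order = sorted(set(treatments.values()))
    rows = {t: i for i, t in enumerate(treatment_order)}
    cols = {c: j for j, c in enumerate(CLASS_LABELS)}
    counts = np.zeros((len(rows), len(cols)), dtype=int)
    for r in records:
        if r.pig_id not in treatments:
            raise ValidationError(f"pig {r.pig_id} has no treatment assignment")
        counts[rows[treatments[r.pig_id]], cols[r.mts_class]] += 1
    return ContingencyTable(tuple(treatment_order), CLASS_LABELS, counts)


def pearson_chi_square(table: ContingencyTable) -> tuple[float, int, float]:
    """Pearson chi-square of independence on a contingency table.

    Returns (statistic, df, p).  Expected counts come from the row and
    column margins; a zero margin makes them degenerate and raises.
    """
    O = np.asarray(table.counts, dtype=float)
    row = O.sum(axis=1)
    col = O.sum(axis=0)
    total = O.sum()
    if np.any(row == 0) or np.any(col == 0) or total == 0:
        raise ValidationError("zero row/column margin: expected counts undefined")
    E = np.outer(row, col) / total
    statistic = float(np.sum((O - E) ** 2 / E))
    df = (O.shape[0] - 1) * (O.shape[1] - 1)
    p = float(stats.chi2.sf(statistic, df))
    return statistic, df, p


def median_iqr(values: Sequence[float]) -> tuple[float, float, float]:
    """Median and quartiles (Q1, Q3) by linear interpolation.

    Quartiles interpolate between order statistics at positions
    0.25(n-1)+1 and 0.75(n-1)+1 (the same convention as
    ``numpy.percentile(..., method="linear")``).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValidationError("median of an empty collection is undefined")
    med, q1, q3 = np.percentile(v, [50, 25, 75], method="linear")
    return float(med), float(q1), float(q3)
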