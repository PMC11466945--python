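"""Behavioral data model and I/O.

Observations arrive as long-format CSV tables produced either by human
scan-sampling of video recordings or by :mod:`tailnet.simulate`:

* **scans** — one row per pig per scan instant: whether the pig was lying
  and which pen-mates it was lying together with (bodily contact).
* **bites** — one row per tail-biting event: initiator, recipient, and the
  time (minutes) into the 6-h observation window.
* **tail scores** — one row per pig per assessment on the 0-4 injury scale.

The central derived object is :class:`LyingAggregate`: per pen and
observation period, the symmetric count matrix ``x[a, b]`` of scans in
which pigs *a* and *b* lay together, and the vector ``n[a]`` of scans in
which pig *a* lay at all.  These are exactly the quantities the half-weight
association index consumes.

Pig order within every matrix is lexicographic by ``pig_id`` and fixed
across scans and periods, so matrix layouts are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScanRecord",
    "BiteEvent",
    "TailScoreRecord",
    "LyingAggregate",
    "ValidationError",
    "read_scans",
    "write_scans",
    "read_bites",
    "write_bites",
    "read_tail_scores",
    "write_tail_scores",
    "build_scan_matrices",
    "aggregate_scans",
    "lying_time_budget",
    "write_matrix_csv",
    "read_matrix_csv",
]

SCAN_COLUMNS = ["pen_id", "period", "scan_index", "pig_id", "lying", "partners"]
BITE_COLUMNS = ["pen_id", "period", "timestamp_min", "biter", "recipient"]
SCORE_COLUMNS = ["pig_id", "assessment_index", "score"]


class ValidationError(ValueError):
    """Raised when a table violates a structural invariant."""


@dataclass(frozen=True)
class ScanRecord:
    """One pig's lying state at one scan instant.

    ``partners`` is the set of pen-mates the pig was lying together with
    (parallel/inverse-parallel, >50 % body contact).  A nonempty partner
    set implies ``lying == 1``, and partnership is symmetric across the
    records of the same scan.
    """

    pen_id: str
    period: int
    scan_index: int
    pig_id: str
    lying: int
    partners: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.lying not in (0, 1):
            raise ValidationError(f"lying must be 0/1, got {self.lying!r}")
        if self.pig_id in self.partners:
            raise ValidationError(f"pig {self.pig_id} listed as its own partner")
        if self.partners and self.lying != 1:
            raise ValidationError(
                f"pig {self.pig_id} has partners {sorted(self.partners)} but lying=0"
            )
        if self.scan_index < 1:
            raise ValidationError("scan_index is 1-based and must be >= 1")


@dataclass(frozen=True)
class BiteEvent:
    """A directed tail-biting event: ``biter`` bit ``recipient``."""

    pen_id: str
    period: int
    timestamp_min: float
    biter: str
    recipient: str

    def __post_init__(self) -> None:
        if self.biter == self.recipient:
            raise ValidationError(f"pig {self.biter} cannot bite itself")


@dataclass(frozen=True)
class TailScoreRecord:
    """One tail-injury assessment for one pig, on the 0-4 scale."""

    pig_id: str
    assessment_index: int
    score: int

    def __post_init__(self) -> None:
        if self.score not in (0, 1, 2, 3, 4):
            raise ValidationError(f"score must be in 0..4, got {self.score!r}")


@dataclass(frozen=True)
class LyingAggregate:
    """Per pen-period aggregate of the scan-level lying matrices.

    ``x[a, b]`` counts scans in which pigs ``nodes[a]`` and ``nodes[b]``
    lay together; ``n[a]`` counts scans in which ``nodes[a]`` lay.
    """

    pen_id: str
    period: int
    nodes: tuple[str, ...]
    x: np.ndarray
    n: np.ndarray
    scans_total: int

    def __post_init__(self) -> None:
        x = np.asarray(self.x)
        n = np.asarray(self.n)
        k = len(self.nodes)
        if x.shape != (k, k) or n.shape != (k,):
            raise ValidationError("aggregate dimensions inconsistent with node list")
        if not np.array_equal(x, x.T):
            raise ValidationError("co-lying count matrix must be symmetric")
        if np.any(np.diag(x) != 0):
            raise ValidationError("co-lying count matrix must have zero diagonal")
        if np.any(n > self.scans_total):
            raise ValidationError("n(a) cannot exceed scans_total")
        pairwise_cap = np.minimum.outer(n, n)
        np.fill_diagonal(pairwise_cap, 0)
        if np.any(x > pairwise_cap):
            raise ValidationError("x(a,b) cannot exceed min(n(a), n(b))")


# ---------------------------------------------------------------------------
# CSV I/O


def _check_columns(df: pd.DataFrame, expected: Sequence[str], path: Path) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing} (header required)")


def read_scans(path: str | Path) -> list[ScanRecord]:
    """Read and validate a scan-sample CSV.

    Partners are semicolon-separated in the ``partners`` field (empty
    allowed).  Partnership symmetry is verified per scan; an asymmetric
    record raises :class:`ValidationError` naming the offending line.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _check_columns(df, SCAN_COLUMNS, path)
    records: list[ScanRecord] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        line = idx + 2  # header is line 1
        try:
            partners = frozenset(p for p in str(row.partners).split(";") if p)
            rec = ScanRecord(
                pen_id=str(row.pen_id),
                period=int(row.period),
                scan_index=int(row.scan_index),
                pig_id=str(row.pig_id),
                lying=int(row.lying),
                partners=partners,
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path}:{line}: {exc}") from exc
        records.append(rec)
    _check_partner_symmetry(records)
    return records


def _check_partner_symmetry(records: Iterable[ScanRecord]) -> None:
    by_scan: dict[tuple[str, int, int], dict[str, frozenset[str]]] = {}
    for r in records:
        by_scan.setdefault((r.pen_id, r.period, r.scan_index), {})[r.pig_id] = r.partners
    for (pen, period, scan), pigs in by_scan.items():
        for pig, partners in pigs.items():
            for other in partners:
                if pig not in pigs.get(other, frozenset()):
                    raise ValidationError(
                        f"asymmetric partnership in pen {pen}, period {period}, "
                        f"scan {scan}: {pig} lists {other} but not vice versa"
                    )


def write_scans(records: Iterable[ScanRecord], path: str | Path) -> None:
    rows = [
        {
            "pen_id": r.pen_id,
            "period": r.period,
            "scan_index": r.scan_index,
            "pig_id": r.pig_id,
            "lying": r.lying,
            "partners": ";".join(sorted(r.partners)),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=SCAN_COLUMNS).to_csv(path, index=False)


def read_bites(path: str | Path) -> list[BiteEvent]:
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _check_columns(df, BITE_COLUMNS, path)
    events: list[BiteEvent] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        line = idx + 2
        try:
            events.append(
                BiteEvent(
                    pen_id=str(row.pen_id),
                    period=int(row.period),
                    timestamp_min=float(row.timestamp_min),
                    biter=str(row.biter),
                    recipient=str(row.recipient),
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path}:{line}: {exc}") from exc
    return events


def write_bites(events: Iterable[BiteEvent], path: str | Path) -> None:
    rows = [
        {
            "pen_id": e.pen_id,
            "period": e.period,
            "timestamp_min": e.timestamp_min,
            "biter": e.biter,
            "recipient": e.recipient,
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=BITE_COLUMNS).to_csv(path, index=False)


def read_tail_scores(path: str | Path) -> list[TailScoreRecord]:
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _check_columns(df, SCORE_COLUMNS, path)
    out: list[TailScoreRecord] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        line = idx + 2
        try:
            out.append(
                TailScoreRecord(
                    pig_id=str(row.pig_id),
                    assessment_index=int(row.assessment_index),
                    score=int(row.score),
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path}:{line}: {exc}") from exc
    return out


def write_tail_scores(records: Iterable[TailScoreRecord], path: str | Path) -> None:
    rows = [
        {"pig_id": r.pig_id, "assessment_index": r.assessment_index, "score": r.score}
        for r in records
    ]
    pd.DataFrame(rows, columns=SCORE_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Matrix construction and aggregation


def build_scan_matrices(
    records: Iterable[ScanRecord], pen_id: str, period: int,
    drop_incomplete: bool = False,
) -> tuple[tuple[str, ...], list[tuple[np.ndarray, np.ndarray]]]:
    """Per-scan binary pair matrices and lying vectors for one pen-period.

    Returns ``(nodes, [(pair_matrix, lying_vector), ...])`` in scan order,
    one entry per scan index.  Every pig must appear at every scan of the
    pen-period; a missing (scan, pig) combination raises
    :class:`ValidationError` listing the gaps.  With
    ``drop_incomplete=True`` scans with an incomplete roster (e.g. a pig
    removed mid-study, or unidentifiable at that instant) are dropped
    instead, so aggregates only count scans where every pig was scored —
    keeping association-index denominators honest.
    """
    subset = [r for r in records if r.pen_id == pen_id and r.period == period]
    if not subset:
        raise ValidationError(f"no records for pen {pen_id}, period {period}")
    nodes = tuple(sorted({r.pig_id for r in subset}))
    index = {p: i for i, p in enumerate(nodes)}
    scan_ids = sorted({r.scan_index for r in subset})
    by_scan: dict[int, dict[str, ScanRecord]] = {s: {} for s in scan_ids}
    for r in subset:
        by_scan[r.scan_index][r.pig_id] = r
    missing = [
        (s, p) for s in scan_ids for p in nodes if p not in by_scan[s]
    ]
    if missing and not drop_incomplete:
        raise ValidationError(
            f"pen {pen_id}, period {period}: missing (scan, pig) records {missing}"
        )
    if missing:
        bad = {s for s, _ in missing}
        scan_ids = [s for s in scan_ids if s not in bad]
        if not scan_ids:
            raise ValidationError(
                f"pen {pen_id}, period {period}: no scan has a complete roster"
            )
    out: list[tuple[np.ndarray, np.ndarray]] = []
    k = len(nodes)
    for s in scan_ids:
        pair = np.zeros((k, k), dtype=int)
        lying = np.zeros(k, dtype=int)
        for pig, rec in by_scan[s].items():
            i = index[pig]
            lying[i] = rec.lying
            for other in rec.partners:
                if other not in index:
                    raise ValidationError(
                        f"pen {pen_id}, scan {s}: partner {other} not in pen roster"
                    )
                pair[i, index[other]] = 1
        if not np.array_equal(pair, pair.T):
            raise ValidationError(
                f"pen {pen_id}, period {period}, scan {s}: asymmetric pair matrix"
            )
        out.append((pair, lying))
    return nodes, out


def aggregate_scans(
    matrices: Sequence[tuple[np.ndarray, np.ndarray]],
    pen_id: str = "",
    period: int = 0,
    nodes: Sequence[str] | None = None,
) -> LyingAggregate:
    """Sum per-scan pair matrices and lying vectors into one aggregate."""
    if not matrices:
        raise ValidationError("cannot aggregate an empty matrix list")
    k = matrices[0][0].shape[0]
    for pair, lying in matrices:
        if pair.shape != (k, k) or lying.shape != (k,):
            raise ValidationError("inconsistent matrix dimensions in scan list")
    x = sum(np.asarray(pair, dtype=int) for pair, _ in matrices)
    n = sum(np.asarray(lying, dtype=int) for _, lying in matrices)
    node_t = tuple(nodes) if nodes is not None else tuple(str(i) for i in range(k))
    return LyingAggregate(
        pen_id=pen_id, period=period, nodes=node_t, x=x, n=n,
        scans_total=len(matrices),
    )


def lying_time_budget(agg: LyingAggregate) -> dict[str, float]:
    """Percent of scans each pig was observed lying, 0-100."""
    if agg.scans_total <= 0:
        raise ValidationError("scans_total must be positive")
    return {
        pig: 100.0 * int(agg.n[i]) / agg.scans_total
        for i, pig in enumerate(agg.nodes)
    }


def write_matrix_csv(nodes: Sequence[str], matrix: np.ndarray, path: str | Path) -> None:
    """Square matrix CSV with pig_id header row and column."""
    pd.DataFrame(matrix, index=list(nodes), columns=list(nodes)).to_csv(path)


def read_matrix_csv(path: str | Path) -> tuple[tuple[str, ...], np.ndarray]:
    df = pd.read_csv(path, index_col=0)
    return tuple(str(c) for c in df.columns), df.to_numpy()
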