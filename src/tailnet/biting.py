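"""Directed tail-biting interaction networks.

Arcs run initiator -> recipient and are weighted by bite counts, so a
pig's weighted in-degree is the total number of bites it received over
the covered periods, regardless of how many distinct pigs bit it.
Because per-period matrices are sparse, networks are usually aggregated
over the observation periods (one network per pen).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data import BiteEvent, ValidationError, write_matrix_csv

__all__ = ["BiteNetwork", "build_bite_network", "build_bite_networks"]


@dataclass(frozen=True)
class BiteNetwork:
    """Directed bite-count network: A[i, j] = bites i performed on j."""

    pen_id: str
    periods: frozenset[int]
    nodes: tuple[str, ...]
    A: np.ndarray

    def __post_init__(self) -> None:
        A = np.asarray(self.A)
        k = len(self.nodes)
        if A.shape != (k, k):
            raise ValidationError("adjacency shape inconsistent with nodes")
        if np.any(A < 0):
            raise ValidationError("bite counts must be non-negative")
        if np.any(np.diag(A) != 0):
            raise ValidationError("self-bites are impossible: diagonal must be zero")

    def to_edge_list(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.nodes):
            for j, b in enumerate(self.nodes):
                if i != j and self.A[i, j] > 0:
                    rows.append({"biter": a, "recipient": b, "count": int(self.A[i, j])})
        return pd.DataFrame(rows, columns=["biter", "recipient", "count"])

    def write_csv(self, matrix_path: str | Path, edges_path: str | Path | None = None) -> None:
        write_matrix_csv(self.nodes, self.A, matrix_path)
        if edges_path is not None:
            self.to_edge_list().to_csv(edges_path, index=False)


def build_bite_network(
    events: Iterable[BiteEvent],
    pen_id: str,
    nodes: Sequence[str],
    periods: Iterable[int] | None = None,
) -> BiteNetwork:
    """Count bites per directed dyad for one pen over the given periods.

    ``periods=None`` covers every period present for the pen (the
    aggregated network).  An event naming a pig outside ``nodes`` raises.
    """
    nodes = tuple(sorted(nodes))
    index = {p: i for i, p in enumerate(nodes)}
    pen_events = [e for e in events if e.pen_id == pen_id]
    if periods is None:
        covered = {e.period for e in pen_events}
    else:
        covered = set(periods)
        pen_events = [e for e in pen_events if e.period in covered]
    A = np.zeros((len(nodes), len(nodes)), dtype=int)
    for e in pen_events:
        if e.biter not in index or e.recipient not in index:
            raise ValidationError(
                f"event {e.biter}->{e.recipient} references a pig outside pen {pen_id}"
            )
        A[index[e.biter], index[e.recipient]] += 1
    return BiteNetwork(pen_id, frozenset(covered), nodes, A)


def build_bite_networks(
    events: Iterable[BiteEvent],
    rosters: dict[str, Sequence[str]],
    aggregate: bool = True,
    periods: Sequence[int] | None = None,
) -> list[BiteNetwork]:
    """Bite networks for every pen in ``rosters``.

    ``aggregate=True`` yields one network per pen summing all periods;
    otherwise one network per pen-period.
    """
    events = list(events)
    out: list[BiteNetwork] = []
    for pen_id in sorted(rosters):
        nodes = rosters[pen_id]
        if aggregate:
            out.append(build_bite_network(events, pen_id, nodes, periods))
        else:
            per = periods if periods is not None else sorted(
                {e.period for e in events if e.pen_id == pen_id}
            )
            for p in per:
                out.append(build_bite_network(events, pen_id, nodes, [p]))
    return out
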