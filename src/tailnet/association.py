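"""Half-weight association index (HWI) networks.

Associations between pen-mates are defined by lying in bodily contact.
For a dyad (a, b), with ``x`` the number of scans the two pigs lay
together, ``n_a`` the scans pig a lay, and ``n_b`` the scans pig b lay,

    HWI = x / ((n_a + n_b) / 2)

The half-weight form corrects for the time each member is observable in
the scored state; it ranges 0 (never together) to 1 (always together
whenever lying).  Networks are undirected and weighted by HWI.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data import LyingAggregate, ValidationError, write_matrix_csv

__all__ = ["AssociationNetwork", "half_weight_index", "build_association_network"]


@dataclass(frozen=True)
class AssociationNetwork:
    """Undirected HWI-weighted network over the pigs of one pen-period."""

    pen_id: str
    period: int
    nodes: tuple[str, ...]
    W: np.ndarray

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        k = len(self.nodes)
        if W.shape != (k, k):
            raise ValidationError("weight matrix shape inconsistent with nodes")
        if not np.allclose(W, W.T):
            raise ValidationError("HWI matrix must be symmetric")
        if np.any(np.diag(W) != 0):
            raise ValidationError("HWI matrix must have zero diagonal")
        if np.any(W < 0) or np.any(W > 1):
            raise ValidationError("HWI values must lie in [0, 1]")

    def thresholded(self, min_hwi: float) -> "AssociationNetwork":
        """Optional strong-tie cutoff: zero out edges with HWI < min_hwi."""
        W = self.W.copy()
        W[W < min_hwi] = 0.0
        return AssociationNetwork(self.pen_id, self.period, self.nodes, W)

    def to_edge_list(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.nodes):
            for j in range(i + 1, len(self.nodes)):
                if self.W[i, j] > 0:
                    rows.append({"pig_a": a, "pig_b": self.nodes[j], "hwi": self.W[i, j]})
        return pd.DataFrame(rows, columns=["pig_a", "pig_b", "hwi"])

    def write_csv(self, matrix_path: str | Path, edges_path: str | Path | None = None) -> None:
        write_matrix_csv(self.nodes, self.W, matrix_path)
        if edges_path is not None:
            self.to_edge_list().to_csv(edges_path, index=False)


def half_weight_index(x: float, n_a: float, n_b: float) -> float:
    """HWI for one dyad; 0 when neither pig was ever observed lying.

    Raises on the impossible configuration x > min(n_a, n_b).
    """
    if x < 0 or n_a < 0 or n_b < 0:
        raise ValidationError("counts must be non-negative")
    if x > min(n_a, n_b):
        raise ValidationError(
            f"x={x} exceeds min(n_a, n_b)=({n_a}, {n_b}); impossible co-occurrence"
        )
    denom = (n_a + n_b) / 2.0
    if denom == 0:
        return 0.0
    return x / denom


def build_association_network(
    agg: LyingAggregate, min_hwi: float = 0.0
) -> AssociationNetwork:
    """HWI network from a pen-period lying aggregate.

    ``min_hwi`` applies an optional strong-tie cutoff (default 0, i.e. no
    thresholding).
    """
    k = len(agg.nodes)
    W = np.zeros((k, k), dtype=float)
    for i in range(k):
        for j in range(i + 1, k):
            W[i, j] = W[j, i] = half_weight_index(
                float(agg.x[i, j]), float(agg.n[i]), float(agg.n[j])
            )
    net = AssociationNetwork(agg.pen_id, agg.period, tuple(agg.nodes), W)
    if min_hwi > 0:
        net = net.thresholded(min_hwi)
    return net


def mean_hwi(networks: Sequence[AssociationNetwork]) -> float:
    """Mean off-diagonal HWI across a set of same-size networks."""
    vals = []
    for net in networks:
        k = len(net.nodes)
        iu = np.triu_indices(k, 1)
        vals.append(net.W[iu])
    return float(np.mean(np.concatenate(vals)))
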