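"""Graph-metric engine for small weighted (un)directed networks.

Implements, from first principles, the four quantities used to describe
pen social structure:

* **density** — realized edges / possible edges (edge present iff
  weight > 0);
* **strength** — weighted degree (sum of incident edge weights; in/out
  variants for directed networks);
* **betweenness centrality** — unnormalized Brandes accumulation
  B(v) = sum over ordered (directed) or unordered (undirected) pairs
  (s, t), s != v != t, of sigma_st(v)/sigma_st, where sigma_st counts
  shortest paths.  Weighted variants use edge length 1/weight, the
  standard inversion turning tie strength into closeness;
* **Freeman centralizations** — C = sum_v (c_max - c(v)) / D_max, with
  D_max the spread attained by the star graph of the same size and
  directedness, so a star scores exactly 1 and a regular (e.g. complete)
  graph exactly 0.

Pens hold at most eight pigs, so everything here is exact and fast; the
test suite additionally checks the Brandes accumulation against an
exhaustive path-enumeration oracle.

Conventions for degenerate inputs: an edgeless network has density 0 and
all centralizations 0 (vacuous spread); disconnected pairs contribute 0
to betweenness.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .data import ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .association import AssociationNetwork
    from .biting import BiteNetwork

__all__ = [
    "density",
    "strength",
    "betweenness_centrality",
    "degree_centralization",
    "betweenness_centralization",
    "pen_metrics",
    "pig_metrics",
    "PenMetricSet",
    "PigMetricSet",
]


def _as_square(adjacency: np.ndarray) -> np.ndarray:
    A = np.asarray(adjacency, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValidationError("adjacency must be a square matrix")
    if np.any(np.diag(A) != 0):
        raise ValidationError("adjacency diagonal must be zero")
    if np.any(A < 0):
        raise ValidationError("edge weights must be non-negative")
    return A


def density(adjacency: np.ndarray, directed: bool) -> float:
    """Fraction of realizable dyads with an edge (weight > 0)."""
    A = _as_square(adjacency)
    n = A.shape[0]
    if n < 2:
        raise ValidationError("density undefined for fewer than 2 nodes")
    present = A > 0
    if directed:
        m = int(np.sum(present)) - int(np.sum(np.diag(present)))
        return m / (n * (n - 1))
    m = int(np.sum(np.triu(present | present.T, 1)))
    return m / (n * (n - 1) / 2)


def strength(adjacency: np.ndarray, mode: str = "total") -> np.ndarray:
    """Weighted degree per node.

    ``in`` = column sums (weight received), ``out`` = row sums (weight
    sent), ``total`` = (row + column sums)/2, which for a symmetric matrix
    equals the plain row sum, i.e. the sum of a pig's HWI values.
    """
    A = _as_square(adjacency)
    if mode == "in":
        return A.sum(axis=0)
    if mode == "out":
        return A.sum(axis=1)
    if mode == "total":
        return (A.sum(axis=0) + A.sum(axis=1)) / 2.0
    raise ValidationError(f"unknown strength mode {mode!r}")


def unweighted_degree(adjacency: np.ndarray, mode: str = "total") -> np.ndarray:
    """Binary degree per node (edge present iff weight > 0)."""
    A = _as_square(adjacency) > 0
    if mode == "in":
        return A.sum(axis=0).astype(float)
    if mode == "out":
        return A.sum(axis=1).astype(float)
    if mode == "total":
        return (A | A.T).sum(axis=1).astype(float)
    raise ValidationError(f"unknown degree mode {mode!r}")


# ---------------------------------------------------------------------------
# Betweenness (Brandes accumulation)


def _shortest_path_dag(lengths: np.ndarray, source: int):
    """Dijkstra from ``source`` returning (order, sigma, predecessors).

    ``lengths[i, j]`` is the edge length i->j or inf.  All shortest paths
    are counted (sigma accounting); ties are never broken arbitrarily.
    """
    n = lengths.shape[0]
    dist = np.full(n, np.inf)
    sigma = np.zeros(n)
    preds: list[list[int]] = [[] for _ in range(n)]
    dist[source] = 0.0
    sigma[source] = 1.0
    visited = np.zeros(n, dtype=bool)
    heap: list[tuple[float, int]] = [(0.0, source)]
    order: list[int] = []
    while heap:
        d, v = heapq.heappop(heap)
        if visited[v]:
            continue
        visited[v] = True
        order.append(v)
        for w in range(n):
            lw = lengths[v, w]
            if not np.isfinite(lw):
                continue
            alt = d + lw
            if alt < dist[w]:
                dist[w] = alt
                sigma[w] = sigma[v]
                preds[w] = [v]
                heapq.heappush(heap, (alt, w))
            elif alt == dist[w] and not visited[w]:
                sigma[w] += sigma[v]
                preds[w].append(v)
    return order, sigma, preds


def betweenness_centrality(
    adjacency: np.ndarray, directed: bool, weighted: bool = False
) -> np.ndarray:
    """Unnormalized betweenness per node.

    Undirected values count each unordered pair once; directed values sum
    over ordered pairs.  Weighted shortest paths use length 1/weight.
    """
    A = _as_square(adjacency)
    n = A.shape[0]
    if not directed:
        A = np.maximum(A, A.T)
    with np.errstate(divide="ignore"):
        lengths = np.where(A > 0, (1.0 / A) if weighted else 1.0, np.inf)
    B = np.zeros(n)
    for s in range(n):
        order, sigma, preds = _shortest_path_dag(lengths, s)
        delta = np.zeros(n)
        for w in reversed(order):
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                B[w] += delta[w]
    if not directed:
        B /= 2.0
    return B


# ---------------------------------------------------------------------------
# Freeman centralizations


def degree_centralization(
    adjacency: np.ndarray,
    directed: bool,
    mode: str = "total",
    weighted: bool = False,
) -> float:
    """Freeman degree centralization in [0, 1].

    Default uses binary degrees (edge present iff weight > 0), the
    classical Freeman definition: D_max = (n-1)(n-2) for undirected total
    degree and (n-1)^2 for directed in-/out-degree, so a star (or
    in-/out-star) scores exactly 1.

    ``weighted=True`` switches to the strength-based variant, normalized
    by the spread of a star carrying the observed maximum edge weight on
    every edge, so it stays in [0, 1] and reduces to the binary variant
    on 0/1 matrices.
    """
    A = _as_square(adjacency)
    n = A.shape[0]
    if n < 3:
        raise ValidationError("centralization needs at least 3 nodes")
    if not directed and mode != "total":
        raise ValidationError("undirected networks have total degree only")
    if weighted:
        d = strength(A, mode)
        wmax = float(A.max())
        if wmax == 0:
            return 0.0
        denom = (n - 1) * (n - 2) * wmax if not directed else (n - 1) ** 2 * wmax
    else:
        d = unweighted_degree(A, mode)
        if not np.any(A > 0):
            return 0.0
        denom = (n - 1) * (n - 2) if not directed else (n - 1) ** 2
    return float(np.sum(d.max() - d) / denom)


def betweenness_centralization(
    adjacency: np.ndarray, directed: bool, weighted: bool = False
) -> float:
    """Freeman betweenness centralization in [0, 1].

    D_max is the spread of the star graph of the same n and directedness:
    (n-1)^2 (n-2) / 2 undirected, (n-1)^2 (n-2) directed (the star center
    mediates (n-1)(n-2) ordered leaf pairs).
    """
    A = _as_square(adjacency)
    n = A.shape[0]
    if n < 3:
        raise ValidationError("centralization needs at least 3 nodes")
    if not np.any(A > 0):
        return 0.0
    B = betweenness_centrality(A, directed=directed, weighted=weighted)
    denom = (n - 1) ** 2 * (n - 2) * (0.5 if not directed else 1.0)
    return float(np.sum(B.max() - B) / denom)


# ---------------------------------------------------------------------------
# Dispatch per network type


@dataclass(frozen=True)
class PenMetricSet:
    """Network-level metrics for one pen(-period)."""

    pen_id: str
    period: int | None
    directed: bool
    density: float
    degree_centralization: float | None = None
    in_degree_centralization: float | None = None
    out_degree_centralization: float | None = None
    betweenness_centralization: float = 0.0


@dataclass(frozen=True)
class PigMetricSet:
    """Node-level metrics for one pig in one network."""

    pig_id: str
    pen_id: str
    period: int | None
    strength: float | None = None
    in_strength: float | None = None
    out_strength: float | None = None
    degree: float | None = None
    in_degree: float | None = None
    out_degree: float | None = None
    betweenness: float = 0.0


def _is_bite(network) -> bool:
    return hasattr(network, "A")


def pen_metrics(
    network: "AssociationNetwork | BiteNetwork",
    weighted_centralization: bool = False,
    weighted_betweenness: bool | None = None,
) -> PenMetricSet:
    """Pen-level metric set, dispatched by network type.

    Association networks (undirected, HWI weights) get density, degree
    centralization, betweenness centralization; bite networks (directed)
    get density, in-/out-degree centralization, betweenness
    centralization.  Betweenness distances default to 1/HWI for
    association networks and hop counts for sparse bite networks.
    """
    if _is_bite(network):
        A = network.A
        wb = False if weighted_betweenness is None else weighted_betweenness
        return PenMetricSet(
            pen_id=network.pen_id,
            period=None,
            directed=True,
            density=density(A, directed=True),
            in_degree_centralization=degree_centralization(
                A, directed=True, mode="in", weighted=weighted_centralization
            ),
            out_degree_centralization=degree_centralization(
                A, directed=True, mode="out", weighted=weighted_centralization
            ),
            betweenness_centralization=betweenness_centralization(
                A, directed=True, weighted=wb
            ),
        )
    W = network.W
    wb = True if weighted_betweenness is None else weighted_betweenness
    return PenMetricSet(
        pen_id=network.pen_id,
        period=network.period,
        directed=False,
        density=density(W, directed=False),
        degree_centralization=degree_centralization(
            W, directed=False, weighted=weighted_centralization
        ),
        betweenness_centralization=betweenness_centralization(
            W, directed=False, weighted=wb
        ),
    )


def pig_metrics(
    network: "AssociationNetwork | BiteNetwork",
    weighted_betweenness: bool | None = None,
) -> list[PigMetricSet]:
    """Pig-level metric sets, dispatched by network type."""
    if _is_bite(network):
        A = network.A
        wb = False if weighted_betweenness is None else weighted_betweenness
        s_in = strength(A, "in")
        s_out = strength(A, "out")
        d_in = unweighted_degree(A, "in")
        d_out = unweighted_degree(A, "out")
        B = betweenness_centrality(A, directed=True, weighted=wb)
        return [
            PigMetricSet(
                pig_id=p,
                pen_id=network.pen_id,
                period=None,
                in_strength=float(s_in[i]),
                out_strength=float(s_out[i]),
                in_degree=float(d_in[i]),
                out_degree=float(d_out[i]),
                betweenness=float(B[i]),
            )
            for i, p in enumerate(network.nodes)
        ]
    W = network.W
    wb = True if weighted_betweenness is None else weighted_betweenness
    s = strength(W, "total")
    d = unweighted_degree(W, "total")
    B = betweenness_centrality(W, directed=False, weighted=wb)
    return [
        PigMetricSet(
            pig_id=p,
            pen_id=network.pen_id,
            period=network.period,
            strength=float(s[i]),
            degree=float(d[i]),
            betweenness=float(B[i]),
        )
        for i, p in enumerate(network.nodes)
    ]
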