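"""Quasimetric construction from correlation digraphs.

Lagged correlations measure similarity and satisfy none of the
quasimetric axioms.  They are turned into a quasimetric in two steps:

1. the dissimilarity transform  ``d~(u,v) = sqrt((1 - rho(u,v)) / 2)``,
   mapping perfect positive correlation to 0 and perfect negative
   correlation to 1;
2. shortest-path closure: ``d(u,v)`` is the minimum total ``d~`` weight
   over directed paths from ``u`` to ``v``, which enforces the triangle
   inequality by construction while never increasing any entry.

The result is asymmetric in general, hence a quasimetric rather than a
metric.  Toy digraphs with absent edges keep infinite distances for
unreachable pairs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.sparse.csgraph import shortest_path as _sp_shortest_path

from .exceptions import InvalidCorrelationError, NegativeWeightError

logger = logging.getLogger("bmhnet")

_RHO_TOL = 1e-9
_TRI_TOL = 1e-9


@dataclass
class QuasimetricSpace:
    """An N x N directed distance matrix with node labels.

    ``is_closed`` records whether shortest-path closure was applied;
    only closed matrices are guaranteed to satisfy the triangle
    inequality (verifiable with :func:`check_quasimetric`).
    """

    d: np.ndarray
    node_ids: list[str] = field(default=None)  # type: ignore[assignment]
    is_closed: bool = False

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = self.d.shape[0]
        if self.d.shape != (n, n):
            raise ValueError("distance matrix must be square")
        if self.node_ids is None:
            self.node_ids = [f"v{i}" for i in range(n)]
        if len(self.node_ids) != n:
            raise ValueError("node_ids length does not match matrix")

    @property
    def n_nodes(self) -> int:
        return self.d.shape[0]


@dataclass
class WeightedDigraph:
    """A toy digraph: nodes 0..n-1, directed edges with positive weights.

    A missing ordered pair means infinite weight.  Used for worked
    examples and fixtures where a non-complete digraph is easier to
    reason about than a full quasimetric matrix.
    """

    n_nodes: int
    edges: dict[tuple[int, int], float]

    def __post_init__(self) -> None:
        for (u, v), w in self.edges.items():
            if u == v:
                raise ValueError(f"self-loop ({u},{v}) not allowed")
            if not (0 <= u < self.n_nodes and 0 <= v < self.n_nodes):
                raise ValueError(f"edge ({u},{v}) out of range")
            if not (w > 0 and math.isfinite(w)):
                raise ValueError(f"edge ({u},{v}) weight must be positive finite")

    def to_matrix(self) -> np.ndarray:
        """Dense matrix with inf for absent pairs and zero diagonal."""
        d = np.full((self.n_nodes, self.n_nodes), np.inf)
        np.fill_diagonal(d, 0.0)
        for (u, v), w in self.edges.items():
            d[u, v] = w
        return d


def dissimilarity(rho: float | np.ndarray) -> float | np.ndarray:
    """Map a correlation in [-1, 1] to a dissimilarity sqrt((1-rho)/2)."""
    arr = np.asarray(rho, dtype=float)
    if np.any(np.abs(arr) > 1 + _RHO_TOL):
        raise InvalidCorrelationError("correlation outside [-1, 1]")
    arr = np.clip(arr, -1.0, 1.0)
    out = np.sqrt((1.0 - arr) / 2.0)
    return float(out) if np.isscalar(rho) or out.ndim == 0 else out


def dissimilarity_matrix(rho: np.ndarray) -> np.ndarray:
    """Elementwise dissimilarity of a correlation matrix, zero diagonal."""
    dt = dissimilarity(np.asarray(rho, dtype=float))
    np.fill_diagonal(dt, 0.0)
    return dt


def shortest_path_closure(
    dtilde: np.ndarray, node_ids: list[str] | None = None
) -> QuasimetricSpace:
    """All-pairs shortest directed path distances of a dissimilarity matrix.

    Runs a heap-based single-source search (Dijkstra) from every node.
    Entries may be infinite when the input digraph is not strongly
    connected.  Off-diagonal zeros (perfectly correlated nodes) are kept
    as genuine zero-weight edges and survive closure; they are reported
    by :func:`check_quasimetric` but deliberately not repaired.
    """
    dtilde = np.asarray(dtilde, dtype=float)
    if np.any(dtilde < 0):
        raise NegativeWeightError("dissimilarity matrix has negative entries")
    if np.any(np.diag(dtilde) != 0):
        raise ValueError("dissimilarity matrix must have zero diagonal")
    offdiag = dtilde[~np.eye(dtilde.shape[0], dtype=bool)]
    n_zero = int(np.sum(offdiag == 0.0))
    if n_zero:
        logger.warning(
            "%d off-diagonal zero distances (perfectly correlated nodes); "
            "kept as-is", n_zero,
        )
    # masked entries are non-edges; genuine zero weights stay edges
    graph = np.ma.masked_array(dtilde, mask=~np.isfinite(dtilde))
    d = _sp_shortest_path(graph, method="D", directed=True)
    np.fill_diagonal(d, 0.0)
    return QuasimetricSpace(d=d, node_ids=node_ids, is_closed=True)


@dataclass
class QuasimetricReport:
    """Axiom violations of a candidate quasimetric matrix."""

    negative: list[tuple[int, int]]
    nonzero_diagonal: list[int]
    zero_offdiagonal: list[tuple[int, int]]
    triangle: list[tuple[int, int, int]]

    @property
    def ok(self) -> bool:
        return not (
            self.negative
            or self.nonzero_diagonal
            or self.zero_offdiagonal
            or self.triangle
        )


def check_quasimetric(space: QuasimetricSpace | np.ndarray) -> QuasimetricReport:
    """Enumerate violations of the quasimetric axioms.

    Checks non-negativity, zero diagonal, identity of indiscernibles
    (off-diagonal zeros), and — exhaustively over all ordered triples —
    the triangle inequality ``d(u,w) <= d(u,v) + d(v,w)``.
    """
    d = space.d if isinstance(space, QuasimetricSpace) else np.asarray(space, float)
    n = d.shape[0]
    negative = [tuple(ij) for ij in np.argwhere(d < 0)]
    nonzero_diag = [int(i) for i in range(n) if d[i, i] != 0]
    off = (d == 0) & ~np.eye(n, dtype=bool)
    zero_off = [tuple(ij) for ij in np.argwhere(off)]
    # d[u,w] > d[u,v] + d[v,w] (+tol), scanned with broadcasting
    with np.errstate(invalid="ignore"):
        lhs = d[:, None, :]                      # (u, v, w) -> d[u, w]
        rhs = d[:, :, None] + d[None, :, :]      # d[u, v] + d[v, w]
        bad = lhs > rhs * (1 + _TRI_TOL) + _TRI_TOL
    tri = [
        (int(u), int(v), int(w))
        for u, v, w in np.argwhere(bad)
        if u != v and v != w
    ]
    return QuasimetricReport(
        negative=negative,
        nonzero_diagonal=nonzero_diag,
        zero_offdiagonal=zero_off,
        triangle=tri,
    )


# ---------------------------------------------------------------------------
# I/O: edge lists and adjacency CSV with "inf" tokens
# ---------------------------------------------------------------------------

def read_edge_list(path: str | Path) -> WeightedDigraph:
    """Parse lines "source target weight"; node ids are integers."""
    edges: dict[tuple[int, int], float] = {}
    max_node = -1
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        s, t, w = line.split()
        u, v = int(s), int(t)
        if (u, v) in edges:
            raise ValueError(f"duplicate edge ({u},{v})")
        edges[(u, v)] = float(w)
        max_node = max(max_node, u, v)
    return WeightedDigraph(n_nodes=max_node + 1, edges=edges)


def write_edge_list(g: WeightedDigraph, path: str | Path) -> None:
    lines = [f"{u} {v} {w}" for (u, v), w in sorted(g.edges.items())]
    Path(path).write_text("\n".join(lines) + "\n")


def read_adjacency_csv(path: str | Path) -> np.ndarray:
    import pandas as pd

    df = pd.read_csv(path, index_col=0)
    return df.replace("inf", np.inf).to_numpy(dtype=float)


def write_adjacency_csv(d: np.ndarray, path: str | Path,
                        node_ids: list[str] | None = None) -> None:
    import pandas as pd

    n = d.shape[0]
    ids = node_ids or [f"v{i}" for i in range(n)]
    pd.DataFrame(d, index=ids, columns=ids).to_csv(path)
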