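"""Magnitude and blurred magnitude homology of quasimetric digraphs.

The chain complex is built from *k-paths*: ordered tuples
``(v0, ..., vk)`` with consecutive entries distinct, whose *length* is
the sum of consecutive quasimetric distances.  Strict magnitude chains
``MC(k, l)`` are spanned by the k-paths of length exactly ``l``; the
blurred variant ``BMC(k, l)`` relaxes this to length at most ``l``,
which is the flavour used for Betti-curve featurization.  The boundary
operator drops interior nodes with alternating signs, keeping only
drops whose result is itself a basis member.

Only degrees k <= 2 are implemented, which is all that the zeroth and
first Betti numbers need:

* ``beta0 = dim BMC0 - rank(delta1)`` counts weakly connected
  components of the length-filtered subgraph;
* ``beta1 = dim BMC1 - rank(delta1) - rank(delta2)`` counts independent
  classes of undirected cycles modulo two-path deformations.

Ranks are computed exactly over the rationals (integer-preserving
sparse elimination with unit pivots, falling back to exact fractions),
so no floating tolerance enters the Betti numbers.

Toy digraphs with absent (infinite-weight) edges are supported: a
blurred 2-path enters the basis only if its shortcut pair either is
degenerate or is itself a basis member.  On a shortest-path-closed
space this condition is implied by the triangle inequality; on a
non-complete digraph it is what keeps ``delta1 . delta2 = 0`` while
matching the convention that only triples whose shortcut edge exists
count as deformations.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np

from .exceptions import MismatchedBasesError, UnsupportedDegreeError
from .quasimetric import QuasimetricSpace, WeightedDigraph

_LEN_RTOL = 1e-9
_LEN_ATOL = 1e-12


def _distance_matrix(space) -> np.ndarray:
    if isinstance(space, QuasimetricSpace):
        return space.d
    if isinstance(space, WeightedDigraph):
        return space.to_matrix()
    d = np.asarray(space, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("expected a square distance matrix")
    return d


def _eq(a: float, b: float) -> bool:
    """Exact-level comparison with relative slack for float path sums."""
    if a == b:
        return True
    return math.isclose(a, b, rel_tol=_LEN_RTOL, abs_tol=_LEN_ATOL)


def _le(a: float, b: float) -> bool:
    return a <= b or _eq(a, b)


@dataclass
class ChainBasis:
    """Canonical (lexicographic) basis of a chain space at one level."""

    k: int
    level: float
    blurred: bool
    tuples: list[tuple[int, ...]]
    lengths: list[float]

    def __post_init__(self) -> None:
        self.index = {t: i for i, t in enumerate(self.tuples)}

    @property
    def dim(self) -> int:
        return len(self.tuples)


@dataclass
class BoundaryMatrix:
    """Sparse signed incidence of k-chains into (k-1)-chains."""

    n_rows: int
    n_cols: int
    triplets: list[tuple[int, int, int]]  # (row, col, sign)

    def to_dense(self) -> np.ndarray:
        m = np.zeros((self.n_rows, self.n_cols), dtype=np.int64)
        for r, c, s in self.triplets:
            m[r, c] += s
        return m


def enumerate_paths(space, k: int, level: float, blurred: bool) -> ChainBasis:
    """Enumerate the k-path basis of MC/BMC at the given length level.

    k=0: single nodes (length 0); k=1: ordered pairs with finite
    distance; k=2: ordered triples with finite hops (and, blurred, a
    member or degenerate middle drop).  Lexicographic node order.
    """
    if level < 0:
        raise ValueError("level must be non-negative")
    if k not in (0, 1, 2):
        raise UnsupportedDegreeError(f"k={k} unsupported (only k <= 2)")
    d = _distance_matrix(space)
    n = d.shape[0]
    tuples: list[tuple[int, ...]] = []
    lengths: list[float] = []
    if k == 0:
        if blurred or _eq(level, 0.0):
            tuples = [(i,) for i in range(n)]
            lengths = [0.0] * n
    elif k == 1:
        for u in range(n):
            for v in range(n):
                if u == v or not math.isfinite(d[u, v]):
                    continue
                L = float(d[u, v])
                if (_le(L, level) if blurred else _eq(L, level)):
                    tuples.append((u, v))
                    lengths.append(L)
    else:
        for u in range(n):
            for v in range(n):
                if u == v or not math.isfinite(d[u, v]):
                    continue
                for w in range(n):
                    if w == v or not math.isfinite(d[v, w]):
                        continue
                    L = float(d[u, v] + d[v, w])
                    if blurred:
                        if not _le(L, level):
                            continue
                        if u != w and not (
                            math.isfinite(d[u, w]) and _le(float(d[u, w]), level)
                        ):
                            continue
                    elif not _eq(L, level):
                        continue
                    tuples.append((u, v, w))
                    lengths.append(L)
    return ChainBasis(k=k, level=level, blurred=blurred,
                      tuples=tuples, lengths=lengths)


def boundary_matrix(basis_km1: ChainBasis, basis_k: ChainBasis) -> BoundaryMatrix:
    """Assemble delta_k: columns over k-paths, rows over (k-1)-paths.

    Each drop of an interior or endpoint node contributes ``(-1)^i``
    when the dropped tuple is consecutive-distinct and a member of the
    (k-1) basis; all other drops contribute zero.
    """
    if basis_km1.k != basis_k.k - 1:
        raise MismatchedBasesError("bases must differ in degree by one")
    if basis_km1.blurred != basis_k.blurred or basis_km1.level != basis_k.level:
        raise MismatchedBasesError("bases must share level and flavour")
    trip: list[tuple[int, int, int]] = []
    for col, tup in enumerate(basis_k.tuples):
        for i in range(len(tup)):
            dropped = tup[:i] + tup[i + 1:]
            if any(dropped[j] == dropped[j + 1] for j in range(len(dropped) - 1)):
                continue  # degenerate drop
            row = basis_km1.index.get(dropped)
            if row is not None:
                trip.append((row, col, -1 if i % 2 else 1))
    return BoundaryMatrix(n_rows=basis_km1.dim, n_cols=basis_k.dim, triplets=trip)


# ---------------------------------------------------------------------------
# Exact rank over the rationals
# ---------------------------------------------------------------------------

def rank_exact(bm: BoundaryMatrix) -> int:
    """Rank over Q by sparse Gaussian elimination.

    Pivots of absolute value 1 (almost always available for signed
    incidence matrices) keep all arithmetic in the integers; otherwise
    the elimination step falls back to exact ``Fraction`` arithmetic.
    """
    rows: dict[int, dict[int, object]] = {}
    for r, c, s in bm.triplets:
        row = rows.setdefault(r, {})
        v = row.get(c, 0) + s
        if v:
            row[c] = v
        else:
            row.pop(c, None)
    work = [row for row in rows.values() if row]
    rank = 0
    while work:
        # pivot row: prefer a unit entry, then fewest nonzeros
        best_i, best_key = 0, None
        for i, row in enumerate(work):
            has_unit = any(v == 1 or v == -1 for v in row.values())
            key = (not has_unit, len(row))
            if best_key is None or key < best_key:
                best_i, best_key = i, key
        prow = work.pop(best_i)
        rank += 1
        pcol = None
        for c, v in prow.items():
            if v == 1 or v == -1:
                pcol = c
                break
        if pcol is None:
            pcol = next(iter(prow))
        pval = prow[pcol]
        unit = pval == 1 or pval == -1
        nxt = []
        for row in work:
            coeff = row.get(pcol)
            if coeff:
                f = coeff * pval if unit else Fraction(coeff) / Fraction(pval)
                for c, v in prow.items():
                    nv = row.get(c, 0) - f * v
                    if nv:
                        row[c] = nv
                    else:
                        row.pop(c, None)
            if row:
                nxt.append(row)
        work = nxt
    return rank


def rank_float(bm: BoundaryMatrix, tol: float = 1e-8) -> int:
    """Floating rank via singular values; cross-check for rank_exact."""
    if bm.n_rows == 0 or bm.n_cols == 0 or not bm.triplets:
        return 0
    s = np.linalg.svd(bm.to_dense().astype(float), compute_uv=False)
    return int(np.sum(s > tol * max(1.0, float(s[0]))))


# ---------------------------------------------------------------------------
# Betti numbers
# ---------------------------------------------------------------------------

def betti_number(space, n: int, level: float, blurred: bool = True) -> int:
    """Blurred (default) or strict magnitude Betti number at one level."""
    if n not in (0, 1):
        raise UnsupportedDegreeError(f"n={n} unsupported (only beta0, beta1)")
    if not blurred:
        return magnitude_betti(space, n, level)
    b0 = enumerate_paths(space, 0, level, True)
    b1 = enumerate_paths(space, 1, level, True)
    d1 = boundary_matrix(b0, b1)
    r1 = rank_exact(d1)
    if n == 0:
        return b0.dim - r1
    b2 = enumerate_paths(space, 2, level, True)
    d2 = boundary_matrix(b1, b2)
    r2 = rank_exact(d2)
    return b1.dim - r1 - r2


def magnitude_betti(space, n: int, level: float) -> int:
    """Strict (non-blurred) magnitude homology dimension.

    For n=0 the chain space is trivial at positive levels, so the
    answer is N at level 0 and 0 otherwise; for n=1, delta1 is the zero
    operator and ``MH1 = dim MC1 - rank(delta2)``.
    """
    if n not in (0, 1):
        raise UnsupportedDegreeError(f"n={n} unsupported (only beta0, beta1)")
    if level < 0:
        raise ValueError("level must be non-negative")
    if n == 0:
        b0 = enumerate_paths(space, 0, level, False)
        b1 = enumerate_paths(space, 1, level, False)
        return b0.dim - rank_exact(boundary_matrix(b0, b1))
    b1 = enumerate_paths(space, 1, level, False)
    b2 = enumerate_paths(space, 2, level, False)
    return b1.dim - rank_exact(boundary_matrix(b1, b2))


def weak_component_count(space, level: float) -> int:
    """Union-find count of weakly connected components at one level.

    Independent of the boundary-operator machinery: nodes ``u`` and
    ``v`` are joined whenever either directed distance is <= level.
    """
    if level < 0:
        raise ValueError("level must be non-negative")
    d = _distance_matrix(space)
    n = d.shape[0]
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u in range(n):
        for v in range(u + 1, n):
            m = min(d[u, v], d[v, u])
            if math.isfinite(m) and _le(float(m), level):
                ru, rv = find(u), find(v)
                if ru != rv:
                    parent[ru] = rv
    return len({find(i) for i in range(n)})


# ---------------------------------------------------------------------------
# Debug dumps
# ---------------------------------------------------------------------------

def dump_complex(space, level: float, blurred: bool, path: str | Path) -> None:
    """JSON dump of bases and boundary triplets for cross-checking."""
    bases = [enumerate_paths(space, k, level, blurred) for k in (0, 1, 2)]
    d1 = boundary_matrix(bases[0], bases[1])
    d2 = boundary_matrix(bases[1], bases[2])
    payload = {
        "level": level,
        "blurred": blurred,
        "bases": [
            {"k": b.k, "tuples": [list(t) for t in b.tuples], "lengths": b.lengths}
            for b in bases
        ],
        "delta1": {"shape": [d1.n_rows, d1.n_cols], "triplets": d1.triplets},
        "delta2": {"shape": [d2.n_rows, d2.n_cols], "triplets": d2.triplets},
    }
    Path(path).write_text(json.dumps(payload, indent=1))
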