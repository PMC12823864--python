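"""Betti curves over threshold grids and subnetwork featurization.

A Betti curve evaluates a Betti number at every point of an evenly
spaced threshold grid: [0, 1] for beta0 (the range of the dissimilarity
quasimetric) and [0, 2] for beta1 (the range of two-hop path lengths).
Computing curves on a whole 116-region connectome is expensive, so the
regions are split into nine canonical functional subnetworks and the
curves are computed per subnetwork, giving the 18-curve feature
representation: nine beta0 curves followed by nine beta1 curves, each
block in the fixed subnetwork order.

Curve evaluation enumerates paths once at the top of the grid and
filters per level, which is equivalent to naive per-level recomputation
but avoids repeated enumeration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import DirectedConnectome
from .exceptions import ConfigurationError
from .homology import (
    ChainBasis,
    boundary_matrix,
    enumerate_paths,
    rank_exact,
    _le,
)
from .quasimetric import dissimilarity_matrix, shortest_path_closure

#: Canonical functional subnetwork order used everywhere in the package:
#: basal ganglia, cerebellar, dorsal attention, default mode,
#: frontoparietal, limbic, sensorimotor, ventral attention, visual.
SUBNETWORKS: tuple[str, ...] = (
    "BGN", "CEREN", "DAN", "DMN", "FPN", "LN", "SMN", "VAN", "VN",
)


@dataclass
class ThresholdGrid:
    """T evenly spaced thresholds, inclusive of both endpoints."""

    d_min: float
    d_max: float
    T: int

    def __post_init__(self) -> None:
        if self.T < 2:
            raise ConfigurationError("grid needs at least 2 points")
        if not self.d_max > self.d_min:
            raise ConfigurationError("d_max must exceed d_min")
        self.points = np.linspace(self.d_min, self.d_max, self.T)


def default_grids(T: int = 256) -> tuple[ThresholdGrid, ThresholdGrid]:
    """The standard grids: [0, 1] for beta0 and [0, 2] for beta1."""
    return ThresholdGrid(0.0, 1.0, T), ThresholdGrid(0.0, 2.0, T)


@dataclass
class BettiCurve:
    """Integer Betti numbers evaluated on a threshold grid."""

    n: int
    grid: ThresholdGrid
    values: np.ndarray
    subnetwork: str = "global"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.shape != (self.grid.T,):
            raise ValueError("values length does not match grid")
        if np.any(self.values < 0):
            raise ValueError("Betti numbers must be non-negative")


def _filtered_basis(basis: ChainBasis, level: float,
                    extra: list[float] | None = None) -> ChainBasis:
    """Restrict a basis enumerated at d_max to a lower level."""
    tuples, lengths = [], []
    for i, (t, L) in enumerate(zip(basis.tuples, basis.lengths)):
        if not _le(L, level):
            continue
        if extra is not None and not _le(extra[i], level):
            continue
        tuples.append(t)
        lengths.append(L)
    return ChainBasis(k=basis.k, level=level, blurred=True,
                      tuples=tuples, lengths=lengths)


def betti_curve(space, n: int, grid: ThresholdGrid,
                subnetwork: str = "global") -> BettiCurve:
    """Evaluate the blurred magnitude Betti curve beta_n over a grid.

    Paths are enumerated once at ``grid.d_max``; at each grid point the
    bases are filtered by length (triples also by their shortcut
    length) and the ranks of the boundary operators recomputed exactly.
    """
    if n not in (0, 1):
        from .exceptions import UnsupportedDegreeError

        raise UnsupportedDegreeError(f"n={n} unsupported (only beta0, beta1)")
    top = float(grid.d_max)
    b0_full = enumerate_paths(space, 0, top, True)
    b1_full = enumerate_paths(space, 1, top, True)
    if n == 1:
        from .homology import _distance_matrix

        d = _distance_matrix(space)
        b2_full = enumerate_paths(space, 2, top, True)
        # shortcut length of each triple; degenerate middle drop -> always ok
        shortcut = [
            0.0 if t[0] == t[2] else float(d[t[0], t[2]]) for t in b2_full.tuples
        ]
    values = np.zeros(grid.T, dtype=np.int64)
    for i, lev in enumerate(grid.points):
        lev = float(lev)
        b0 = _filtered_basis(b0_full, lev)
        b1 = _filtered_basis(b1_full, lev)
        r1 = rank_exact(boundary_matrix(b0, b1))
        if n == 0:
            values[i] = b0.dim - r1
        else:
            b2 = _filtered_basis(b2_full, lev, extra=shortcut)
            r2 = rank_exact(boundary_matrix(b1, b2))
            values[i] = b1.dim - r1 - r2
    return BettiCurve(n=n, grid=grid, values=values, subnetwork=subnetwork)


# ---------------------------------------------------------------------------
# Subnetwork partition and the 18-curve feature bundle
# ---------------------------------------------------------------------------

@dataclass
class SubnetworkPartition:
    """Assignment of every region label to one of the nine subnetworks."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        bad = {s for s in self.mapping.values() if s not in SUBNETWORKS}
        if bad:
            raise ConfigurationError(f"unknown subnetwork label(s): {sorted(bad)}")
        counts = {s: 0 for s in SUBNETWORKS}
        for s in self.mapping.values():
            counts[s] += 1
        thin = [s for s, c in counts.items() if c < 3]
        if thin:
            raise ConfigurationError(
                f"subnetwork(s) with fewer than 3 regions: {thin}"
            )

    def regions_of(self, subnetwork: str, region_order: list[str]) -> list[str]:
        """Regions of one subnetwork, in the connectome's region order."""
        return [r for r in region_order if self.mapping.get(r) == subnetwork]

    @classmethod
    def read_csv(cls, path: str | Path) -> "SubnetworkPartition":
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise ConfigurationError("partition CSV needs two columns")
        col_r, col_s = df.columns[:2]
        return cls(mapping=dict(zip(df[col_r].astype(str), df[col_s].astype(str))))

    def write_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"region_label": list(self.mapping), "subnetwork_label": list(self.mapping.values())}
        ).to_csv(path, index=False)


@dataclass
class FeatureBundle:
    """The 18-curve feature representation of one connectome.

    ``beta0_joint`` concatenates the nine beta0 curves in canonical
    subnetwork order, ``beta1_joint`` the nine beta1 curves;
    ``x_betti`` concatenates the two blocks (length 18*T).
    ``x_connectome`` is the row-major off-diagonal flattening of the
    lagged-correlation matrix.
    """

    beta0_joint: np.ndarray
    beta1_joint: np.ndarray
    x_connectome: np.ndarray
    T: int
    curves: list[BettiCurve] = field(default_factory=list)

    @property
    def x_betti(self) -> np.ndarray:
        return np.concatenate([self.beta0_joint, self.beta1_joint])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "T": self.T,
            "beta0_joint": self.beta0_joint.tolist(),
            "beta1_joint": self.beta1_joint.tolist(),
            "x_connectome": self.x_connectome.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureBundle":
        payload = json.loads(Path(path).read_text())
        return cls(
            beta0_joint=np.asarray(payload["beta0_joint"]),
            beta1_joint=np.asarray(payload["beta1_joint"]),
            x_connectome=np.asarray(payload["x_connectome"], dtype=float),
            T=int(payload["T"]),
        )


def subnetwork_features(conn: DirectedConnectome,
                        partition: SubnetworkPartition,
                        T: int = 256) -> FeatureBundle:
    """Compute the 18-curve bundle of a connectome.

    For each subnetwork (canonical order) the correlation matrix is
    restricted to that subnetwork's regions, transformed to a
    dissimilarity, closed by shortest paths *within the subnetwork*,
    and beta0/beta1 curves are evaluated on the default grids.
    """
    missing = [r for r in conn.region_ids if r not in partition.mapping]
    if missing:
        raise ConfigurationError(f"region(s) not in partition: {missing}")
    grid0, grid1 = default_grids(T)
    idx = {r: i for i, r in enumerate(conn.region_ids)}
    curves: list[BettiCurve] = []
    beta0_blocks, beta1_blocks = [], []
    for sub in SUBNETWORKS:
        regions = partition.regions_of(sub, conn.region_ids)
        if len(regions) < 3:
            raise ConfigurationError(
                f"subnetwork {sub} has fewer than 3 regions in this connectome"
            )
        sel = np.array([idx[r] for r in regions])
        rho_sub = conn.rho[np.ix_(sel, sel)]
        space = shortest_path_closure(dissimilarity_matrix(rho_sub),
                                      node_ids=regions)
        c0 = betti_curve(space, 0, grid0, subnetwork=sub)
        c1 = betti_curve(space, 1, grid1, subnetwork=sub)
        curves.extend([c0, c1])
        beta0_blocks.append(c0.values.astype(float))
        beta1_blocks.append(c1.values.astype(float))
    return FeatureBundle(
        beta0_joint=np.concatenate(beta0_blocks),
        beta1_joint=np.concatenate(beta1_blocks),
        x_connectome=conn.offdiagonal_vector(),
        T=T,
        curves=curves,
    )


def extract_features(connectomes: list[DirectedConnectome],
                     partition: SubnetworkPartition,
                     T: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """Stack feature bundles of a cohort into (Xc, Xb) design matrices."""
    bundles = [subnetwork_features(c, partition, T) for c in connectomes]
    Xc = np.stack([b.x_connectome for b in bundles])
    Xb = np.stack([b.x_betti for b in bundles])
    return Xc, Xb


# ---------------------------------------------------------------------------
# Curve serialization (long-format CSV round-trip)
# ---------------------------------------------------------------------------

def curves_to_frame(curves: list[BettiCurve], subject: str = "s0") -> pd.DataFrame:
    rows = []
    for c in curves:
        for i, (thr, val) in enumerate(zip(c.grid.points, c.values)):
            rows.append(
                dict(subject=subject, subnetwork=c.subnetwork, n=c.n,
                     grid_index=i, threshold=float(thr), betti=int(val))
            )
    return pd.DataFrame(rows)


def frame_to_curves(df: pd.DataFrame) -> list[BettiCurve]:
    curves = []
    for (sub, n), g in df.groupby(["subnetwork", "n"], sort=False):
        g = g.sort_values("grid_index")
        pts = g["threshold"].to_numpy(dtype=float)
        grid = ThresholdGrid(float(pts[0]), float(pts[-1]), len(pts))
        curves.append(
            BettiCurve(n=int(n), grid=grid,
                       values=g["betti"].to_numpy(dtype=np.int64),
                       subnetwork=str(sub))
        )
    return curves
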