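"""Directed connectome construction from ROI time series.

A directed functional connectome is built by correlating each region's
activity with a time-shifted copy of every other region's activity
(lagged Pearson correlation, lagged PCC).  Because the correlation of
``x_u`` at times ``1..T-tau`` with ``x_v`` at times ``tau+1..T`` is not
symmetric in ``(u, v)``, the resulting connectivity matrix defines a
weighted *digraph*.  The default lag is one timestep: the shortest
possible delay, so the coefficient captures direct rather than indirect
interaction between regions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, InvalidLagError

logger = logging.getLogger("bmhnet")

# |rho| may overshoot 1 by round-off only; anything worse is a bug upstream.
_CLIP_TOL = 1e-12


@dataclass
class ROITimeSeries:
    """Multivariate region-of-interest time series.

    Parameters
    ----------
    values : (T, N) float array
        Rows are timepoints, columns are regions (BOLD-like amplitude,
        dimensionless).
    region_ids : list of str
        N region labels, one per column.
    """

    values: np.ndarray
    region_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (T, N) array")
        T, N = self.values.shape
        if T < 3:
            raise ValueError(f"need at least 3 timepoints, got {T}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite values")
        if self.region_ids is None:
            self.region_ids = [f"R{i:03d}" for i in range(N)]
        if len(self.region_ids) != N:
            raise ValueError("region_ids length does not match column count")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass
class DirectedConnectome:
    """Asymmetric lagged-correlation matrix with its lag.

    ``rho[u, v]`` is the correlation of region ``u``'s activity with
    region ``v``'s activity ``tau`` steps later; the diagonal holds each
    region's lagged autocorrelation and is never used as an edge.
    """

    rho: np.ndarray
    tau: int
    region_ids: list[str]

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        n = self.rho.shape[0]
        if self.rho.shape != (n, n):
            raise ValueError("rho must be square")
        if len(self.region_ids) != n:
            raise ValueError("region_ids length does not match rho")
        if np.any(np.abs(self.rho) > 1 + _CLIP_TOL):
            raise ValueError("correlation entries outside [-1, 1]")

    @property
    def n_regions(self) -> int:
        return self.rho.shape[0]

    def offdiagonal_vector(self) -> np.ndarray:
        """Row-major flattening of the off-diagonal entries (N*(N-1),)."""
        n = self.n_regions
        mask = ~np.eye(n, dtype=bool)
        return self.rho[mask]


def _window_stats(x: np.ndarray) -> tuple[float, float]:
    mu = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    return mu, sd


def lagged_pcc(x_u: np.ndarray, x_v: np.ndarray, tau: int) -> float:
    """Lagged Pearson correlation of two equal-length series.

    Correlates ``x_u`` restricted to steps ``1..T-tau`` with ``x_v``
    restricted to steps ``tau+1..T``, using the sample mean and sample
    standard deviation (divisor ``T-tau-1``) of each window.  ``tau=0``
    recovers the ordinary Pearson correlation.
    """
    x_u = np.asarray(x_u, dtype=float)
    x_v = np.asarray(x_v, dtype=float)
    if x_u.shape != x_v.shape or x_u.ndim != 1:
        raise ValueError("x_u and x_v must be 1-D series of equal length")
    T = x_u.shape[0]
    if tau < 0 or tau >= T - 1:
        raise InvalidLagError(f"lag tau={tau} invalid for series of length {T}")
    a = x_u[: T - tau]
    b = x_v[tau:]
    mu_a, sd_a = _window_stats(a)
    mu_b, sd_b = _window_stats(b)
    if sd_a == 0.0 or sd_b == 0.0:
        raise DegenerateInputError("zero-variance window in lagged correlation")
    r = float(np.sum((a - mu_a) * (b - mu_b)) / ((T - tau - 1) * sd_a * sd_b))
    return float(np.clip(r, -1.0, 1.0))


def build_connectome(ts: ROITimeSeries, tau: int = 1) -> DirectedConnectome:
    """Build the directed fully connected connectome of a time series.

    Entry ``(u, v)`` is ``lagged_pcc(column u, column v, tau)``; the
    diagonal stores each region's lagged autocorrelation.  Raises
    :class:`DegenerateInputError` naming the offending region if any
    window is constant.
    """
    T = ts.n_timepoints
    if tau < 0 or tau >= T - 1:
        raise InvalidLagError(f"lag tau={tau} invalid for series of length {T}")
    early = ts.values[: T - tau]
    late = ts.values[tau:]
    sd_e = np.std(early, axis=0, ddof=1)
    sd_l = np.std(late, axis=0, ddof=1)
    for sd, which in ((sd_e, "leading"), (sd_l, "trailing")):
        bad = np.nonzero(sd == 0.0)[0]
        if bad.size:
            names = ", ".join(ts.region_ids[i] for i in bad)
            raise DegenerateInputError(
                f"zero-variance {which} window for region(s): {names}"
            )
    ez = (early - early.mean(axis=0)) / sd_e
    lz = (late - late.mean(axis=0)) / sd_l
    rho = ez.T @ lz / (T - tau - 1)
    np.clip(rho, -1.0, 1.0, out=rho)
    return DirectedConnectome(rho=rho, tau=tau, region_ids=list(ts.region_ids))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_timeseries(path: str | Path, delimiter: str | None = None) -> ROITimeSeries:
    """Read a delimited (T, N) matrix; a non-numeric first row is a header."""
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, header=None, engine="python")
    first = df.iloc[0]
    has_header = not all(_is_number(v) for v in first)
    if has_header:
        labels = [str(v) for v in first]
        df = df.iloc[1:]
    else:
        labels = None
    values = df.to_numpy(dtype=float)
    return ROITimeSeries(values=values, region_ids=labels)


def write_timeseries(ts: ROITimeSeries, path: str | Path, delimiter: str = ",") -> None:
    pd.DataFrame(ts.values, columns=ts.region_ids).to_csv(
        path, sep=delimiter, index=False
    )


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def write_connectome(conn: DirectedConnectome, path: str | Path) -> None:
    """CSV matrix with region labels plus a JSON sidecar recording tau."""
    path = Path(path)
    pd.DataFrame(conn.rho, index=conn.region_ids, columns=conn.region_ids).to_csv(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"tau": conn.tau}))


def read_connectome(path: str | Path) -> DirectedConnectome:
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    sidecar = path.with_suffix(path.suffix + ".json")
    tau = json.loads(sidecar.read_text())["tau"] if sidecar.exists() else 1
    return DirectedConnectome(
        rho=df.to_numpy(dtype=float), tau=tau, region_ids=[str(c) for c in df.columns]
    )
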