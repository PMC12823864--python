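"""Synthetic inputs: worked-example fixture, random quasimetric spaces,
VAR(1) time series with directed coupling, and two-class cohorts.

The vector-autoregressive generator emulates the one statistical
feature the lagged-correlation connectome is designed to detect:
directed lag-1 coupling between regions.  Subjects are grouped into
subnetwork-structured cohorts whose classes differ in within-subnetwork
coupling density, so that both the vectorized connectome and the
subnetwork Betti curves carry class signal.  No haemodynamics, scanner
or site effects are simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectome import ROITimeSeries
from .curves import SUBNETWORKS, SubnetworkPartition
from .exceptions import NonStationaryError
from .quasimetric import QuasimetricSpace, WeightedDigraph, shortest_path_closure

#: Canonical weights of the worked five-node example digraph.
EXAMPLE1_EDGES: dict[tuple[int, int], float] = {
    (0, 1): 0.1,
    (0, 3): 0.1,
    (2, 3): 0.1,
    (1, 2): 0.2,
    (1, 4): 0.2,
    (2, 4): 0.3,
}


def example1_graph(
    weights: dict[tuple[int, int], float] | None = None
) -> WeightedDigraph:
    """The five-node worked-example digraph.

    Six directed edges: three of weight 0.1 (v0->v1, v0->v3, v2->v3),
    two of weight 0.2 (v1->v2, v1->v4) and one of weight 0.3 (v2->v4).
    Its blurred magnitude Betti curves on the grid (0, 0.1, ..., 0.5)
    are beta0 = (5,2,1,1,1,1) and beta1 = (0,0,1,2,2,1).  ``weights``
    may override edge weights (same edge set) for perturbation studies.
    """
    edges = dict(EXAMPLE1_EDGES)
    if weights is not None:
        if set(weights) != set(edges):
            raise ValueError("weights must cover exactly the fixture edge set")
        edges = dict(weights)
    return WeightedDigraph(n_nodes=5, edges=edges)


def random_quasimetric(n: int, seed: int) -> QuasimetricSpace:
    """Random closed quasimetric space on n nodes.

    Draws an asymmetric nonnegative matrix (uniform on [0.05, 1)) with
    zero diagonal and applies shortest-path closure, so the output
    always passes the axiom check.
    """
    if n < 2:
        raise ValueError("need at least 2 nodes")
    rng = np.random.default_rng(seed)
    dt = rng.uniform(0.05, 1.0, size=(n, n))
    np.fill_diagonal(dt, 0.0)
    return shortest_path_closure(dt)


@dataclass
class VARSpec:
    """Specification of a stationary VAR(1) process.

    ``coupling[u, v]`` is the lag-1 influence of region u on region v:
    ``x_t = coupling.T @ x_{t-1} + noise``.  Stationarity requires the
    spectral radius of the coupling matrix to be below 1.
    """

    n_regions: int
    coupling: np.ndarray
    noise_sd: float = 1.0
    T: int = 150
    seed: int = 0
    burn_in: int = 100

    def __post_init__(self) -> None:
        self.coupling = np.asarray(self.coupling, dtype=float)
        if self.coupling.shape != (self.n_regions, self.n_regions):
            raise ValueError("coupling must be (n_regions, n_regions)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.T < 50:
            raise ValueError("T must be at least 50")


def var1_timeseries(spec: VARSpec) -> ROITimeSeries:
    """Simulate a VAR(1) series, discarding a burn-in prefix."""
    radius = float(np.max(np.abs(np.linalg.eigvals(spec.coupling))))
    if radius >= 1.0:
        raise NonStationaryError(
            f"coupling spectral radius {radius:.3f} >= 1"
        )
    rng = np.random.default_rng(spec.seed)
    n = spec.n_regions
    total = spec.T + spec.burn_in
    x = np.zeros((total, n))
    x[0] = rng.normal(0.0, spec.noise_sd, size=n)
    A = spec.coupling.T
    noise = rng.normal(0.0, spec.noise_sd, size=(total, n))
    for t in range(1, total):
        x[t] = A @ x[t - 1] + noise[t]
    return ROITimeSeries(values=x[spec.burn_in:])


# ---------------------------------------------------------------------------
# Two-class cohorts with subnetwork-structured coupling
# ---------------------------------------------------------------------------

@dataclass
class CouplingSpec:
    """Within-subnetwork random coupling generator for one class.

    ``density`` is the probability that an ordered within-subnetwork
    region pair carries a directed coupling (a scalar, or a per-
    subnetwork dict); ``strength`` is the coupling weight, jittered by
    +-20% per edge.  ``self_decay`` puts temporal autocorrelation on
    the diagonal.
    """

    density: float | dict[str, float] = 0.3
    strength: float = 0.45
    self_decay: float = 0.2

    def density_of(self, subnetwork: str) -> float:
        if isinstance(self.density, dict):
            return float(self.density.get(subnetwork, 0.0))
        return float(self.density)


def default_partition(n_per_subnetwork: int = 4) -> SubnetworkPartition:
    """Synthetic partition: n_per regions per subnetwork, canonical order."""
    mapping = {}
    i = 0
    for sub in SUBNETWORKS:
        for _ in range(n_per_subnetwork):
            mapping[f"R{i:03d}"] = sub
            i += 1
    return SubnetworkPartition(mapping=mapping)


@dataclass
class CohortSpec:
    """Two-class cohort of VAR(1) subjects sharing a region layout."""

    n_subjects: tuple[int, int] = (20, 20)
    class0: CouplingSpec = field(default_factory=lambda: CouplingSpec(density=0.15))
    class1: CouplingSpec = field(default_factory=lambda: CouplingSpec(density=0.55))
    partition: SubnetworkPartition = field(default_factory=default_partition)
    noise_sd: float = 1.0
    T: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_subjects) < 1:
            raise ValueError("both classes must be non-empty")


def _subject_coupling(cls_spec: CouplingSpec, partition: SubnetworkPartition,
                      region_order: list[str], rng: np.random.Generator) -> np.ndarray:
    n = len(region_order)
    idx = {r: i for i, r in enumerate(region_order)}
    C = np.zeros((n, n))
    np.fill_diagonal(C, cls_spec.self_decay)
    for sub in SUBNETWORKS:
        regions = partition.regions_of(sub, region_order)
        p = cls_spec.density_of(sub)
        for a in regions:
            for b in regions:
                if a == b:
                    continue
                if rng.random() < p:
                    C[idx[a], idx[b]] = cls_spec.strength * rng.uniform(0.8, 1.2)
    radius = float(np.max(np.abs(np.linalg.eigvals(C))))
    if radius >= 0.95:
        C *= 0.9 / radius  # keep the process comfortably stationary
    return C


@dataclass
class Cohort:
    subjects: list[ROITimeSeries]
    labels: np.ndarray
    partition: SubnetworkPartition


def make_cohort(spec: CohortSpec) -> Cohort:
    """Generate a labeled two-class cohort, seed-deterministic.

    Per-subject seeds are derived from the cohort seed so individual
    subjects are reproducible regardless of generation order.
    """
    region_order = list(spec.partition.mapping)
    root = np.random.SeedSequence(spec.seed)
    subject_seeds = root.spawn(sum(spec.n_subjects))
    subjects: list[ROITimeSeries] = []
    labels = []
    k = 0
    for label, cls_spec, count in (
        (0, spec.class0, spec.n_subjects[0]),
        (1, spec.class1, spec.n_subjects[1]),
    ):
        for _ in range(count):
            rng = np.random.default_rng(subject_seeds[k])
            C = _subject_coupling(cls_spec, spec.partition, region_order, rng)
            series_seed = int(rng.integers(0, 2**31 - 1))
            ts = var1_timeseries(
                VARSpec(
                    n_regions=len(region_order), coupling=C,
                    noise_sd=spec.noise_sd, T=spec.T, seed=series_seed,
                )
            )
            ts.region_ids = list(region_order)
            subjects.append(ts)
            labels.append(label)
            k += 1
    return Cohort(subjects=subjects, labels=np.array(labels, dtype=int),
                  partition=spec.partition)


def injected_cohort_spec(seed: int, target: str = "DMN",
                         n_subjects: tuple[int, int] = (20, 20),
                         base_density: float = 0.2,
                         injected_density: float = 0.7) -> CohortSpec:
    """Cohort whose class difference lives in a single subnetwork.

    Both classes share the base coupling density everywhere except the
    target subnetwork, where class 1 is denser — the setup used to
    check that gradient importance ranks the informative subnetwork
    first.
    """
    d0 = {s: base_density for s in SUBNETWORKS}
    d1 = dict(d0)
    d1[target] = injected_density
    return CohortSpec(
        n_subjects=n_subjects,
        class0=CouplingSpec(density=d0),
        class1=CouplingSpec(density=d1),
        seed=seed,
    )
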