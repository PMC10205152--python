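"""Mass-univariate cluster-based permutation statistics.

One-sample (one-sided) tests over sensors for unique predictive power, and
paired (two-sided) tests over time for mTRF global field power.  The cluster
test thresholds pointwise t values at the t equivalent to uncorrected
p <= 0.05, sums t within adjacency-connected clusters (cluster mass), and
compares each observed mass against the distribution of the maximum cluster
mass under sign-flipping of whole subjects.  When the complete set of sign
flips (2^n) is no larger than the requested permutation count, it is
enumerated exactly — p values are then exact multiples of 2^-n and the
result is seed-independent.  The identity flip is always part of the null
set, so p > 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats
from scipy.spatial import Delaunay, QhullError

from .errors import ConfigError, DataError

__all__ = [
    "SensorAdjacency",
    "Cluster",
    "ClusterResult",
    "cluster_test_one_sample",
    "cluster_test_paired",
    "gfp",
]


@dataclass
class SensorAdjacency:
    """Symmetric neighbour structure over named channels."""

    names: tuple[str, ...]
    neighbors: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for ch in self.names:
            if ch not in self.neighbors:
                raise DataError(f"channel {ch!r} missing from adjacency")
            if ch in self.neighbors[ch]:
                raise DataError(f"channel {ch!r} is its own neighbour")
            for nb in self.neighbors[ch]:
                if ch not in self.neighbors.get(nb, frozenset()):
                    raise DataError(f"adjacency not symmetric: {ch!r}/{nb!r}")

    @classmethod
    def from_edges(
        cls, names: list[str], edges: list[tuple[str, str]]
    ) -> "SensorAdjacency":
        nb: dict[str, set[str]] = {ch: set() for ch in names}
        for a, b in edges:
            if a == b:
                continue
            nb[a].add(b)
            nb[b].add(a)
        return cls(tuple(names), {ch: frozenset(s) for ch, s in nb.items()})

    @classmethod
    def from_coords(
        cls,
        names: list[str],
        coords: np.ndarray,
        max_distance: float | None = None,
    ) -> "SensorAdjacency":
        """Delaunay-neighbour graph on 2-D positions, with a distance
        threshold fallback for degenerate layouts."""
        coords = np.asarray(coords, dtype=float)
        edges: list[tuple[str, str]] = []
        try:
            tri = Delaunay(coords)
            for simplex in tri.simplices:
                for i in range(len(simplex)):
                    for j in range(i + 1, len(simplex)):
                        edges.append((names[simplex[i]], names[simplex[j]]))
        except (QhullError, ValueError):
            if max_distance is None:
                d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
                max_distance = 1.5 * np.median(d[d > 0]) if np.any(d > 0) else 1.0
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    if np.linalg.norm(coords[i] - coords[j]) <= max_distance:
                        edges.append((names[i], names[j]))
        if max_distance is not None:
            edges = [
                (a, b)
                for a, b in edges
                if np.linalg.norm(
                    coords[names.index(a)] - coords[names.index(b)]
                )
                <= max_distance
            ]
        return cls.from_edges(names, edges)

    def index_neighbors(self) -> list[np.ndarray]:
        idx = {ch: i for i, ch in enumerate(self.names)}
        return [
            np.asarray(sorted(idx[nb] for nb in self.neighbors[ch]), dtype=int)
            for ch in self.names
        ]

    @classmethod
    def chain(cls, n: int, prefix: str = "t") -> "SensorAdjacency":
        """1-D (temporal) adjacency: each point neighbours its predecessor
        and successor."""
        names = [f"{prefix}{i}" for i in range(n)]
        edges = [(names[i], names[i + 1]) for i in range(n - 1)]
        return cls.from_edges(names, edges)


@dataclass
class Cluster:
    members: tuple[int, ...]
    member_names: tuple[str, ...]
    mass: float
    t_max: float
    p: float


@dataclass
class ClusterResult:
    """Clusters with mass statistics and permutation p values."""

    clusters: list[Cluster]
    t_values: np.ndarray
    threshold: float
    n_permutations: int
    complete_enumeration: bool
    tail: str

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p <= alpha]


def _components(mask: np.ndarray, neighbors: list[np.ndarray]) -> list[np.ndarray]:
    """Connected components of the supra-threshold set under adjacency."""
    comps = []
    seen = np.zeros(mask.size, dtype=bool)
    for start in np.flatnonzero(mask):
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        comp = []
        while stack:
            v = stack.pop()
            comp.append(v)
            for nb in neighbors[v]:
                if mask[nb] and not seen[nb]:
                    seen[nb] = True
                    stack.append(nb)
        comps.append(np.asarray(sorted(comp)))
    return comps


def _sign_matrix(
    n_subjects: int, n_perm: int, seed
) -> tuple[np.ndarray, bool]:
    """Sign-flip null set; complete enumeration when 2^n <= n_perm."""
    if n_subjects <= 30 and 2**n_subjects <= n_perm:
        bits = np.arange(2**n_subjects)[:, None] >> np.arange(n_subjects) & 1
        return np.where(bits == 1, -1.0, 1.0), True
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_subjects))
    signs[0] = 1.0  # identity flip is always a member of the null set
    return signs, False


def _t_one_sample(x: np.ndarray) -> np.ndarray:
    """t statistic against 0 per column of a (subjects x points) array."""
    n = x.shape[0]
    m = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (sd / np.sqrt(n))
    return np.where(sd == 0, np.where(m == 0, 0.0, np.sign(m) * np.inf), t)


def _masses(
    t: np.ndarray, thr: float, neighbors: list[np.ndarray], tail: str
) -> list[tuple[np.ndarray, float]]:
    out = []
    if tail in ("greater", "two-sided"):
        for comp in _components(t >= thr, neighbors):
            out.append((comp, float(t[comp].sum())))
    if tail in ("less", "two-sided"):
        for comp in _components(t <= -thr, neighbors):
            out.append((comp, float(t[comp].sum())))
    return out


def _cluster_test(
    x: np.ndarray,
    adjacency: SensorAdjacency,
    tail: str,
    alpha_form: float,
    n_perm: int,
    seed,
) -> ClusterResult:
    n_subj, n_points = x.shape
    if n_subj < 2:
        raise DataError("cluster test requires at least 2 subjects")
    if len(adjacency.names) != n_points:
        raise DataError(
            f"adjacency covers {len(adjacency.names)} points, data has {n_points}"
        )
    df = n_subj - 1
    if tail == "greater":
        thr = float(sstats.t.ppf(1 - alpha_form, df))
    elif tail == "two-sided":
        thr = float(sstats.t.ppf(1 - alpha_form / 2, df))
    else:
        raise ConfigError(f"unsupported tail {tail!r}")
    neighbors = adjacency.index_neighbors()

    signs, complete = _sign_matrix(n_subj, n_perm, seed)
    n_used = signs.shape[0]
    # vectorised flipped t values: means from signs @ x, variances from the
    # flip-invariant sum of squares
    m = (signs @ x) / n_subj
    ssq = (x**2).sum(axis=0)
    var = np.maximum(ssq[None, :] - n_subj * m**2, 0.0) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        t_null = m / np.sqrt(var / n_subj)
    t_null = np.nan_to_num(t_null, nan=0.0, posinf=np.inf, neginf=-np.inf)

    # observed t is the identity flip (row 0): bit-identical arithmetic to
    # the null rows, so the identity permutation guarantees p >= 1/n_perm
    t_obs = t_null[0]
    observed = _masses(t_obs, thr, neighbors, tail)

    null_max = np.zeros(n_used)
    for i in range(n_used):
        masses = _masses(t_null[i], thr, neighbors, tail)
        if masses:
            null_max[i] = max(abs(mass) for _, mass in masses)

    clusters = []
    for comp, mass in observed:
        p = float(np.mean(null_max >= abs(mass)))
        tm = float(t_obs[comp].max() if mass > 0 else t_obs[comp].min())
        clusters.append(
            Cluster(
                members=tuple(int(i) for i in comp),
                member_names=tuple(adjacency.names[i] for i in comp),
                mass=mass,
                t_max=tm,
                p=p,
            )
        )
    clusters.sort(key=lambda c: abs(c.mass), reverse=True)
    return ClusterResult(
        clusters=clusters,
        t_values=t_obs,
        threshold=thr,
        n_permutations=n_used,
        complete_enumeration=complete,
        tail=tail,
    )


def cluster_test_one_sample(
    values: np.ndarray,
    adjacency: SensorAdjacency,
    tail: str = "greater",
    alpha_form: float = 0.05,
    n_perm: int = 10000,
    seed: int | np.random.Generator = 0,
) -> ClusterResult:
    """One-sample cluster-mass permutation test of (subjects x channels)
    values against zero.

    The cluster-forming threshold is the t value equivalent to uncorrected
    ``p <= alpha_form`` for the given tail; the null distribution is the
    maximum cluster mass over whole-subject sign flips.
    """
    return _cluster_test(np.asarray(values, float), adjacency, tail,
                         alpha_form, n_perm, seed)


def cluster_test_paired(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    adjacency: SensorAdjacency | None = None,
    tail: str = "two-sided",
    alpha_form: float = 0.05,
    n_perm: int = 10000,
    seed: int | np.random.Generator = 0,
) -> ClusterResult:
    """Paired cluster-mass permutation test of (subjects x points) conditions.

    Equivalent to a one-sample test on the paired differences, with
    condition labels flipped within subjects for the null.  With no
    adjacency given, points are treated as a time axis (contiguous
    clustering).
    """
    a = np.asarray(cond_a, dtype=float)
    b = np.asarray(cond_b, dtype=float)
    if a.shape != b.shape:
        raise DataError("paired conditions must have identical shape")
    if adjacency is None:
        adjacency = SensorAdjacency.chain(a.shape[1])
    return _cluster_test(a - b, adjacency, tail, alpha_form, n_perm, seed)


def gfp(kernels: np.ndarray, roi: list[int] | None = None) -> np.ndarray:
    """Global field power: across-channel standard deviation at each point.

    ``kernels`` is ``(n_channels, n_points)``; ``roi`` selects a channel
    subset.  Uses the population SD (classic GFP definition), so two
    channels at +a and -a give GFP = a.
    """
    kernels = np.atleast_2d(np.asarray(kernels, dtype=float))
    if roi is not None:
        if len(roi) == 0:
            raise ConfigError("ROI must be a nonempty channel subset")
        kernels = kernels[np.asarray(roi, dtype=int)]
    return kernels.std(axis=0, ddof=0)
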