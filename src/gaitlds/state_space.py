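"""State-space reconstruction from a scalar stride series.

Delay embedding with the delay chosen at the first minimum of the average
mutual information (AMI) and the dimension by global false nearest neighbours
(FNN).  The cohort pipeline by default applies one fixed parameter set to all
subjects (delays per sensor family and axis at 100 samples/stride, dimension
6), with per-subject computed parameters available by configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree


class StateSpaceError(ValueError):
    pass


#: Fixed embedding delays (samples, at 100 samples/stride) per sensor family
#: and axis, from first AMI minima on elderly-gait trunk/shank acceleration.
REFERENCE_DELAYS = {
    "trunk": {"v": 11, "ml": 8, "ap": 10},
    "shank": {"v": 9, "ml": 6, "ap": 11},
}
REFERENCE_DIMENSION = 6


@dataclass
class EmbeddingSpec:
    """Delay-embedding parameters: delay in samples, dimension, provenance."""

    delay: int
    dimension: int
    source: str = "fixed"  # "fixed" (cohort default) | "computed" (per series)

    def __post_init__(self) -> None:
        if self.delay < 1:
            raise StateSpaceError(f"delay must be >= 1, got {self.delay}")
        if self.dimension < 1:
            raise StateSpaceError(f"dimension must be >= 1, got {self.dimension}")


@dataclass
class StateTrajectory:
    """Embedded states: row t = [x(t), x(t+tau), ..., x(t+(d-1)tau)]."""

    points: np.ndarray
    spec: EmbeddingSpec
    samples_per_stride: int = 100

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


def default_embedding(sensor_id: str, axis: str) -> EmbeddingSpec:
    """Fixed cohort-default embedding for a sensor/axis pair."""
    family = "trunk" if sensor_id.startswith("trunk") else "shank"
    return EmbeddingSpec(delay=REFERENCE_DELAYS[family][axis],
                         dimension=REFERENCE_DIMENSION, source="fixed")


def _equiprobable_edges(x: np.ndarray, n_bins: int) -> np.ndarray:
    edges = np.quantile(x, np.linspace(0.0, 1.0, n_bins + 1))
    edges[0] -= 1e-12
    edges[-1] += 1e-12
    return np.unique(edges)


def average_mutual_information(x, max_lag: int, n_bins: int | None = None) -> np.ndarray:
    """AMI (bits) between a series and its lagged copy, lags 0..max_lag.

    Histogram estimator with equiprobable bins (edges at quantiles of the
    full series), ceil(N^(1/3)) bins by default.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if max_lag < 1:
        raise StateSpaceError("max_lag must be >= 1")
    if n < 10 * max_lag:
        raise StateSpaceError(f"series length {n} < 10 x max_lag ({10 * max_lag})")
    if np.std(x) < 1e-14:
        raise StateSpaceError("zero variance series")
    if n_bins is None:
        n_bins = int(np.ceil(n ** (1.0 / 3.0)))
    edges = _equiprobable_edges(x, n_bins)
    ami = np.empty(max_lag + 1)
    for lag in range(max_lag + 1):
        a = x[: n - lag]
        b = x[lag:]
        joint, _, _ = np.histogram2d(a, b, bins=(edges, edges))
        joint /= joint.sum()
        px = joint.sum(axis=1)
        py = joint.sum(axis=0)
        nz = joint > 0
        outer = np.outer(px, py)
        ami[lag] = float(np.sum(joint[nz] * np.log2(joint[nz] / outer[nz])))
    return ami


def first_minimum(ami_curve, window: int = 1) -> int:
    """Smallest lag k with ami[k] < ami[k-1] and ami[k] <= ami[k+1].

    A plateau resolves to its smallest lag.  ``window`` widens the
    neighbourhood a minimum must dominate (``window=1`` is the strict
    three-point rule); shallow AMI floors of nearly periodic signals carry
    estimator noise that a wider window rides over.  If no local minimum
    exists the global minimum is returned with a warning.
    """
    ami = np.asarray(ami_curve, dtype=float)
    if ami.size < 3:
        raise StateSpaceError("AMI curve must have length >= 3")
    if window < 1:
        raise StateSpaceError("window must be >= 1")
    for k in range(1, ami.size - 1):
        lo = max(0, k - window)
        hi = min(ami.size, k + window + 1)
        if ami[k] < ami[k - 1] and ami[k] == ami[lo:hi].min() and np.all(ami[k] <= ami[k:hi]):
            return k
    warnings.warn("AMI has no local minimum; returning the global minimum", stacklevel=2)
    return int(np.argmin(ami))


def delay_embed(x, spec: EmbeddingSpec, samples_per_stride: int = 100) -> StateTrajectory:
    """Delay-embed a scalar series; rows = N - (dimension - 1) * delay."""
    x = np.asarray(x, dtype=float)
    n = x.size
    rows = n - (spec.dimension - 1) * spec.delay
    if rows < 1:
        raise StateSpaceError(
            f"series of length {n} too short for d={spec.dimension}, tau={spec.delay} "
            f"(need >= {(spec.dimension - 1) * spec.delay + 1})"
        )
    cols = [x[j * spec.delay : j * spec.delay + rows] for j in range(spec.dimension)]
    return StateTrajectory(points=np.column_stack(cols), spec=spec,
                           samples_per_stride=samples_per_stride)


def false_nearest_neighbors(
    x,
    delay: int,
    max_dim: int = 8,
    rtol: float = 15.0,
    atol: float = 2.0,
    threshold: float = 0.01,
) -> tuple[np.ndarray, int]:
    """Fraction of false nearest neighbours per dimension and the chosen one.

    Kennel criteria: a neighbour at dimension d is false when the extra-axis
    separation exceeds ``rtol`` times the d-dimensional distance, or when the
    (d+1)-dimensional distance exceeds ``atol`` times the attractor size
    (series standard deviation).  Chosen dimension is the smallest with a
    false fraction below ``threshold`` (else ``max_dim`` with a warning).
    """
    x = np.asarray(x, dtype=float)
    ra = float(np.std(x))
    if ra < 1e-14:
        raise StateSpaceError("zero variance series")
    fractions = np.empty(max_dim)
    chosen = None
    for d in range(1, max_dim + 1):
        n_pts = x.size - d * delay  # rows valid for both d and d+1 embeddings
        if n_pts < 100:
            raise StateSpaceError(
                f"series too short for FNN at dimension {d} ({n_pts} points < 100)"
            )
        rows = np.arange(n_pts)
        xd = np.column_stack([x[j * delay : j * delay + n_pts] for j in range(d)])
        tree = cKDTree(xd)
        dist, idx = tree.query(xd, k=2)
        r = dist[:, 1]
        j = idx[:, 1]
        extra = np.abs(x[rows + d * delay] - x[j + d * delay])
        r_safe = np.maximum(r, 1e-300)
        false = (extra / r_safe > rtol) | (np.sqrt(r**2 + extra**2) / ra > atol)
        fractions[d - 1] = float(np.mean(false))
        if chosen is None and fractions[d - 1] < threshold:
            chosen = d
    if chosen is None:
        warnings.warn(
            f"FNN fraction never dropped below {threshold:.0%}; "
            f"returning max_dim={max_dim}", stacklevel=2,
        )
        chosen = max_dim
    return fractions, chosen


def computed_embedding(
    x,
    max_lag: int = 40,
    max_dim: int = 8,
    samples_per_stride: int = 100,
) -> EmbeddingSpec:
    """Per-series embedding: AMI first-minimum delay, FNN dimension."""
    ami = average_mutual_information(x, max_lag=max_lag)
    delay = max(1, first_minimum(ami, window=3))
    _, dim = false_nearest_neighbors(x, delay=delay, max_dim=max_dim)
    return EmbeddingSpec(delay=delay, dimension=max(2, dim), source="computed")
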