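"""Second-order spatial statistics for 2-D localization patterns.

Implements Ripley's K and its variance-stabilized transform
L(r) = sqrt(K(r)/pi), the centered curve L(r) - r whose maximum summarizes
cluster organization, a pairwise-distance frequency curve normalized against
seeded CSR (complete spatial randomness) nulls, and nearest-neighbor
distance analysis (NNA) whose histogram mode reflects within-cluster
density.

The K estimator is the standard unbiased count form

    K_hat(r) = |W| / (n (n - 1)) * sum_{i != j} 1(0 < d_ij <= r)

with either no edge correction or toroidal (periodic) wrapping of the
rectangular window. Under CSR, E[K(r)] = pi r^2 so L(r) - r fluctuates
around zero; clustering pushes it positive at the cluster scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

from .core import PointPattern, Window


def default_radii(r_max: float = 500.0, step: float = 5.0) -> np.ndarray:
    """Default radius grid: 0 to r_max (nm) in `step` nm increments."""
    return np.arange(0.0, r_max + step / 2, step)


@dataclass
class RipleyResult:
    r: np.ndarray
    k: np.ndarray
    l: np.ndarray
    l_minus_r: np.ndarray
    n: int
    area: float
    edge_mode: str
    peak_radius: float = field(init=False)
    peak_value: float = field(init=False)

    def __post_init__(self) -> None:
        self.peak_radius, self.peak_value = ripley_peak(self)


@dataclass
class PairFrequencyCurve:
    bin_edges: np.ndarray
    values: np.ndarray
    mode: str  # "csr_expectation" or "count"

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class NNAResult:
    distances: np.ndarray
    bin_edges: np.ndarray
    density: np.ndarray  # histogram normalized to unit area
    mode_radius: float
    mode_height: float
    n_duplicates: int


def _torus_pdist(points: np.ndarray, window: Window) -> np.ndarray:
    """Condensed pairwise distances on the window treated as a torus."""
    dx = np.abs(points[:, None, 0] - points[None, :, 0])
    dy = np.abs(points[:, None, 1] - points[None, :, 1])
    dx = np.minimum(dx, window.width - dx)
    dy = np.minimum(dy, window.height - dy)
    d = np.sqrt(dx * dx + dy * dy)
    iu = np.triu_indices(len(points), k=1)
    return d[iu]


def _pair_distances(pattern: PointPattern, edge_mode: str) -> np.ndarray:
    if edge_mode == "none":
        return pdist(pattern.points)
    if edge_mode == "torus":
        return _torus_pdist(pattern.points, pattern.window)
    raise ValueError(f"edge_mode must be 'none' or 'torus', got {edge_mode!r}")


def ripley_k(
    pattern: PointPattern,
    radii: np.ndarray | None = None,
    edge_mode: str = "none",
) -> RipleyResult:
    """Ripley's K/L curves with the peak of the centered curve L(r) - r.

    In torus mode the maximum radius must not exceed half the shorter window
    side (beyond that, wrapped distances are no longer well defined).
    """
    if pattern.n < 2:
        raise ValueError("Ripley's K requires at least 2 points")
    r = default_radii() if radii is None else np.asarray(radii, dtype=float)
    if r.ndim != 1 or len(r) == 0 or np.any(np.diff(r) <= 0) or r[0] < 0:
        raise ValueError("radii must be a nonempty ascending grid with r >= 0")
    w = pattern.window
    if edge_mode == "torus" and r[-1] > min(w.width, w.height) / 2:
        raise ValueError("torus mode requires max(radii) <= half the shorter side")

    d = np.sort(_pair_distances(pattern, edge_mode))
    n_zero = int(np.searchsorted(d, 0.0, side="right"))
    counts = np.searchsorted(d, r, side="right") - n_zero  # pairs with 0 < d <= r
    n = pattern.n
    k = w.area * 2.0 * counts / (n * (n - 1))
    l = np.sqrt(k / np.pi)
    return RipleyResult(r, k, l, l - r, n, w.area, edge_mode)


def ripley_peak(result: RipleyResult) -> tuple[float, float]:
    """(peak_radius, peak_value) of the centered curve; ties -> smaller r."""
    if len(result.l_minus_r) == 0:
        raise ValueError("empty curve")
    i = int(np.argmax(result.l_minus_r))  # argmax returns the first maximum
    return float(result.r[i]), float(result.l_minus_r[i])


def pair_distance_frequency(
    pattern: PointPattern,
    bin_width: float = 5.0,
    normalize: str = "csr_expectation",
    r_max: float | None = None,
    n_null: int = 50,
    seed: int = 0,
) -> PairFrequencyCurve:
    """Histogram of all pairwise distances, optionally CSR-normalized.

    ``csr_expectation`` divides each bin count by the mean count over
    ``n_null`` seeded CSR patterns of equal n and window, giving a curve that
    is ~1 under CSR and > 1 at distances enriched by clustering. ``count``
    returns the relative frequency (bin counts / number of pairs).
    """
    if pattern.n < 2:
        raise ValueError("need at least 2 points")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    from .synthgen import gen_csr  # local import to avoid a module cycle

    d = pdist(pattern.points)
    if r_max is None:
        r_max = float(d.max())
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    hist, _ = np.histogram(d, edges)

    if normalize == "count":
        return PairFrequencyCurve(edges, hist / len(d), "count")
    if normalize != "csr_expectation":
        raise ValueError("normalize must be 'csr_expectation' or 'count'")

    rng = np.random.default_rng(seed)
    null = np.zeros(len(edges) - 1)
    for _ in range(n_null):
        p = gen_csr(pattern.n, pattern.window, int(rng.integers(0, 2**31 - 1)))
        null += np.histogram(pdist(p.points), edges)[0]
    null /= n_null
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(null > 0, hist / null, np.nan)
    return PairFrequencyCurve(edges, values, "csr_expectation")


def nna(pattern: PointPattern, bin_width: float = 5.0) -> NNAResult:
    """Nearest-neighbor distance analysis.

    Coincident points yield zero distances; they are kept, counted, and
    surfaced as a warning rather than silently dropped.
    """
    if pattern.n < 2:
        raise ValueError("NNA requires at least 2 points")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    tree = cKDTree(pattern.points)
    d, _ = tree.query(pattern.points, k=2)
    d_nn = d[:, 1]
    n_dup = int(np.sum(d_nn == 0))
    if n_dup:
        warnings.warn(
            f"{n_dup} point(s) have a coincident nearest neighbor (d_nn = 0)",
            stacklevel=2,
        )
    edges = np.arange(0.0, d_nn.max() + bin_width, bin_width)
    if len(edges) < 2:
        edges = np.array([0.0, bin_width])
    hist, _ = np.histogram(d_nn, edges)
    density = hist / (pattern.n * bin_width)
    i = int(np.argmax(hist))
    mode_radius = float(0.5 * (edges[i] + edges[i + 1]))
    return NNAResult(d_nn, edges, density, mode_radius, float(density[i]), n_dup)
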