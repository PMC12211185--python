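"""Independent brute-force oracles used only by the tests.

Deliberately naive implementations: a full boundary-matrix reduction over
all simplices (no clearing, no bit packing), a double-loop Ripley K
estimator, a minimum-spanning-tree reference for H0 deaths, and a two-sided
t-test p-value obtained by numerically integrating the t density written
out from its gamma-function formula.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import integrate
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform


def naive_ripley_k(points: np.ndarray, area: float, radii: np.ndarray) -> np.ndarray:
    """K_hat by explicit double loop over ordered pairs."""
    points = np.asarray(points, float)
    n = len(points)
    k = np.zeros(len(radii))
    for ri, r in enumerate(radii):
        count = 0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                d = math.hypot(*(points[i] - points[j]))
                if 0 < d <= r:
                    count += 1
        k[ri] = area * count / (n * (n - 1))
    return k


def brute_persistence(points: np.ndarray, max_radius: float) -> list[tuple]:
    """Full-matrix mod-2 reduction of the radius-parameterized Rips complex.

    Returns sorted bars (dim, birth, death); zero-persistence H1 pairs are
    dropped and all H0 bars kept, matching the production convention.
    """
    points = np.asarray(points, float)
    n = len(points)
    half = squareform(pdist(points)) / 2.0

    simplices: list[tuple[float, int, tuple]] = [(0.0, 0, (v,)) for v in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if half[i, j] <= max_radius:
                simplices.append((half[i, j], 1, (i, j)))
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                b = max(half[i, j], half[i, k], half[j, k])
                if b <= max_radius:
                    simplices.append((b, 2, (i, j, k)))
    simplices.sort(key=lambda s: (s[0], s[1], s[2]))
    index = {s[2]: gi for gi, s in enumerate(simplices)}

    columns: list[set[int]] = []
    for _, dim, verts in simplices:
        if dim == 0:
            columns.append(set())
        else:
            faces = [
                tuple(v for f, v in enumerate(verts) if f != drop)
                for drop in range(len(verts))
            ]
            columns.append({index[f] for f in faces})

    low_of: dict[int, int] = {}  # pivot row -> column index
    pairs: dict[int, int] = {}  # birth simplex -> death simplex
    for gi in range(len(simplices)):
        col = columns[gi]
        while col:
            low = max(col)
            if low not in low_of:
                break
            col ^= columns[low_of[low]]
        columns[gi] = col
        if col:
            low = max(col)
            low_of[low] = gi
            pairs[low] = gi

    bars = []
    killed = set(pairs) | set(pairs.values())
    for birth_gi, death_gi in pairs.items():
        b, dim, _ = simplices[birth_gi]
        d = simplices[death_gi][0]
        if dim == 0 or d > b:
            bars.append((dim, b, d))
    for gi, (b, dim, _) in enumerate(simplices):
        if gi not in killed and not columns[gi] and dim < 2:
            bars.append((dim, b, math.inf))
    bars.sort()
    return bars


def mst_half_lengths(points: np.ndarray) -> np.ndarray:
    """Sorted halved edge lengths of the Euclidean minimum spanning tree."""
    d = squareform(pdist(np.asarray(points, float)))
    mst = minimum_spanning_tree(d)
    return np.sort(mst.data / 2.0)


def t_test_oracle(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """(t, df, two-tailed p) from the textbook pooled-variance formula.

    The p-value integrates the t density (gamma-function form) numerically.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    df = na + nb - 2
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / df
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))

    c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))

    def pdf(x: float) -> float:
        return c * (1 + x * x / df) ** (-(df + 1) / 2)

    tail, _ = integrate.quad(pdf, abs(t), math.inf)
    return t, float(df), 2 * tail
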