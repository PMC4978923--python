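"""Independent brute-force oracles used only by the test suite.

These deliberately share no code with the package: the SASA oracle uses
icosphere-subdivision sample points and an all-pairs burial loop, the
alignment oracle is a plain Gotoh dynamic program, and the hypergeometric
oracle sums the tail with exact rational arithmetic.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def icosphere_points(subdivisions: int = 5) -> np.ndarray:
    """Quasi-uniform unit-sphere points by icosahedron subdivision.

    5 subdivisions give 10 * 4**5 + 2 = 10,242 vertices.
    """
    t = (1.0 + np.sqrt(5.0)) / 2.0
    verts = [
        (-1, t, 0), (1, t, 0), (-1, -t, 0), (1, -t, 0),
        (0, -1, t), (0, 1, t), (0, -1, -t), (0, 1, -t),
        (t, 0, -1), (t, 0, 1), (-t, 0, -1), (-t, 0, 1),
    ]
    faces = [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ]
    verts = [np.array(v, dtype=float) / np.linalg.norm(v) for v in verts]
    cache: dict[tuple[int, int], int] = {}

    def midpoint(i: int, j: int) -> int:
        key = (min(i, j), max(i, j))
        if key not in cache:
            m = verts[i] + verts[j]
            verts.append(m / np.linalg.norm(m))
            cache[key] = len(verts) - 1
        return cache[key]

    for _ in range(subdivisions):
        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        faces = new_faces

    pts = np.array(verts)
    # dual-area weight per vertex: one third of each adjacent spherical
    # triangle's area, so the weighted point set integrates areas exactly
    # in the mesh limit (plain point counting is biased by vertex density)
    weights = np.zeros(len(pts))
    for a, b, c in faces:
        va, vb, vc = pts[a], pts[b], pts[c]
        num = abs(np.dot(va, np.cross(vb, vc)))
        den = 1.0 + np.dot(va, vb) + np.dot(vb, vc) + np.dot(vc, va)
        area = 2.0 * np.arctan2(num, den)  # spherical excess
        for v in (a, b, c):
            weights[v] += area / 3.0
    weights /= weights.sum()
    return pts, weights


def dense_sasa(
    coords: np.ndarray, radii: np.ndarray, probe: float = 1.4, subdivisions: int = 5
) -> np.ndarray:
    """All-pairs Shrake-Rupley with area-weighted icosphere points."""
    pts, weights = icosphere_points(subdivisions)
    expanded = radii + probe
    out = np.empty(len(coords))
    for i in range(len(coords)):
        sample = coords[i] + expanded[i] * pts
        exposed = np.ones(len(pts), dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            if np.sum((coords[i] - coords[j]) ** 2) > (expanded[i] + expanded[j]) ** 2:
                continue
            exposed &= np.sum((sample - coords[j]) ** 2, axis=1) > expanded[j] ** 2
        out[i] = weights[exposed].sum() * 4.0 * np.pi * expanded[i] ** 2
    return out


def gotoh_score(
    query: str,
    target: str,
    matrix,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> float:
    """Optimal global affine-gap alignment score.

    Convention: a gap of length k costs open + (k - 1) * extend; end gaps
    are penalized.  ``matrix`` is a callable (a, b) -> score.
    """
    n, m = len(query), len(target)
    neg = float("-inf")
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)  # gap in target (query consumed)
    Y = np.full((n + 1, m + 1), neg)  # gap in query
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix(query[i - 1], target[j - 1])
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend,
                          Y[i - 1, j] - gap_open)
            Y[i, j] = max(M[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend,
                          X[i, j - 1] - gap_open)
    return float(max(M[n, m], X[n, m], Y[n, m]))


def hypergeom_upper_tail(n_r: int, N: int, N_r: int, n: int) -> Fraction:
    """P(X >= n_r) for X ~ Hypergeometric(N, N_r, n), exact."""
    denom = comb(N, n)
    total = Fraction(0)
    for k in range(n_r, min(n, N_r) + 1):
        if n - k > N - N_r:
            continue
        total += Fraction(comb(N_r, k) * comb(N - N_r, n - k), denom)
    return total


def bh_qvalues(p: list[float]) -> list[float]:
    """Benjamini-Hochberg by hand: m*p/i with monotone cumulative minimum."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        i = m - rank_from_end
        running = min(running, m * p[idx] / i)
        q[idx] = running
    return q
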