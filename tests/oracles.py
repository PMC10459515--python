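"""Independent brute-force references used by the unit and acceptance tests.

Everything here is written naively (explicit walks, trial division, nested
loops) and stays independent of the implementation paths it checks.
"""

from __future__ import annotations

import numpy as np


def primes_up_to(limit: int) -> set[int]:
    """Sieve of Eratosthenes."""
    if limit < 2:
        return set()
    sieve = np.ones(limit + 1, dtype=bool)
    sieve[:2] = False
    for p in range(2, int(limit**0.5) + 1):
        if sieve[p]:
            sieve[p * p :: p] = False
    return set(np.flatnonzero(sieve).tolist())


def spiral_walk(n: int) -> np.ndarray:
    """Cell-by-cell Ulam spiral: turn counter-clockwise whenever possible.

    Independent of the run-length construction: after placing each number,
    try to turn to the next counter-clockwise direction; turn if that cell
    is empty, otherwise continue straight.
    """
    grid = np.zeros((n, n), dtype=int)
    r = c = (n - 1) // 2
    grid[r, c] = 1
    # image coordinates: right, up, left, down is counter-clockwise
    dirs = [(0, 1), (-1, 0), (0, -1), (1, 0)]
    d = 0
    r, c = r, c + 1  # first step right
    for v in range(2, n * n + 1):
        grid[r, c] = v
        turn = (d + 1) % 4
        tr, tc = r + dirs[turn][0], c + dirs[turn][1]
        if 0 <= tr < n and 0 <= tc < n and grid[tr, tc] == 0:
            d = turn
            r, c = tr, tc
        else:
            r, c = r + dirs[d][0], c + dirs[d][1]
    return grid


def sg_coords_bruteforce(n: int) -> list[tuple[int, tuple[int, int]]]:
    """(value, (row, col)) for Sophie Germain primes, ascending value."""
    grid = spiral_walk(n)
    ps = primes_up_to(2 * n * n + 1)
    out = []
    for r in range(n):
        for c in range(n):
            v = int(grid[r, c])
            if v in ps and (2 * v + 1) in ps:
                out.append((v, (r, c)))
    out.sort()
    return out


def relieff_naive(X, y, k):
    """Loop-based ReliefF: every instance visited once in index order.

    Range-normalizes features, finds k nearest hits and per-class misses
    by explicit distance sorting, and accumulates prior-weighted diffs.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, d = X.shape
    lo = X.min(axis=0)
    rng = X.max(axis=0) - lo
    rng[rng == 0] = 1.0
    Xn = (X - lo) / rng
    classes, counts = np.unique(y, return_counts=True)
    prior = {c: cnt / n for c, cnt in zip(classes, counts)}
    w = np.zeros(d)
    for i in range(n):
        dists = [(float(np.sqrt(((Xn[j] - Xn[i]) ** 2).sum())), j)
                 for j in range(n) if j != i]
        dists.sort()
        hits = [j for _, j in dists if y[j] == y[i]][:k]
        for f in range(d):
            w[f] -= sum(abs(Xn[j, f] - Xn[i, f]) for j in hits) / len(hits)
        for c in classes:
            if c == y[i]:
                continue
            misses = [j for _, j in dists if y[j] == c][:k]
            coef = prior[c] / (1.0 - prior[y[i]])
            for f in range(d):
                w[f] += coef * sum(abs(Xn[j, f] - Xn[i, f]) for j in misses) / len(misses)
    return w / n


def sine_amplitude(x: np.ndarray, fs: float, f: float) -> float:
    """Steady-state amplitude of the f-Hz component (middle half, projection)."""
    n = len(x)
    mid = x[n // 4 : 3 * n // 4]
    t = np.arange(n)[n // 4 : 3 * n // 4] / fs
    a = 2 * np.mean(mid * np.sin(2 * np.pi * f * t))
    b = 2 * np.mean(mid * np.cos(2 * np.pi * f * t))
    return float(np.hypot(a, b))
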