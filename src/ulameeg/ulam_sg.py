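"""Ulam spirals, Sophie Germain primes, and the feature-sampling mask.

The feature extractor reads gray tones from a time-frequency image patch at
the grid cells where Sophie Germain primes (primes ``p`` with ``2p + 1`` also
prime) land on an Ulam spiral of the patch size.  The spiral starts with 1 at
the center cell and winds outward counter-clockwise; with the convention used
here the first step goes right, the second up.  Any fixed orientation is a
coordinate permutation of any other and carries the same information; this
one is declared so that feature indices are reproducible.

Coordinates are 0-based ``(row, col)`` with the origin at the top-left,
matching image indexing everywhere else in the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = [
    "UlamSpiral",
    "SGMask",
    "is_prime",
    "is_sophie_germain",
    "ulam_spiral",
    "sg_mask",
    "sg_count",
]


def is_prime(m: int) -> bool:
    """Deterministic trial-division primality test for m >= 0."""
    if m < 0:
        raise ValueError(f"is_prime expects a nonnegative integer, got {m}")
    if m < 2:
        return False
    if m < 4:
        return True
    if m % 2 == 0:
        return False
    d = 3
    while d * d <= m:
        if m % d == 0:
            return False
        d += 2
    return True


def is_sophie_germain(p: int) -> bool:
    """True iff p is prime and 2p + 1 is prime (the "safe" companion)."""
    if p < 1:
        raise ValueError(f"is_sophie_germain expects a positive integer, got {p}")
    return is_prime(p) and is_prime(2 * p + 1)


@dataclass(frozen=True)
class UlamSpiral:
    """An n x n grid holding each of 1..n^2 exactly once, 1 at the center."""

    grid: np.ndarray
    n: int

    def __post_init__(self) -> None:
        if self.grid.shape != (self.n, self.n):
            raise ValueError("grid shape does not match n")


@dataclass(frozen=True)
class SGMask:
    """Cells of an n x n Ulam spiral holding Sophie Germain primes.

    ``coords`` and ``values`` are aligned and sorted by ascending spiral
    value, which fixes the within-patch feature ordering.
    """

    coords: tuple[tuple[int, int], ...]
    n: int
    values: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.coords)


def _check_odd(n: int) -> None:
    if n < 1 or n % 2 == 0:
        raise ValueError(
            f"Ulam spiral size must be an odd positive integer, got {n}; "
            "even sizes have no unambiguous center cell"
        )


@lru_cache(maxsize=None)
def ulam_spiral(n: int) -> UlamSpiral:
    """Build the n x n Ulam spiral (n odd).

    1 sits at the center; 2 is placed one cell to the right; the walk then
    turns counter-clockwise (up, left, down, right) with run lengths
    1, 1, 2, 2, 3, 3, ... until n^2 is placed.
    """
    _check_odd(n)
    grid = np.zeros((n, n), dtype=np.int64)
    r = c = (n - 1) // 2
    grid[r, c] = 1
    if n == 1:
        return UlamSpiral(grid=grid, n=n)
    # (dr, dc) cycle: right, up, left, down == counter-clockwise in
    # image coordinates (row grows downward).
    steps = ((0, 1), (-1, 0), (0, -1), (1, 0))
    value = 2
    run = 1
    direction = 0
    total = n * n
    while value <= total:
        for _ in range(2):  # two runs per run-length (right/up, left/down, ...)
            dr, dc = steps[direction]
            for _ in range(run):
                r += dr
                c += dc
                if 0 <= r < n and 0 <= c < n:
                    grid[r, c] = value
                value += 1
                if value > total:
                    break
            direction = (direction + 1) % 4
            if value > total:
                break
        run += 1
        if value > total:
            break
    return UlamSpiral(grid=grid, n=n)


@lru_cache(maxsize=None)
def sg_mask(n: int) -> SGMask:
    """Coordinates of every Sophie Germain prime on the n x n spiral."""
    spiral = ulam_spiral(n)
    entries = []
    for (r, c), v in np.ndenumerate(spiral.grid):
        v = int(v)
        if is_sophie_germain(v) if v >= 1 else False:
            entries.append((v, (int(r), int(c))))
    entries.sort()  # ascending spiral value => deterministic feature order
    values = tuple(v for v, _ in entries)
    coords = tuple(rc for _, rc in entries)
    return SGMask(coords=coords, n=n, values=values)


def sg_count(n: int) -> int:
    """Number of Sophie Germain primes <= n^2 (the per-patch feature count)."""
    return len(sg_mask(n))
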