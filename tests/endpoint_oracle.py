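"""Brute-force oracle for temporal closure over interval endpoints.

Independent of the package's point-algebra propagation: every interval
gets a (start, end) value pair from a small integer grid, all grid
assignments satisfying the premises are enumerated exhaustively, and a
relation is entailed iff its defining constraints hold in *every*
satisfying assignment. A weak order on 2n points always embeds into
{0..2n-1}, so a grid of 2n values per endpoint covers all endpoint
orderings of n intervals.
"""

from __future__ import annotations

from itertools import product

import numpy as np

RELATION_TYPES = ("BEFORE", "CONTAINS", "OVERLAP", "BEGINS-ON", "ENDS-ON")

_CACHE: dict[int, np.ndarray] = {}


def _assignments(n_intervals: int) -> np.ndarray:
    """All (start, end) grid assignments with start < end per interval:
    array of shape (N, 2 * n_intervals), columns s0, e0, s1, e1, ..."""
    if n_intervals in _CACHE:
        return _CACHE[n_intervals]
    grid = 2 * n_intervals
    pairs = np.array(
        [(s, e) for s in range(grid) for e in range(grid) if s < e], dtype=np.int8
    )
    k = len(pairs)
    idx = np.array(list(product(range(k), repeat=n_intervals)), dtype=np.int32)
    cols = [pairs[idx[:, i]] for i in range(n_intervals)]
    out = np.concatenate(cols, axis=1)
    _CACHE[n_intervals] = out
    return out


def _holds(v: np.ndarray, i: int, j: int, rtype: str) -> np.ndarray:
    """Boolean mask of assignments where rtype(i, j) holds."""
    s1, e1 = v[:, 2 * i], v[:, 2 * i + 1]
    s2, e2 = v[:, 2 * j], v[:, 2 * j + 1]
    if rtype == "BEFORE":
        return e1 < s2
    if rtype == "CONTAINS":
        return (s1 < s2) & (e2 < e1)
    if rtype == "OVERLAP":
        return (s1 < e2) & (s2 < e1)
    if rtype == "BEGINS-ON":
        return s1 == s2
    if rtype == "ENDS-ON":
        return e1 == e2
    raise ValueError(rtype)


_MASKS: dict[int, dict[tuple[int, int, str], np.ndarray]] = {}


def _masks(n_intervals: int) -> dict[tuple[int, int, str], np.ndarray]:
    """Per-(i, j, type) boolean masks over all grid assignments."""
    if n_intervals not in _MASKS:
        v = _assignments(n_intervals)
        _MASKS[n_intervals] = {
            (i, j, t): _holds(v, i, j, t)
            for i in range(n_intervals)
            for j in range(n_intervals)
            if i != j
            for t in RELATION_TYPES
        }
    return _MASKS[n_intervals]


def oracle_closure(
    n_intervals: int, edges: list[tuple[int, int, str]]
) -> set[tuple[int, int, str]] | None:
    """Entailed relations by exhaustive enumeration; None if the
    premises are unsatisfiable."""
    masks = _masks(n_intervals)
    premise = np.ones(len(_assignments(n_intervals)), dtype=bool)
    for e in edges:
        premise &= masks[e]
    if not premise.any():
        return None
    out: set[tuple[int, int, str]] = set()
    for key, mask in masks.items():
        # entailed iff every premise-satisfying assignment satisfies it
        if not (premise & ~mask).any():
            out.add(key)
    return out
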