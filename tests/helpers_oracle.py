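"""Independent oracles used to cross-check the alignment engine.

``oracle_local_score`` is a top-down memoized suffix recursion over explicit
gap states — a different formulation from the engine's bottom-up Gotoh
matrices.  ``exhaustive_local_score`` enumerates every alignment path with no
memoization at all and validates the oracle itself on very small strings.
"""

from __future__ import annotations

from functools import lru_cache


def oracle_local_score(a: str, b: str, score_fn, gap_open: int, gap_extend: int) -> int:
    """Best local-alignment score; affine gap of length L costs
    gap_open + L*gap_extend; empty alignment scores 0."""
    open_cost = gap_open + gap_extend

    @lru_cache(maxsize=None)
    def ext(i: int, j: int, mode: int) -> int:
        # best score obtainable by extending (or stopping) an alignment
        # whose next columns consume a[i:], b[j:]; mode: 0 after a match
        # column, 1 inside a gap in a, 2 inside a gap in b
        best = 0
        if i < len(a) and j < len(b):
            best = max(best, score_fn(a[i], b[j]) + ext(i + 1, j + 1, 0))
        if j < len(b):
            cost = gap_extend if mode == 1 else open_cost
            best = max(best, -cost + ext(i, j + 1, 1))
        if i < len(a):
            cost = gap_extend if mode == 2 else open_cost
            best = max(best, -cost + ext(i + 1, j, 2))
        return best

    best = 0
    for i in range(len(a)):
        for j in range(len(b)):
            best = max(best, ext(i, j, 0))
    ext.cache_clear()
    return best


def exhaustive_local_score(a: str, b: str, score_fn, gap_open: int, gap_extend: int) -> int:
    """Plain enumeration of every alignment path from every start pair;
    exponential, only usable on very small strings."""
    open_cost = gap_open + gap_extend
    best = 0

    def walk(i: int, j: int, mode: int, acc: int) -> None:
        nonlocal best
        if acc > best:
            best = acc
        if i < len(a) and j < len(b):
            walk(i + 1, j + 1, 0, acc + score_fn(a[i], b[j]))
        if j < len(b):
            walk(i, j + 1, 1, acc - (gap_extend if mode == 1 else open_cost))
        if i < len(a):
            walk(i + 1, j, 2, acc - (gap_extend if mode == 2 else open_cost))

    for i in range(len(a)):
        for j in range(len(b)):
            walk(i, j, 0, 0)
    return best
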