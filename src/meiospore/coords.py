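"""Coordinate conventions.

All *reported* intervals in this package are 1-based inclusive (the convention
genome papers print, e.g. ``Chr12B:1-172,535``).  Internal arithmetic that
slices sequences or tiles windows uses 0-based half-open.  These converters are
the only place the two conventions meet; everything else calls them.
"""

from __future__ import annotations


def to_zero_based(start1: int, end1: int) -> tuple[int, int]:
    """1-based inclusive ``[start1, end1]`` -> 0-based half-open ``[start0, end0)``."""
    if start1 < 1 or end1 < start1:
        raise ValueError(f"invalid 1-based interval [{start1}, {end1}]")
    return start1 - 1, end1


def to_one_based(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open ``[start0, end0)`` -> 1-based inclusive ``[start1, end1]``."""
    if start0 < 0 or end0 <= start0:
        raise ValueError(f"invalid 0-based interval [{start0}, {end0})")
    return start0 + 1, end0


def interval_length(start1: int, end1: int) -> int:
    """Length of a 1-based inclusive interval."""
    if end1 < start1:
        raise ValueError(f"end {end1} < start {start1}")
    return end1 - start1 + 1


def gap_between(end1_left: int, start1_right: int) -> int:
    """Number of bases strictly between two 1-based inclusive intervals.

    Adjacent intervals (``start1_right == end1_left + 1``) have gap 0.
    """
    return start1_right - end1_left - 1


def overlap_length(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Overlap (bp) of two 1-based inclusive intervals; 0 if disjoint."""
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)
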