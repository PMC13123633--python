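"""Coordinate conventions, centralized.

VCF positions are 1-based; annotation intervals are 0-based half-open
[start, end). Every conversion in the package goes through these helpers.
"""

from __future__ import annotations

__all__ = ["to_zero_based", "point_in_interval", "gap_to_interval"]


def to_zero_based(pos1: int) -> int:
    """1-based point position → 0-based."""
    if pos1 < 1:
        raise ValueError("1-based positions start at 1")
    return pos1 - 1


def point_in_interval(pos1: int, start0: int, end0: int) -> bool:
    """Does a 1-based point fall inside a 0-based half-open interval?"""
    return start0 <= to_zero_based(pos1) < end0


def gap_to_interval(pos1: int, start0: int, end0: int) -> int:
    """bp gap from a 1-based point to a 0-based half-open interval (0 inside).

    One bp past the interval end is a gap of 1; one bp before its start is
    likewise a gap of 1.
    """
    p = to_zero_based(pos1)
    if p < start0:
        return start0 - p
    if p >= end0:
        return p - end0 + 1
    return 0
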