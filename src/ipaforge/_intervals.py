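"""Strand-agnostic interval arithmetic on 0-based half-open intervals.

All functions take and return lists of ``(start, end)`` tuples with
``start < end``. Inputs need not be sorted; outputs are sorted and disjoint.
"""

from __future__ import annotations


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of intervals as a minimal sorted disjoint list."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def subtract_intervals(
    a: list[tuple[int, int]], b: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Set difference ``a \\ b``."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    out: list[tuple[int, int]] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def intersect_intervals(
    a: list[tuple[int, int]], b: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Set intersection of two interval lists."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def total_length(intervals: list[tuple[int, int]]) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))


def point_in_intervals(pos: int, intervals: list[tuple[int, int]]) -> bool:
    return any(s <= pos < e for s, e in intervals)
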