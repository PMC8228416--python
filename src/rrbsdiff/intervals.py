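"""Minimal interval arithmetic on 0-based half-open [start, end) intervals.

All genome feature queries in the package (promoter windows, exons, CpG
islands and shores) reduce to membership in a merged, sorted interval set,
which numpy searchsorted answers in O(log n) per point.
"""

from __future__ import annotations

import numpy as np


def merge_intervals(starts, ends) -> tuple[np.ndarray, np.ndarray]:
    """Merge overlapping or touching half-open intervals.

    Returns sorted, disjoint (starts, ends). Touching intervals
    ([0,5) and [5,8)) are merged.
    """
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


def points_in_intervals(pos, starts, ends) -> np.ndarray:
    """Boolean membership of points in a merged, sorted interval set."""
    pos = np.asarray(pos, dtype=np.int64)
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return np.zeros(pos.shape, dtype=bool)
    idx = np.searchsorted(starts, pos, side="right") - 1
    ok = idx >= 0
    out = np.zeros(pos.shape, dtype=bool)
    out[ok] = pos[ok] < ends[idx[ok]]
    return out
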