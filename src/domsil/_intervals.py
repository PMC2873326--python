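"""Interval-union arithmetic on sorted coordinate arrays.

Coverage queries against a fixed repeat annotation are the inner loop
of the feature catalogue, so the merged union is precomputed once and
queried in O(log n) with prefix sums.
"""

from __future__ import annotations

import numpy as np


def merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge possibly overlapping [start, end) intervals into a disjoint union."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="mergesort")
    s, e = starts[order], ends[order]
    out_s, out_e = [s[0]], [e[0]]
    for i in range(1, len(s)):
        if s[i] <= out_e[-1]:
            if e[i] > out_e[-1]:
                out_e[-1] = e[i]
        else:
            out_s.append(s[i])
            out_e.append(e[i])
    return np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64)


class IntervalUnion:
    """Disjoint union of intervals supporting fast covered-length queries."""

    def __init__(self, starts, ends):
        self.starts, self.ends = merge_intervals(np.asarray(starts), np.asarray(ends))
        lengths = self.ends - self.starts
        # prefix[i] = covered bases in union intervals 0..i-1
        self.prefix = np.concatenate([[0], np.cumsum(lengths)])

    @property
    def total(self) -> int:
        return int(self.prefix[-1])

    def covered(self, start, end) -> np.ndarray:
        """Covered bases of the union within each query [start, end).

        Accepts scalars or arrays; returns int64 of the broadcast shape.
        """
        q_s = np.atleast_1d(np.asarray(start, dtype=np.int64))
        q_e = np.atleast_1d(np.asarray(end, dtype=np.int64))
        if self.starts.size == 0:
            out = np.zeros(np.broadcast(q_s, q_e).shape, dtype=np.int64)
            return out if np.ndim(start) or np.ndim(end) else out[0]
        # union intervals fully inside (lo..hi-1), partial at the edges
        lo = np.searchsorted(self.ends, q_s, side="right")
        hi = np.searchsorted(self.starts, q_e, side="left")
        full = self.prefix[np.maximum(hi, lo)] - self.prefix[lo]
        # clip the first and last union interval in range to the query
        cov = np.zeros_like(full)
        has = hi > lo
        if np.any(has):
            first_s = np.where(has, self.starts[np.minimum(lo, len(self.starts) - 1)], 0)
            last_e = np.where(has, self.ends[np.maximum(hi - 1, 0)], 0)
            trim_left = np.maximum(q_s - first_s, 0)
            trim_right = np.maximum(last_e - q_e, 0)
            cov = np.where(has, full - trim_left - trim_right, 0)
        cov = np.maximum(cov, 0)
        return cov if (np.ndim(start) or np.ndim(end)) else int(cov[0])
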