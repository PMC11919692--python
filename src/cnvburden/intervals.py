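"""Half-open genomic interval sets with vectorized coverage queries.

All coordinates in this package are 0-based, half-open (BED convention).
An :class:`IntervalSet` stores the merged, sorted intervals of one
chromosome; a :class:`GenomeIntervals` maps chromosome name to set.

The coverage queries are the hot path of the filter cascade and the
burden partitions (tens of thousands of calls x several tracks per
simulated cohort), so they are implemented with ``searchsorted`` on a
cumulative-coverage array instead of a per-query tree walk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, Mapping, Tuple

import numpy as np

__all__ = ["IntervalSet", "GenomeIntervals", "merge_intervals", "reciprocal_overlap"]


def merge_intervals(starts: np.ndarray, ends: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Sort and merge overlapping/adjacent half-open intervals."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts, ends
    if np.any(ends <= starts):
        raise ValueError("degenerate interval: end <= start")
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    # running max of ends; a new block begins where start > max(prev ends)
    run_max = np.maximum.accumulate(ends)
    new_block = np.empty(starts.size, dtype=bool)
    new_block[0] = True
    new_block[1:] = starts[1:] > run_max[:-1]
    block_id = np.cumsum(new_block) - 1
    out_starts = starts[new_block]
    out_ends = np.maximum.reduceat(ends, np.flatnonzero(new_block))
    del block_id
    return out_starts, out_ends


class IntervalSet:
    """Merged, sorted, half-open intervals on a single chromosome."""

    __slots__ = ("starts", "ends", "_cum")

    def __init__(self, starts: Iterable[int] = (), ends: Iterable[int] = ()):
        s, e = merge_intervals(np.asarray(list(starts)), np.asarray(list(ends)))
        self.starts = s
        self.ends = e
        cum = np.zeros(s.size + 1, dtype=np.int64)
        if s.size:
            np.cumsum(e - s, out=cum[1:])
        self._cum = cum

    @classmethod
    def from_pairs(cls, pairs: Iterable[Tuple[int, int]]) -> "IntervalSet":
        pairs = list(pairs)
        if not pairs:
            return cls()
        s, e = zip(*pairs)
        return cls(s, e)

    def __len__(self) -> int:
        return int(self.starts.size)

    def __iter__(self) -> Iterator[Tuple[int, int]]:
        return iter(zip(self.starts.tolist(), self.ends.tolist()))

    @property
    def total_bp(self) -> int:
        return int(self._cum[-1])

    def coverage(self, qstarts, qends) -> np.ndarray:
        """Bases of each query interval covered by this set (vectorized)."""
        qs = np.atleast_1d(np.asarray(qstarts, dtype=np.int64))
        qe = np.atleast_1d(np.asarray(qends, dtype=np.int64))
        if self.starts.size == 0:
            return np.zeros(qs.shape, dtype=np.int64)
        i0 = np.searchsorted(self.ends, qs, side="right")
        i1 = np.searchsorted(self.starts, qe, side="left")
        cov = self._cum[i1] - self._cum[i0]
        has = i0 < i1
        if np.any(has):
            left = np.clip(qs[has] - self.starts[np.minimum(i0[has], self.starts.size - 1)], 0, None)
            right = np.clip(self.ends[i1[has] - 1] - qe[has], 0, None)
            cov[has] -= left + right
        return np.clip(cov, 0, None)

    def overlaps(self, qstarts, qends) -> np.ndarray:
        """Boolean: does each query overlap the set by >=1 bp."""
        return self.coverage(qstarts, qends) > 0


@dataclass
class GenomeIntervals:
    """Per-chromosome interval sets for one annotation track."""

    by_chrom: Dict[str, IntervalSet] = field(default_factory=dict)

    @classmethod
    def from_frame(cls, df, chrom="chrom", start="start", end="end") -> "GenomeIntervals":
        out: Dict[str, IntervalSet] = {}
        for c, grp in df.groupby(chrom, sort=True):
            out[str(c)] = IntervalSet(grp[start].to_numpy(), grp[end].to_numpy())
        return cls(out)

    def get(self, chrom: str) -> IntervalSet:
        return self.by_chrom.get(chrom, _EMPTY)

    def coverage_frame(self, calls) -> np.ndarray:
        """Covered bp for each row of a calls frame (chrom/start/end columns)."""
        cov = np.zeros(len(calls), dtype=np.int64)
        idx = np.arange(len(calls))
        chroms = calls["chrom"].to_numpy()
        starts = calls["start"].to_numpy()
        ends = calls["end"].to_numpy()
        for c in np.unique(chroms):
            m = chroms == c
            cov[idx[m]] = self.get(str(c)).coverage(starts[m], ends[m])
        return cov

    def total_bp(self) -> int:
        return sum(s.total_bp for s in self.by_chrom.values())

    def to_frame(self):
        import pandas as pd

        rows = []
        for c in sorted(self.by_chrom):
            s = self.by_chrom[c]
            for a, b in s:
                rows.append((c, a, b))
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])


_EMPTY = IntervalSet()


def reciprocal_overlap(a_start, a_end, b_start, b_end) -> np.ndarray:
    """Reciprocal overlap fraction: overlap / max(len_a, len_b), vectorized.

    Both intervals must exceed a threshold on overlap/len for each; since
    overlap/max(len) <= overlap/len for both, a single comparison against
    the max-length fraction implements the usual "both >= t" rule.
    """
    a_start = np.asarray(a_start, dtype=np.int64)
    a_end = np.asarray(a_end, dtype=np.int64)
    b_start = np.asarray(b_start, dtype=np.int64)
    b_end = np.asarray(b_end, dtype=np.int64)
    ov = np.minimum(a_end, b_end) - np.maximum(a_start, b_start)
    ov = np.clip(ov, 0, None).astype(float)
    longest = np.maximum(a_end - a_start, b_end - b_start)
    return np.where(longest > 0, ov / longest, 0.0)
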