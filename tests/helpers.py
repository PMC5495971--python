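"""Shared test utilities: compact reading constructors and brute-force oracles.

The oracles here deliberately use a different algorithmic style from the
implementation (exhaustive window scans, union-find) so agreement is
meaningful.
"""

from __future__ import annotations

from datetime import datetime, timedelta
from typing import Dict, List, Sequence, Set, Tuple

from glucolog.core import CONTEXTS, Reading, ReadingWindow, TargetRange


def R(ts: str, value: float, context: str = "other", **kw) -> Reading:
    return Reading(timestamp=datetime.fromisoformat(ts), value=value, context=context, **kw)


def make_window(readings: Sequence[Reading], pad_days: float = 1.0, availability: float = 1.0) -> ReadingWindow:
    readings = sorted(readings, key=lambda r: r.timestamp)
    if not readings:
        start = datetime(2014, 1, 1)
        return ReadingWindow((), start, start + timedelta(days=50), availability)
    start = readings[0].timestamp - timedelta(days=pad_days)
    end = readings[-1].timestamp
    return ReadingWindow(tuple(readings), start, end, availability)


def brute_force_trend_runs(
    window: ReadingWindow, target: TargetRange, min_len: int = 3
) -> List[Tuple[str, str, Tuple[int, ...]]]:
    """All maximal same-direction out-of-range runs, by exhaustive window scan.

    For every context and every candidate [i, j] span of the context's
    subsequence, check that every reading is out of range in the same
    direction and that the span cannot be extended either way.
    """

    def direction(r: Reading) -> str:
        lo, hi = target.band_for(r.context)
        if r.value < lo:
            return "low"
        if r.value > hi:
            return "high"
        return "in"

    out = []
    for context in CONTEXTS:
        seq = [(i, r) for i, r in enumerate(window.readings) if r.context == context]
        n = len(seq)
        for a in range(n):
            for b in range(a + min_len - 1, n):
                dirs = {direction(r) for _, r in seq[a : b + 1]}
                if len(dirs) != 1 or "in" in dirs:
                    continue
                d = dirs.pop()
                if a > 0 and direction(seq[a - 1][1]) == d:
                    continue  # extendable left
                if b < n - 1 and direction(seq[b + 1][1]) == d:
                    continue  # extendable right
                out.append((context, d, tuple(i for i, _ in seq[a : b + 1])))
    return out


class UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        self.parent[self.find(i)] = self.find(j)


def union_find_hypo_episodes(window: ReadingWindow, mild: float = 3.4) -> int:
    """Episode count by union-find over hour-slot adjacency of all low pairs."""
    lows = [i for i, r in enumerate(window.readings) if r.value < mild]
    if not lows:
        return 0
    slots = {
        i: window.readings[i].timestamp.replace(minute=0, second=0, microsecond=0) for i in lows
    }
    uf = UnionFind(len(lows))
    for a in range(len(lows)):
        for b in range(a + 1, len(lows)):
            gap = abs((slots[lows[a]] - slots[lows[b]]).total_seconds())
            if gap <= 3600:
                uf.union(a, b)
    return len({uf.find(k) for k in range(len(lows))})
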