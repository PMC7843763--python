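"""Per-chromosome interval index with half-open overlap semantics."""

from __future__ import annotations

from collections import defaultdict
from typing import Any, Iterable

from intervaltree import IntervalTree


class IntervalIndex:
    """Searchable set of ``(chrom, start, end, payload)`` records.

    ``query`` returns exactly the payloads whose interval shares >= 1 bp with
    the query under 0-based half-open coordinates. Backed by one interval
    tree per chromosome.
    """

    def __init__(self, records: Iterable[tuple[str, int, int, Any]] = ()) -> None:
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for chrom, start, end, payload in records:
            self.add(chrom, start, end, payload)

    def add(self, chrom: str, start: int, end: int, payload: Any) -> None:
        if end <= start:
            raise ValueError(f"empty interval [{start},{end}) on {chrom}")
        self._trees[chrom].addi(start, end, payload)

    def query(self, chrom: str, start: int, end: int) -> list[Any]:
        """Payloads overlapping [start, end) by at least 1 bp."""
        if chrom not in self._trees:
            return []
        return [iv.data for iv in self._trees[chrom].overlap(start, end)]

    def query_point(self, chrom: str, pos: int) -> list[Any]:
        """Payloads covering the single base at ``pos``."""
        return self.query(chrom, pos, pos + 1)

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())
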