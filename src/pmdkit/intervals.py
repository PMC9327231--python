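"""Half-open genomic interval sets with merge/intersect/coverage algebra.

All coordinates are 0-based, half-open ``[start, end)`` (BED semantics).
An :class:`IntervalSet` stores, per chromosome, sorted non-overlapping
intervals as a pair of numpy arrays, which makes merge and point-membership
queries O(n log n) via ``searchsorted``.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = ["IntervalSet", "read_bed", "write_bed"]


def _merge_arrays(starts: np.ndarray, ends: np.ndarray, gap: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Merge sorted intervals whose separation is <= gap (bedtools -d semantics)."""
    if starts.size == 0:
        return starts, ends
    order = np.lexsort((ends, starts))
    s, e = starts[order], ends[order]
    out_s, out_e = [int(s[0])], [int(e[0])]
    for i in range(1, s.size):
        if int(s[i]) - out_e[-1] <= gap:
            out_e[-1] = max(out_e[-1], int(e[i]))
        else:
            out_s.append(int(s[i]))
            out_e.append(int(e[i]))
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


@dataclass
class IntervalSet:
    """A set of genomic intervals, normalised to sorted non-overlapping form.

    Construct via :meth:`from_records` (which merges overlaps) or pass
    pre-normalised per-chromosome arrays directly.
    """

    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, int, int]], merge_gap: int = 0
    ) -> "IntervalSet":
        acc: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in records:
            if end <= start:
                raise ValueError(f"empty or inverted interval {chrom}:{start}-{end}")
            acc.setdefault(chrom, []).append((int(start), int(end)))
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, ivs in acc.items():
            arr = np.asarray(ivs, dtype=np.int64)
            out[chrom] = _merge_arrays(arr[:, 0], arr[:, 1], gap=merge_gap)
        return cls(out)

    # -- iteration / basic ---------------------------------------------------
    def __iter__(self) -> Iterator[tuple[str, int, int]]:
        for chrom in sorted(self.by_chrom):
            s, e = self.by_chrom[chrom]
            for i in range(s.size):
                yield chrom, int(s[i]), int(e[i])

    def __len__(self) -> int:
        return sum(s.size for s, _ in self.by_chrom.values())

    def is_empty(self) -> bool:
        return len(self) == 0

    def total_length(self) -> int:
        return int(sum((e - s).sum() for s, e in self.by_chrom.values()))

    def coverage_fraction(self, chrom_sizes: Mapping[str, int]) -> float:
        """Fraction of the genome (sum of chrom_sizes) covered by this set."""
        genome = sum(chrom_sizes.values())
        if genome == 0:
            return 0.0
        return self.total_length() / genome

    # -- algebra -------------------------------------------------------------
    def merge(self, gap: int = 0) -> "IntervalSet":
        return IntervalSet(
            {c: _merge_arrays(s, e, gap=gap) for c, (s, e) in self.by_chrom.items()}
        )

    def union(self, other: "IntervalSet") -> "IntervalSet":
        return IntervalSet.from_records(list(self) + list(other))

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in self.by_chrom.keys() & other.by_chrom.keys():
            s1, e1 = self.by_chrom[chrom]
            s2, e2 = other.by_chrom[chrom]
            res_s, res_e = [], []
            i = j = 0
            while i < s1.size and j < s2.size:
                lo = max(s1[i], s2[j])
                hi = min(e1[i], e2[j])
                if lo < hi:
                    res_s.append(int(lo))
                    res_e.append(int(hi))
                if e1[i] < e2[j]:
                    i += 1
                else:
                    j += 1
            if res_s:
                out[chrom] = (
                    np.asarray(res_s, dtype=np.int64),
                    np.asarray(res_e, dtype=np.int64),
                )
        return IntervalSet(out)

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        out: list[tuple[str, int, int]] = []
        for chrom, (s1, e1) in self.by_chrom.items():
            if chrom not in other.by_chrom:
                for i in range(s1.size):
                    out.append((chrom, int(s1[i]), int(e1[i])))
                continue
            s2, e2 = other.by_chrom[chrom]
            for i in range(s1.size):
                cur = int(s1[i])
                end = int(e1[i])
                k = np.searchsorted(e2, cur, side="right")
                while k < s2.size and s2[k] < end:
                    if s2[k] > cur:
                        out.append((chrom, cur, int(s2[k])))
                    cur = max(cur, int(e2[k]))
                    k += 1
                if cur < end:
                    out.append((chrom, cur, end))
        return IntervalSet.from_records(out) if out else IntervalSet()

    # -- queries -------------------------------------------------------------
    def contains_points(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Boolean mask: which positions fall inside an interval of this set."""
        positions = np.asarray(positions, dtype=np.int64)
        if chrom not in self.by_chrom or positions.size == 0:
            return np.zeros(positions.shape, dtype=bool)
        s, e = self.by_chrom[chrom]
        idx = np.searchsorted(s, positions, side="right") - 1
        ok = idx >= 0
        res = np.zeros(positions.shape, dtype=bool)
        res[ok] = positions[ok] < e[idx[ok]]
        return res

    def overlaps_interval(self, chrom: str, start: int, end: int) -> bool:
        """True if [start, end) overlaps any interval by >= 1 bp."""
        if chrom not in self.by_chrom:
            return False
        s, e = self.by_chrom[chrom]
        i = np.searchsorted(e, start, side="right")
        return bool(i < s.size and s[i] < end)

    def overlap_length(self, chrom: str, start: int, end: int) -> int:
        """Total bp of [start, end) covered by this set."""
        if chrom not in self.by_chrom:
            return 0
        s, e = self.by_chrom[chrom]
        lo = np.maximum(s, start)
        hi = np.minimum(e, end)
        return int(np.maximum(hi - lo, 0).sum())

    def assert_disjoint(self) -> None:
        for chrom, (s, e) in self.by_chrom.items():
            if np.any(s[1:] < e[:-1]):
                raise ValueError(f"overlapping intervals on {chrom}")


def read_bed(path: str | Path) -> IntervalSet:
    """Read a 3+ column BED file (plain or gzipped) into an IntervalSet."""
    opener = gzip.open if str(path).endswith(".gz") else open
    records = []
    with opener(path, "rt") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            records.append((parts[0], int(parts[1]), int(parts[2])))
    return IntervalSet.from_records(records) if records else IntervalSet()


def write_bed(ivs: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in ivs:
            fh.write(f"{chrom}\t{start}\t{end}\n")
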