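"""Sequence-derived annotations: CpG enumeration, solo-WCGW classification,
fixed bin grids and TSS-proximity labels.

A solo-WCGW CpG sits in an A/T flanked context (W-C-G-W) and has no other
CpG within +-``window`` bp (C-to-C distance, inclusive); this CpG class is
the most informative readout of partially-methylated-domain hypomethylation.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import IntervalSet

__all__ = [
    "GenomeSequence",
    "BinGrid",
    "enumerate_cpgs",
    "classify_solo_wcgw",
    "make_bins",
    "classify_tss_proximity",
    "read_chrom_sizes",
]

_C, _G, _A, _T = (ord(b) for b in "CGAT")


@dataclass
class GenomeSequence:
    """Upper-case nucleotide sequences over {A,C,G,T,N}, one per chromosome."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        self.sequences = {c: s.upper() for c, s in self.sequences.items()}

    @property
    def chrom_names(self) -> list[str]:
        return list(self.sequences)

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeSequence":
        from pyfaidx import Fasta

        fa = Fasta(str(path), rebuild=True, build_index=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for chrom, seq in self.sequences.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


@dataclass
class BinGrid:
    """Non-overlapping fixed-width bins tiling each chromosome from 0.

    ``bins`` has columns chrom, start, end, partial (True for a trailing
    bin shorter than ``width``).
    """

    width: int
    bins: pd.DataFrame = field(repr=False)

    def __len__(self) -> int:
        return len(self.bins)

    def bin_index(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Row index into ``bins`` for each position on ``chrom`` (-1 if off-grid)."""
        positions = np.asarray(positions, dtype=np.int64)
        sub = self.bins[self.bins["chrom"] == chrom]
        if sub.empty:
            return np.full(positions.shape, -1, dtype=np.int64)
        offset = sub.index[0]
        size = int(sub["end"].iloc[-1])
        local = positions // self.width
        out = np.where((positions >= 0) & (positions < size), offset + local, -1)
        return out.astype(np.int64)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                name, size = line.split()[:2]
                sizes[name] = int(size)
    return sizes


def enumerate_cpgs(genome: GenomeSequence) -> pd.DataFrame:
    """All plus-strand CpG positions, as a frame (chrom, pos) sorted by (chrom, pos).

    ``pos`` is the 0-based position of the C. N-containing dinucleotides
    never match.
    """
    frames = []
    for chrom in genome.chrom_names:
        arr = np.frombuffer(genome.sequences[chrom].encode("ascii"), dtype=np.uint8)
        if arr.size < 2:
            continue
        hits = np.nonzero((arr[:-1] == _C) & (arr[1:] == _G))[0]
        if hits.size:
            frames.append(pd.DataFrame({"chrom": chrom, "pos": hits.astype(np.int64)}))
    if not frames:
        return pd.DataFrame({"chrom": pd.Series(dtype=str), "pos": pd.Series(dtype=np.int64)})
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def classify_solo_wcgw(
    sites: pd.DataFrame, genome: GenomeSequence, window: int = 35
) -> pd.DataFrame:
    """Flag solo-WCGW CpGs among ``sites`` (output of :func:`enumerate_cpgs`).

    A CpG qualifies iff the base before the C and the base after the G are
    both A or T, and no other CpG's C lies within ``window`` bp (inclusive,
    C-to-C). Edge CpGs with a missing flank never qualify.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    out = sites.copy()
    flags = np.zeros(len(out), dtype=bool)
    for chrom, sub in out.groupby("chrom", sort=False):
        arr = np.frombuffer(genome.sequences[chrom].encode("ascii"), dtype=np.uint8)
        pos = sub["pos"].to_numpy()
        has_flanks = (pos >= 1) & (pos + 2 < arr.size)
        wcgw = np.zeros(pos.shape, dtype=bool)
        ok = has_flanks
        left = arr[np.where(ok, pos - 1, 0)]
        right = arr[np.where(ok, pos + 2, 0)]
        wcgw[ok] = (np.isin(left[ok], (_A, _T))) & (np.isin(right[ok], (_A, _T)))
        # neighbor exclusion: nearest CpG C within +-window disqualifies
        solo = np.ones(pos.shape, dtype=bool)
        if pos.size > 1:
            d_prev = np.diff(pos, prepend=pos[0] - (window + 1))
            d_next = np.diff(pos, append=pos[-1] + (window + 1))
            solo = (d_prev > window) & (d_next > window)
        flags[sub.index] = wcgw & solo
    out["is_solo_wcgw"] = flags
    return out


def make_bins(chrom_sizes: Mapping[str, int], width: int = 100_000) -> BinGrid:
    """Tile each chromosome with ``width``-bp bins; trailing partial bin kept."""
    if width <= 0:
        raise ValueError("bin width must be positive")
    rows = []
    for chrom, size in chrom_sizes.items():
        starts = np.arange(0, size, width, dtype=np.int64)
        for s in starts:
            e = min(int(s) + width, int(size))
            rows.append((chrom, int(s), e, e - int(s) < width))
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end", "partial"])
    return BinGrid(width=width, bins=bins)


def classify_tss_proximity(
    intervals: Sequence[tuple[str, int, int]] | IntervalSet,
    tss_positions: Mapping[str, Sequence[int]],
    cutoff: int = 2000,
) -> list[str]:
    """Label each interval "promoter" (distance to nearest TSS < cutoff) or "distal".

    Distance is 0 when a TSS falls inside the interval; otherwise the gap
    between the TSS and the nearest covered base. Ties at exactly ``cutoff``
    resolve to "distal".
    """
    tss_sorted = {c: np.sort(np.asarray(p, dtype=np.int64)) for c, p in tss_positions.items()}
    if all(v.size == 0 for v in tss_sorted.values()) or not tss_sorted:
        warnings.warn("no TSS positions supplied; labeling everything distal")
    labels = []
    for chrom, start, end in intervals:
        d = tss_distance(chrom, start, end, tss_sorted)
        labels.append("promoter" if d is not None and d < cutoff else "distal")
    return labels


def tss_distance(
    chrom: str, start: int, end: int, tss_sorted: Mapping[str, np.ndarray]
) -> int | None:
    """Distance from interval [start, end) to the nearest TSS on its chromosome.

    Measured to the interval's covered bases [start, end-1]; None if the
    chromosome has no TSS.
    """
    tss = tss_sorted.get(chrom)
    if tss is None or len(tss) == 0:
        return None
    tss = np.asarray(tss)
    i = np.searchsorted(tss, start)
    best = None
    for j in (i - 1, i, np.searchsorted(tss, end - 1, side="right")):
        if 0 <= j < tss.size:
            t = int(tss[j])
            d = 0 if start <= t <= end - 1 else min(abs(t - start), abs(t - (end - 1)))
            best = d if best is None else min(best, d)
    # also check the insertion point for end-1
    j = np.searchsorted(tss, end - 1)
    if 0 <= j < tss.size:
        t = int(tss[j])
        d = 0 if start <= t <= end - 1 else min(abs(t - start), abs(t - (end - 1)))
        best = d if best is None else min(best, d)
    return best


def write_cpg_bed(sites: pd.DataFrame, path: str | Path) -> None:
    """CpG sites as 4-column BED: chrom, pos, pos+2, solo flag (0/1)."""
    df = pd.DataFrame(
        {
            "chrom": sites["chrom"],
            "start": sites["pos"],
            "end": sites["pos"] + 2,
            "solo": sites.get("is_solo_wcgw", False),
        }
    )
    df["solo"] = df["solo"].astype(int)
    df.to_csv(path, sep="\t", header=False, index=False)


def read_cpg_bed(path: str | Path) -> pd.DataFrame:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        df = pd.read_csv(
            fh, sep="\t", header=None, names=["chrom", "start", "end", "solo"]
        )
    return pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["start"].astype(np.int64),
            "is_solo_wcgw": df["solo"].astype(bool),
        }
    )
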