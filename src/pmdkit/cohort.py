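"""Cohort-level PMD analysis: per-bin PMD frequency, common-PMD derivation,
combination with external PMD catalogs, methylome masking and solo-WCGW
scoring.

"Common" PMDs (e.g. ovcaPMDs) are bins called PMD in at least
``min_samples`` cohort samples (default 10, the literal reading of
"more than 9"), merged across adjacency. The combined set — cohort-common
PMDs united with an external common-PMD catalog — is the mask applied
before downstream heterogeneity and DMR analyses, and the region over
which per-sample solo-WCGW scores are averaged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import BinGrid
from .intervals import IntervalSet
from .methylome_io import MethylomeTable
from .pmd import PMDCallSet

__all__ = [
    "PMDFrequencyMap",
    "CombinedPMDSet",
    "pmd_frequency",
    "common_pmds",
    "combine_pmd_sets",
    "mask_methylome",
    "solo_wcgw_score",
]


@dataclass
class PMDFrequencyMap:
    grid: BinGrid
    counts: np.ndarray  # per grid row: number of samples calling the bin PMD
    n_samples: int

    def to_bedgraph(self, path) -> None:
        df = self.grid.bins[["chrom", "start", "end"]].copy()
        df["count"] = self.counts
        df.to_csv(path, sep="\t", header=False, index=False)


@dataclass
class CombinedPMDSet:
    """Union of cohort-common and external PMD intervals with provenance."""

    intervals: IntervalSet
    cohort_only: IntervalSet = field(repr=False)
    external_only: IntervalSet = field(repr=False)
    both: IntervalSet = field(repr=False)

    def span_fractions(self, chrom_sizes: Mapping[str, int]) -> dict[str, float]:
        return {
            "combined": self.intervals.coverage_fraction(chrom_sizes),
            "cohort_only": self.cohort_only.coverage_fraction(chrom_sizes),
            "external_only": self.external_only.coverage_fraction(chrom_sizes),
            "both": self.both.coverage_fraction(chrom_sizes),
        }


def pmd_frequency(calls: Sequence[PMDCallSet], grid: BinGrid) -> PMDFrequencyMap:
    """Count, per bin, how many samples call that bin PMD.

    PMD calls are unions of whole bins by construction, so a bin is covered
    iff its midpoint is inside a call interval.
    """
    counts = np.zeros(len(grid.bins), dtype=np.int64)
    mids = ((grid.bins["start"] + grid.bins["end"]) // 2).to_numpy()
    chroms = grid.bins["chrom"].to_numpy()
    for call in calls:
        if not call.bin_p_high[["chrom", "start", "end"]].equals(
            grid.bins[["chrom", "start", "end"]]
        ):
            raise ValueError(f"sample {call.sample_id}: PMD calls on a different grid")
        for chrom in np.unique(chroms):
            mask = chroms == chrom
            counts[mask] += call.intervals.contains_points(chrom, mids[mask])
    return PMDFrequencyMap(grid=grid, counts=counts, n_samples=len(calls))


def common_pmds(freq: PMDFrequencyMap, min_samples: int = 10) -> IntervalSet:
    """Bins PMD in >= min_samples samples, merged across adjacency."""
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    keep = freq.counts >= min_samples
    records = [
        (r.chrom, int(r.start), int(r.end))
        for r, k in zip(freq.grid.bins.itertuples(index=False), keep)
        if k
    ]
    return IntervalSet.from_records(records) if records else IntervalSet()


def combine_pmd_sets(cohort: IntervalSet, external: IntervalSet) -> CombinedPMDSet:
    """Interval union with per-base provenance categories."""
    both = cohort.intersect(external)
    return CombinedPMDSet(
        intervals=cohort.union(external),
        cohort_only=cohort.subtract(external),
        external_only=external.subtract(cohort),
        both=both,
    )


def mask_methylome(
    table: MethylomeTable, mask: IntervalSet
) -> tuple[MethylomeTable, int]:
    """Remove records whose CpG position lies inside any mask interval.

    Returns the masked table and the number of removed records;
    |input| == |output| + removed.
    """
    mask.assert_disjoint()
    keep = np.ones(len(table.df), dtype=bool)
    for chrom, sub in table.df.groupby("chrom", sort=False):
        inside = mask.contains_points(chrom, sub["pos"].to_numpy())
        keep[sub.index] = ~inside
    out = table.df[keep].reset_index(drop=True)
    return MethylomeTable(table.sample_id, out), int((~keep).sum())


def solo_wcgw_score(
    table: MethylomeTable,
    solo_sites: pd.DataFrame,
    combined: CombinedPMDSet | IntervalSet,
) -> tuple[float, int]:
    """Mean beta over covered solo-WCGW CpGs inside the combined PMD set.

    Returns (score, n_sites); score is NaN (with a warning) when no
    in-set solo-WCGW CpG is covered.
    """
    ivs = combined.intervals if isinstance(combined, CombinedPMDSet) else combined
    solo = solo_sites[solo_sites.get("is_solo_wcgw", True) == True]  # noqa: E712
    keys = pd.MultiIndex.from_frame(solo[["chrom", "pos"]])
    df = table.df.set_index(["chrom", "pos"])
    hit = df[df.index.isin(keys)].reset_index()
    betas = []
    for chrom, sub in hit.groupby("chrom", sort=False):
        inside = ivs.contains_points(chrom, sub["pos"].to_numpy())
        betas.append(sub["beta"].to_numpy()[inside])
    vals = np.concatenate(betas) if betas else np.array([])
    if vals.size == 0:
        warnings.warn(
            f"sample {table.sample_id}: no covered solo-WCGW CpGs inside the PMD set"
        )
        return float("nan"), 0
    return float(vals.mean()), int(vals.size)
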