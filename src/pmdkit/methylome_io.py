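"""Per-CpG methylation call tables: reading, validation, coverage filtering
and strand collapsing.

Two text dialects are supported:

``biscuit-bed``
    chrom, start, end, beta (fraction in [0,1]), coverage — the 5-column
    BED emitted by BISCUIT-style callers.
``bedgraph+coverage``
    chrom, start, end, methylation percentage in [0,100], coverage — the
    Bismark-coverage-style variant.

Records are keyed by the 0-based position of the measured cytosine. Missing
CpGs (uncovered or filtered) are absent records, never zeros: downstream
code must distinguish "unmethylated" from "unobserved".
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MethylomeTable",
    "read_methylome",
    "write_methylome",
    "filter_by_coverage",
    "merge_strands",
]

_COLUMNS = ["chrom", "pos", "beta", "coverage"]


@dataclass
class MethylomeTable:
    """One sample's methylation calls, sorted by (chrom, pos)."""

    sample_id: str
    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"methylome table missing columns {missing}")
        df = self.df[_COLUMNS]
        if not df["pos"].is_monotonic_increasing or df["chrom"].nunique() > 1:
            df = df.sort_values(["chrom", "pos"], kind="mergesort")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def copy(self) -> "MethylomeTable":
        return MethylomeTable(self.sample_id, self.df.copy())


def _sorted(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def read_methylome(
    path: str | Path, dialect: str = "biscuit-bed", sample_id: str | None = None
) -> MethylomeTable:
    """Parse, validate and sort a per-CpG methylation file.

    Malformed lines raise with their 1-based line number; beta outside
    [0,1] (after percentage conversion) is a hard error. Unsorted input is
    sorted with a warning.
    """
    if dialect not in ("biscuit-bed", "bedgraph+coverage"):
        raise ValueError(f"unknown dialect {dialect!r}")
    opener = gzip.open if str(path).endswith(".gz") else open
    chroms: list[str] = []
    poss: list[int] = []
    betas: list[float] = []
    covs: list[int] = []
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ValueError(f"{path}: line {lineno}: expected 5 columns, got {len(parts)}")
            try:
                pos = int(parts[1])
                value = float(parts[3])
                cov = int(parts[4])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
            beta = value / 100.0 if dialect == "bedgraph+coverage" else value
            if not 0.0 <= beta <= 1.0:
                raise ValueError(
                    f"{path}: line {lineno}: beta {beta:g} outside [0, 1]"
                )
            if cov < 0:
                raise ValueError(f"{path}: line {lineno}: negative coverage")
            chroms.append(parts[0])
            poss.append(pos)
            betas.append(beta)
            covs.append(cov)
    df = pd.DataFrame(
        {
            "chrom": pd.Series(chroms, dtype=str),
            "pos": pd.Series(poss, dtype=np.int64),
            "beta": pd.Series(betas, dtype=float),
            "coverage": pd.Series(covs, dtype=np.int64),
        }
    )
    srt = _sorted(df)
    if not df["pos"].equals(srt["pos"]) or not df["chrom"].equals(srt["chrom"]):
        warnings.warn(f"{path}: records out of coordinate order; sorting")
    sid = sample_id if sample_id is not None else Path(path).stem.replace(".bed", "")
    return MethylomeTable(sid, srt)


def write_methylome(
    table: MethylomeTable, path: str | Path, dialect: str = "biscuit-bed"
) -> None:
    """Write with deterministic column order and float formatting."""
    scale = 100.0 if dialect == "bedgraph+coverage" else 1.0
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for row in table.df.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.pos + 1}\t"
                f"{row.beta * scale:.6g}\t{row.coverage}\n"
            )


def filter_by_coverage(table: MethylomeTable, min_cov: int = 5) -> MethylomeTable:
    """Drop records with fewer than ``min_cov`` reads; order preserved."""
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    kept = table.df[table.df["coverage"] >= min_cov].reset_index(drop=True)
    return MethylomeTable(table.sample_id, kept)


def merge_strands(
    table: MethylomeTable, cpg_sites: pd.DataFrame
) -> tuple[MethylomeTable, int]:
    """Collapse plus/minus strand records onto the CpG's plus-strand C.

    For a CpG whose C sits at plus-strand position p, records at p and p+1
    are pooled: coverage is summed and beta becomes the coverage-weighted
    mean (equivalent to recomputing beta from pooled read counts). Records
    at positions that are neither p nor p+1 of any CpG are dropped; their
    count is returned. Idempotent, and conserves total read mass over
    retained records.
    """
    out_frames = []
    n_dropped = 0
    for chrom, sub in table.df.groupby("chrom", sort=False):
        sites = cpg_sites.loc[cpg_sites["chrom"] == chrom, "pos"].to_numpy(np.int64)
        if sites.size == 0:
            n_dropped += len(sub)
            continue
        pos = sub["pos"].to_numpy(np.int64)
        idx = np.searchsorted(sites, pos, side="right") - 1
        idx_clamped = np.clip(idx, 0, sites.size - 1)
        anchor = sites[idx_clamped]
        valid = (idx >= 0) & ((pos == anchor) | (pos == anchor + 1))
        n_dropped += int((~valid).sum())
        if not valid.any():
            continue
        sub = sub[valid]
        key = anchor[valid]
        cov = sub["coverage"].to_numpy(float)
        meth_mass = sub["beta"].to_numpy(float) * cov
        grp = pd.DataFrame({"pos": key, "cov": cov, "mass": meth_mass}).groupby(
            "pos", sort=True
        )
        agg = grp.sum()
        total_cov = agg["cov"].to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            beta = np.where(total_cov > 0, agg["mass"].to_numpy() / total_cov, np.nan)
        out_frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": agg.index.to_numpy(np.int64),
                    "beta": beta,
                    "coverage": total_cov.astype(np.int64),
                }
            )
        )
    if out_frames:
        merged = _sorted(pd.concat(out_frames, ignore_index=True))
    else:
        merged = table.df.iloc[0:0].copy()
    return MethylomeTable(table.sample_id, merged), n_dropped
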