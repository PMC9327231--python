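"""Linking DMRs to candidate target genes through methylation-expression
correlation.

Transcripts are filtered by length, abundance and isoform share; gene
expression is summarised as log2(sum of retained transcript TPMs + 1).
DMRs within 2 kb of a TSS are "promoter" regions linked only to the
closest gene; "distal" DMRs are linked to up to 10 genes on each side.
Per candidate link, Spearman correlation is computed over per-patient
(delta methylation, delta expression) pairs restricted to the patients in
which the DMR was identified, and links with two-sided p < 0.05 are
retained. Benjamini-Hochberg q-values are reported alongside raw p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import IntervalSet

__all__ = [
    "TranscriptTable",
    "filter_transcripts",
    "gene_expression",
    "candidate_genes",
    "correlate_links",
    "correlate_all_links",
    "LinkCandidate",
]


@dataclass
class TranscriptTable:
    """Transcript annotations plus per-sample TPM and isoform-percentage matrices.

    ``info`` columns: transcript_id, gene_id, chrom, start, end, length.
    ``tpm`` and ``isoform_pct`` are transcripts x samples frames sharing
    the transcript_id index.
    """

    info: pd.DataFrame = field(repr=False)
    tpm: pd.DataFrame = field(repr=False)
    isoform_pct: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        ids = self.info["transcript_id"]
        if not (self.tpm.index.equals(pd.Index(ids)) and self.isoform_pct.index.equals(pd.Index(ids))):
            self.tpm = self.tpm.loc[ids]
            self.isoform_pct = self.isoform_pct.loc[ids]

    def __len__(self) -> int:
        return len(self.info)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.tpm.columns)


def filter_transcripts(
    table: TranscriptTable,
    min_len: int = 300,
    min_tpm: float = 0.05,
    min_isoform_pct: float = 1.0,
    min_samples: int = 6,
    blacklist: IntervalSet | None = None,
) -> TranscriptTable:
    """Artifact/low-expression transcript filter.

    Keeps transcripts with length > min_len that are expressed — TPM >
    min_tpm AND isoform percentage > min_isoform_pct — in at least
    ``min_samples`` samples, and that do not overlap any blacklist
    interval. All thresholds are strict inequalities; tightening any of
    them never adds transcripts.
    """
    info = table.info
    keep = info["length"] > min_len
    expressed = (table.tpm.to_numpy() > min_tpm) & (
        table.isoform_pct.to_numpy() > min_isoform_pct
    )
    keep &= pd.Series(expressed.sum(axis=1) >= min_samples, index=info.index)
    if blacklist is not None and not blacklist.is_empty():
        hit = info.apply(
            lambda r: blacklist.overlaps_interval(r["chrom"], int(r["start"]), int(r["end"])),
            axis=1,
        )
        keep &= ~hit
    sub = info[keep].reset_index(drop=True)
    return TranscriptTable(
        info=sub,
        tpm=table.tpm.loc[sub["transcript_id"]],
        isoform_pct=table.isoform_pct.loc[sub["transcript_id"]],
    )


def gene_expression(table: TranscriptTable) -> pd.DataFrame:
    """Per-gene expression: log2(sum of retained transcript TPMs + 1).

    Returns genes x samples.
    """
    tpm = table.tpm.copy()
    tpm["gene_id"] = table.info.set_index("transcript_id").loc[tpm.index, "gene_id"].to_numpy()
    summed = tpm.groupby("gene_id").sum()
    return np.log2(summed + 1.0)


@dataclass
class LinkCandidate:
    dmr: tuple[str, int, int]
    context: str  # promoter | distal
    gene_id: str
    distance: int
    rank: int  # signed: negative upstream, positive downstream, 0 overlapping


def candidate_genes(
    dmr: tuple[str, int, int],
    tss_table: pd.DataFrame,
    context_cutoff: int = 2000,
    n_each_side: int = 10,
) -> list[LinkCandidate]:
    """Candidate target genes for one DMR.

    ``tss_table`` columns: gene_id, chrom, tss. Context is promoter when
    the nearest TSS is strictly closer than ``context_cutoff`` (distance
    measured TSS-to-DMR-edge, 0 if the TSS is inside). Promoter DMRs link
    to the single closest gene; distal DMRs to the ``n_each_side``
    nearest genes up- and downstream. Ties break by (distance, gene_id).
    """
    chrom, start, end = dmr
    sub = tss_table[tss_table["chrom"] == chrom]
    if sub.empty:
        warnings.warn(f"no genes on {chrom}; empty candidate list")
        return []
    tss = sub["tss"].to_numpy(np.int64)
    dist = np.where(
        (tss >= start) & (tss <= end - 1),
        0,
        np.minimum(np.abs(tss - start), np.abs(tss - (end - 1))),
    )
    frame = pd.DataFrame(
        {"gene_id": sub["gene_id"].to_numpy(), "tss": tss, "distance": dist}
    ).sort_values(["distance", "gene_id"], kind="mergesort")
    nearest = int(frame["distance"].iloc[0])
    context = "promoter" if nearest < context_cutoff else "distal"
    if context == "promoter":
        row = frame.iloc[0]
        return [
            LinkCandidate(dmr, "promoter", str(row["gene_id"]), int(row["distance"]), 0)
        ]
    inside = frame[frame["distance"] == 0]
    upstream = frame[(frame["distance"] > 0) & (frame["tss"] < start)].head(n_each_side)
    downstream = frame[(frame["distance"] > 0) & (frame["tss"] >= end)].head(n_each_side)
    out = []
    for _, row in inside.iterrows():
        out.append(LinkCandidate(dmr, "distal", str(row["gene_id"]), 0, 0))
    for i, (_, row) in enumerate(upstream.iterrows(), start=1):
        out.append(LinkCandidate(dmr, "distal", str(row["gene_id"]), int(row["distance"]), -i))
    for i, (_, row) in enumerate(downstream.iterrows(), start=1):
        out.append(LinkCandidate(dmr, "distal", str(row["gene_id"]), int(row["distance"]), i))
    return out


def correlate_links(
    meth_deltas: Mapping[str, float],
    expr_deltas: Mapping[str, float],
    retain_p: float = 0.05,
) -> dict:
    """Spearman correlation of per-patient methylation vs expression change.

    Restricted to patients present in both mappings (the patients in which
    the DMR was identified). Returns rho, two-sided p, direction and the
    retention decision; a constant vector leaves rho undefined and the
    link discarded.
    """
    patients = sorted(set(meth_deltas) & set(expr_deltas))
    if len(patients) < 3:
        return {"rho": float("nan"), "p_value": float("nan"), "n": len(patients),
                "direction": "undefined", "retained": False,
                "reason": "fewer than 3 patient pairs"}
    x = np.asarray([meth_deltas[p] for p in patients], dtype=float)
    y = np.asarray([expr_deltas[p] for p in patients], dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return {"rho": float("nan"), "p_value": float("nan"), "n": len(patients),
                "direction": "undefined", "retained": False,
                "reason": "constant vector"}
    rho, p = stats.spearmanr(x, y)
    return {
        "rho": float(rho),
        "p_value": float(p),
        "n": len(patients),
        "direction": "positive" if rho > 0 else "inverse",
        "retained": bool(p < retain_p),
        "reason": "",
    }


def correlate_all_links(
    candidates: Sequence[LinkCandidate],
    meth_deltas_of: Mapping[tuple, Mapping[str, float]],
    expr_deltas: pd.DataFrame,
    retain_p: float = 0.05,
) -> pd.DataFrame:
    """Run :func:`correlate_links` for every candidate and attach BH q-values.

    ``meth_deltas_of`` maps a DMR tuple to its per-patient methylation
    deltas; ``expr_deltas`` is genes x patients. Retention uses raw p by
    default (q reported alongside).
    """
    rows = []
    for cand in candidates:
        md = meth_deltas_of.get(cand.dmr)
        if md is None or cand.gene_id not in expr_deltas.index:
            continue
        ed = expr_deltas.loc[cand.gene_id].to_dict()
        res = correlate_links(md, ed, retain_p=retain_p)
        rows.append(
            {
                "chrom": cand.dmr[0],
                "start": cand.dmr[1],
                "end": cand.dmr[2],
                "gene_id": cand.gene_id,
                "context": cand.context,
                "rank": cand.rank,
                **{k: res[k] for k in ("rho", "p_value", "n", "direction", "retained", "reason")},
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        ok = df["p_value"].notna()
        q = np.full(len(df), np.nan)
        if ok.any():
            q[ok.to_numpy()] = stats.false_discovery_control(df.loc[ok, "p_value"])
        df["q_value"] = q
    return df
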