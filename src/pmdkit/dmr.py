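"""Post-processing of externally called DMRs (metilene-style tables):
cross-patient sharing, distance merging, discordance classification, and
annotation enrichment against matched random backgrounds.

Sign convention for ``delta_meth``: recurrent minus primary mean beta, so
positive deltas are regions hypermethylated at recurrence. Output writers
echo this convention in their headers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import IntervalSet

__all__ = [
    "read_metilene",
    "shared_dmrs",
    "merge_dmrs",
    "classify_discordance",
    "SharedDMR",
    "MatchedBackground",
    "sample_matched_background",
    "annotation_enrichment",
]

DMR_COLUMNS = ["chrom", "start", "end", "patient_id", "delta_meth", "q_value", "n_cpgs"]


def read_metilene(path, patient_id: str) -> pd.DataFrame:
    """Read a metilene-style TSV (chrom, start, stop, q-value, mean
    difference, #CpGs) into the internal DMR record frame."""
    raw = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "q_value", "delta_meth", "n_cpgs"],
        comment="#",
    )
    raw["patient_id"] = patient_id
    return raw[DMR_COLUMNS]


@dataclass
class SharedDMR:
    """A cross-patient merged DMR with per-patient methylation deltas."""

    chrom: str
    start: int
    end: int
    deltas: dict[str, float]  # patient_id -> delta_meth
    status: str = ""

    @property
    def patients(self) -> list[str]:
        return sorted(self.deltas)


def shared_dmrs(records: pd.DataFrame, min_patients: int = 2) -> list[SharedDMR]:
    """Retain regions where DMRs from >= min_patients distinct patients overlap.

    Records are clustered into connected overlap components (>= 1 bp,
    half-open: abutting intervals do not overlap); components contributed
    by fewer than ``min_patients`` distinct patients are dropped. Each
    retained component becomes one SharedDMR spanning the component, with
    per-patient deltas averaged over that patient's member records.
    """
    out: list[SharedDMR] = []
    for chrom, sub in records.groupby("chrom", sort=True):
        sub = sub.sort_values(["start", "end"], kind="mergesort")
        cluster: list = []
        cur_end = None
        for row in sub.itertuples(index=False):
            if cur_end is None or row.start < cur_end:
                cluster.append(row)
                cur_end = max(cur_end or 0, row.end)
            else:
                out.extend(_finish_cluster(chrom, cluster, min_patients))
                cluster = [row]
                cur_end = row.end
        if cluster:
            out.extend(_finish_cluster(chrom, cluster, min_patients))
    return out


def _finish_cluster(chrom: str, cluster: list, min_patients: int) -> list[SharedDMR]:
    patients = {r.patient_id for r in cluster}
    if len(patients) < min_patients:
        return []
    deltas: dict[str, list[float]] = {}
    for r in cluster:
        deltas.setdefault(r.patient_id, []).append(float(r.delta_meth))
    return [
        SharedDMR(
            chrom=chrom,
            start=min(r.start for r in cluster),
            end=max(r.end for r in cluster),
            deltas={p: float(np.mean(v)) for p, v in deltas.items()},
        )
    ]


def merge_dmrs(
    regions: Sequence[tuple[str, int, int]] | IntervalSet, gap: int = 250
) -> IntervalSet:
    """bedtools-merge semantics: regions separated by <= gap bp merge
    transitively (``-d`` parameter)."""
    if gap < 0:
        raise ValueError("gap must be >= 0")
    ivs = regions if isinstance(regions, IntervalSet) else IntervalSet.from_records(regions)
    return ivs.merge(gap=gap)


def classify_discordance(shared: SharedDMR, min_abs_delta: float = 0.0) -> str:
    """Label a shared DMR by the sign pattern of its per-patient deltas.

    discordant: at least one delta > +min_abs_delta and one < -min_abs_delta;
    concordant-hyper / concordant-hypo: all informative deltas share a sign;
    null-change: every delta is exactly zero.
    """
    d = np.asarray(list(shared.deltas.values()), dtype=float)
    if len(d) < 2:
        raise ValueError("shared DMR needs >= 2 per-patient deltas")
    if np.all(d == 0):
        return "null-change"
    has_up = np.any(d > min_abs_delta)
    has_down = np.any(d < -min_abs_delta)
    if has_up and has_down:
        return "discordant"
    return "concordant-hyper" if np.any(d > 0) else "concordant-hypo"


@dataclass
class MatchedBackground:
    """Per-query random intervals matched on length (and optionally CpG count)."""

    mode: str
    seed: int
    draws: dict[int, list[tuple[str, int, int]]] = field(repr=False, default_factory=dict)
    unmatched: list[int] = field(default_factory=list)


def _count_cpgs(
    genome_cpgs: Mapping[str, np.ndarray], chrom: str, start: int, end: int
) -> int:
    pos = genome_cpgs.get(chrom)
    if pos is None:
        return 0
    return int(np.searchsorted(pos, end) - np.searchsorted(pos, start))


def sample_matched_background(
    queries: Sequence[tuple[str, int, int]],
    genome_cpgs: Mapping[str, np.ndarray],
    chrom_sizes: Mapping[str, int],
    mode: str = "size_only",
    n_per_query: int = 100,
    cpg_tolerance: float = 0.10,
    seed: int = 0,
    max_tries: int = 2000,
) -> MatchedBackground:
    """Random background intervals for enrichment nulls.

    Every draw has exactly the query's length, is placed uniformly on a
    size-weighted random chromosome, and avoids the query set. In
    ``size_plus_cpg`` mode draws are additionally rejection-sampled until
    their CpG count is within ±``cpg_tolerance`` (relative) of the
    query's. Queries that cannot be matched within ``max_tries`` per draw
    are reported in ``unmatched`` and excluded from enrichment.
    """
    if mode not in ("size_only", "size_plus_cpg"):
        raise ValueError(f"unknown background mode {mode!r}")
    rng = np.random.default_rng(seed)
    query_set = IntervalSet.from_records(queries)
    chroms = list(chrom_sizes)
    sizes = np.asarray([chrom_sizes[c] for c in chroms], dtype=float)
    bg = MatchedBackground(mode=mode, seed=seed)
    genome_cpgs = {c: np.asarray(p, dtype=np.int64) for c, p in genome_cpgs.items()}
    for qi, (qchrom, qstart, qend) in enumerate(queries):
        length = qend - qstart
        eligible = sizes >= length
        if not eligible.any():
            bg.unmatched.append(qi)
            continue
        probs = np.where(eligible, sizes, 0.0)
        probs = probs / probs.sum()
        q_cpgs = _count_cpgs(genome_cpgs, qchrom, qstart, qend)
        lo = q_cpgs * (1.0 - cpg_tolerance)
        hi = q_cpgs * (1.0 + cpg_tolerance)
        draws: list[tuple[str, int, int]] = []
        tries = 0
        while len(draws) < n_per_query and tries < max_tries * n_per_query:
            tries += 1
            c = chroms[rng.choice(len(chroms), p=probs)]
            s = int(rng.integers(0, chrom_sizes[c] - length + 1))
            e = s + length
            if query_set.overlaps_interval(c, s, e):
                continue
            if mode == "size_plus_cpg":
                n = _count_cpgs(genome_cpgs, c, s, e)
                if not (lo <= n <= hi):
                    continue
            draws.append((c, s, e))
        if len(draws) < n_per_query:
            warnings.warn(
                f"query {qi} ({qchrom}:{qstart}-{qend}): only {len(draws)}/"
                f"{n_per_query} background draws matched; excluded"
            )
            bg.unmatched.append(qi)
        else:
            bg.draws[qi] = draws
    return bg


def annotation_enrichment(
    queries: Sequence[tuple[str, int, int]],
    background: MatchedBackground,
    annotations: Mapping[str, IntervalSet],
    call_threshold: float = 15.0,
) -> pd.DataFrame:
    """Observed vs matched-background overlap per annotation.

    The overlap metric is the fraction of regions with >= 1 bp overlap.
    percent change = 100 * (obs - bg_mean) / bg_mean; called "enriched"
    when strictly above ``call_threshold`` (percent), "depleted" when
    strictly below its negative, else "none". Background mean of zero
    leaves the percent change undefined (NaN, call "undefined").
    """
    if not annotations:
        raise ValueError("no annotations supplied")
    usable = [qi for qi in range(len(queries)) if qi in background.draws]
    rows = []
    for name, ann in annotations.items():
        obs_hits = sum(
            1 for qi in usable if ann.overlaps_interval(*queries[qi])
        )
        obs = obs_hits / len(usable) if usable else float("nan")
        bg_fracs = []
        for qi in usable:
            hits = sum(1 for d in background.draws[qi] if ann.overlaps_interval(*d))
            bg_fracs.append(hits / len(background.draws[qi]))
        bg_mean = float(np.mean(bg_fracs)) if bg_fracs else float("nan")
        if bg_mean == 0 or np.isnan(bg_mean):
            pct, call = float("nan"), "undefined"
        else:
            pct = 100.0 * (obs - bg_mean) / bg_mean
            # strict > on a computed float: guard the boundary against
            # representation error so exactly-at-threshold is never called
            eps = 1e-9 * max(1.0, abs(call_threshold))
            if pct > call_threshold + eps:
                call = "enriched"
            elif pct < -call_threshold - eps:
                call = "depleted"
            else:
                call = "none"
        rows.append((name, obs, bg_mean, pct, call))
    return pd.DataFrame(
        rows, columns=["annotation", "obs_frac", "bg_mean_frac", "pct_change", "call"]
    )
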