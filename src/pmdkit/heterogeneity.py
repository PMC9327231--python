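"""Cohort heterogeneity: variable-CpG selection, PCA, PC-soloWCGW
correlation, pairwise distances, intra- vs inter-patient tests, mQTL
intersection and gene-set-in-PMD hypergeometric tests.

PCA and distances operate on beta values of CpGs observed at adequate
coverage in *every* sample (complete-case); missing sites are excluded
rather than imputed.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform, pdist

from .intervals import IntervalSet
from .methylome_io import MethylomeTable

__all__ = [
    "CpGMatrix",
    "top_variable_cpgs",
    "pca_embed",
    "pc_solowcgw_correlation",
    "pairwise_distances",
    "intra_inter_test",
    "intersect_mqtls",
    "pmd_gene_set_test",
]


@dataclass
class CpGMatrix:
    """Beta matrix, rows = CpG sites (chrom, pos index), columns = samples."""

    values: pd.DataFrame = field(repr=False)
    min_cov: int = 10
    masked: bool = False

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def __len__(self) -> int:
        return len(self.values)


def top_variable_cpgs(
    tables: Sequence[MethylomeTable],
    k: int = 10_000,
    min_cov: int = 10,
    masked: bool = False,
) -> CpGMatrix:
    """Top-k most variable CpGs across samples, complete-case at min_cov.

    Sites must reach ``min_cov`` coverage in every sample; ranking is by
    cross-sample variance descending with deterministic (variance desc,
    chrom, pos) tie-break.
    """
    if len(tables) < 2:
        raise ValueError("need >= 2 samples")
    betas = []
    for t in tables:
        ok = t.df[t.df["coverage"] >= min_cov]
        s = ok.set_index(["chrom", "pos"])["beta"]
        s.name = t.sample_id
        betas.append(s)
    mat = pd.concat(betas, axis=1, join="inner")
    if mat.empty:
        raise ValueError("no CpG observed at required coverage in all samples")
    var = mat.var(axis=1, ddof=1)
    order = pd.DataFrame(
        {
            "neg_var": -var.to_numpy(),
            "chrom": [i[0] for i in mat.index],
            "pos": [i[1] for i in mat.index],
        }
    ).sort_values(["neg_var", "chrom", "pos"], kind="mergesort")
    if len(mat) < k:
        warnings.warn(f"only {len(mat)} eligible CpGs (< k={k}); returning all")
    sel = mat.iloc[order.index[: min(k, len(mat))]]
    return CpGMatrix(values=sel, min_cov=min_cov, masked=masked)


def pca_embed(matrix: CpGMatrix, n_pcs: int = 10) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA over samples on column-centred (unscaled) beta values.

    Returns (scores frame: samples x PCs, explained-variance fractions).
    The sign of each PC is fixed by making its largest-magnitude loading
    positive. Rank-deficient input truncates to the available components.
    """
    X = matrix.values.to_numpy(dtype=float).T  # samples x sites
    n_samples = X.shape[0]
    if n_samples < 2:
        raise ValueError("need >= 2 samples for PCA")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    nz = S > S[0] * 1e-12 if S.size and S[0] > 0 else np.zeros(S.shape, bool)
    n_keep = min(n_pcs, int(nz.sum()))
    U, S, Vt = U[:, :n_keep], S[:n_keep], Vt[:n_keep]
    # sign convention: largest-|loading| entry of each PC positive
    for j in range(n_keep):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    scores = U * S
    total_var = (Xc**2).sum()
    evr = (S**2) / total_var if total_var > 0 else np.zeros(n_keep)
    frame = pd.DataFrame(
        scores,
        index=matrix.sample_ids,
        columns=[f"PC{i + 1}" for i in range(n_keep)],
    )
    return frame, evr


def pc_solowcgw_correlation(
    scores: pd.DataFrame, solo_scores: Mapping[str, float], pc: str = "PC1"
) -> tuple[float, float]:
    """Pearson r (and two-sided p) between a PC score and solo-WCGW scores."""
    samples = list(scores.index)
    if len(samples) < 3:
        raise ValueError("need >= 3 samples")
    x = scores[pc].to_numpy(dtype=float)
    y = np.asarray([solo_scores[s] for s in samples], dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero variance; correlation undefined")
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def pairwise_distances(
    matrix: CpGMatrix,
    patient_of: Mapping[str, str],
    solo_scores: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """All unordered sample pairs with Euclidean distance, pair class and
    |delta soloWCGW|.

    Pair class is "intra" when both samples come from the same patient,
    else "inter".
    """
    samples = matrix.sample_ids
    missing = [s for s in samples if s not in patient_of]
    if missing:
        raise ValueError(f"samples without patient label: {missing}")
    X = matrix.values.to_numpy(dtype=float).T
    D = squareform(pdist(X, metric="euclidean"))
    rows = []
    for i, j in itertools.combinations(range(len(samples)), 2):
        a, b = samples[i], samples[j]
        d_solo = (
            abs(solo_scores[a] - solo_scores[b]) if solo_scores is not None else np.nan
        )
        rows.append(
            (
                a,
                b,
                float(D[i, j]),
                "intra" if patient_of[a] == patient_of[b] else "inter",
                d_solo,
            )
        )
    return pd.DataFrame(
        rows, columns=["sample_a", "sample_b", "distance", "pair_class", "d_solo_wcgw"]
    )


def intra_inter_test(
    distances: pd.DataFrame,
    groups: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """One-sided Mann-Whitney U (intra < inter) per stratum.

    ``groups`` optionally maps sample id to a stratum; a pair belongs to a
    stratum only if both members do. Exact null for small tie-free
    samples, normal approximation with tie correction otherwise
    (scipy's method="auto").
    """

    def run(sub: pd.DataFrame, name: str) -> tuple | None:
        intra = sub.loc[sub["pair_class"] == "intra", "distance"].to_numpy()
        inter = sub.loc[sub["pair_class"] == "inter", "distance"].to_numpy()
        if intra.size == 0 or inter.size == 0:
            warnings.warn(f"stratum {name}: missing intra or inter pairs; skipped")
            return None
        res = stats.mannwhitneyu(intra, inter, alternative="less", method="auto")
        return (name, intra.size, inter.size, float(res.statistic), float(res.pvalue))

    results = []
    if groups is None:
        r = run(distances, "all")
        if r:
            results.append(r)
    else:
        strata = sorted(set(groups.values()))
        for g in strata:
            members = {s for s, v in groups.items() if v == g}
            sub = distances[
                distances["sample_a"].isin(members) & distances["sample_b"].isin(members)
            ]
            r = run(sub, g)
            if r:
                results.append(r)
    return pd.DataFrame(
        results, columns=["stratum", "n_intra", "n_inter", "U", "p_value"]
    )


def intersect_mqtls(
    selected_cpgs: pd.DataFrame,
    mqtls: pd.DataFrame,
    p_cutoff: float = 5.0e-8,
) -> tuple[int, float, pd.DataFrame]:
    """Exact-position intersection of selected CpGs with significant mQTLs.

    ``mqtls`` needs chrom, pos and p_value columns; only entries with
    p_value strictly below ``p_cutoff`` are intersected. Returns
    (count, fraction of selected CpGs, the overlapping sites).
    """
    sig = mqtls[mqtls["p_value"] < p_cutoff]
    sel_idx = pd.MultiIndex.from_frame(selected_cpgs[["chrom", "pos"]])
    sig_idx = pd.MultiIndex.from_frame(sig[["chrom", "pos"]]).drop_duplicates()
    common = sel_idx.intersection(sig_idx)
    frac = len(common) / len(sel_idx) if len(sel_idx) else 0.0
    overlap = pd.DataFrame(list(common), columns=["chrom", "pos"])
    return len(common), frac, overlap


def pmd_gene_set_test(
    gene_intervals: pd.DataFrame,
    gene_set: Sequence[str],
    pmds: IntervalSet,
    side: str = "enrichment",
) -> dict:
    """Hypergeometric test for a gene set among genes located in PMDs.

    A gene is "in PMDs" iff its interval overlaps the PMD set by >= 1 bp.
    With N = universe size, K = |gene_set|, n = genes in PMDs and k = set
    genes in PMDs: enrichment p = P(X >= k), depletion p = P(X <= k) for
    X ~ Hypergeom(N, K, n).
    """
    if gene_intervals.empty:
        raise ValueError("empty gene universe")
    universe = set(gene_intervals["gene_id"])
    stray = set(gene_set) - universe
    if stray:
        raise ValueError(f"gene_set members outside universe: {sorted(stray)[:5]}")
    in_pmd = {
        row.gene_id
        for row in gene_intervals.itertuples(index=False)
        if pmds.overlaps_interval(row.chrom, int(row.start), int(row.end))
    }
    N = len(universe)
    K = len(set(gene_set))
    n = len(in_pmd)
    k = len(in_pmd & set(gene_set))
    if side == "enrichment":
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
    elif side == "depletion":
        p = float(stats.hypergeom.cdf(k, N, K, n))
    else:
        raise ValueError("side must be 'enrichment' or 'depletion'")
    return {"k": k, "K": K, "n": n, "N": N, "p_value": p, "side": side}
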