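"""Per-sample partially-methylated-domain (PMD) detection.

The procedure: average solo-WCGW CpG methylation in non-overlapping 100 kb
bins, transform the bin means to M-values ``M = log2(beta / (1 - beta))``,
fit a univariate 3-component Gaussian mixture with unequal variances by EM,
label the components low / intermediate / high by ascending mean, and call
a bin PMD when its posterior probability of the *high* component falls
below a cutoff (default 0.01). Runs of consecutive PMD bins are merged into
single domains.

The mixture is fit strictly per sample, never pooled across the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .genome import BinGrid
from .intervals import IntervalSet
from .methylome_io import MethylomeTable

__all__ = [
    "BinProfile",
    "GaussianMixture1D",
    "PMDCallSet",
    "bin_solo_wcgw_means",
    "beta_to_m",
    "fit_gmm3",
    "call_pmds",
    "pmd_genome_fraction",
]

COMPONENT_LABELS = ("low", "intermediate", "high")


@dataclass
class BinProfile:
    """Per-sample mean solo-WCGW beta on a fixed bin grid.

    ``table`` is aligned row-for-row with ``grid.bins`` and carries
    mean_beta (NaN where a bin has < min_sites informative CpGs) and
    n_solo_wcgw.
    """

    sample_id: str
    grid: BinGrid
    table: pd.DataFrame = field(repr=False)

    @property
    def informative(self) -> pd.DataFrame:
        return self.table[self.table["mean_beta"].notna()]


@dataclass
class PMDCallSet:
    sample_id: str
    intervals: IntervalSet
    bin_p_high: pd.DataFrame = field(repr=False)  # chrom, start, end, p_high, is_pmd


def bin_solo_wcgw_means(
    table: MethylomeTable,
    solo_sites: pd.DataFrame,
    grid: BinGrid,
    min_sites: int = 10,
) -> BinProfile:
    """Unweighted mean beta over covered solo-WCGW CpGs per bin.

    Bins with fewer than ``min_sites`` informative CpGs are left missing,
    guarding the mixture input against 1-CpG noise.
    """
    grid_chroms = set(grid.bins["chrom"])
    tbl_chroms = set(table.df["chrom"])
    orphans = tbl_chroms - grid_chroms
    if orphans:
        raise ValueError(f"chromosomes absent from bin grid: {sorted(orphans)}")

    solo = solo_sites[solo_sites.get("is_solo_wcgw", True) == True]  # noqa: E712
    keys = pd.MultiIndex.from_frame(solo[["chrom", "pos"]])
    df = table.df.set_index(["chrom", "pos"])
    hit = df[df.index.isin(keys)].reset_index()

    sums = np.zeros(len(grid.bins))
    counts = np.zeros(len(grid.bins), dtype=np.int64)
    for chrom, sub in hit.groupby("chrom", sort=False):
        idx = grid.bin_index(chrom, sub["pos"].to_numpy())
        ok = idx >= 0
        np.add.at(sums, idx[ok], sub["beta"].to_numpy()[ok])
        np.add.at(counts, idx[ok], 1)

    with np.errstate(invalid="ignore"):
        means = np.where(counts >= min_sites, sums / np.maximum(counts, 1), np.nan)
    tab = grid.bins.copy()
    tab["mean_beta"] = means
    tab["n_solo_wcgw"] = counts
    return BinProfile(sample_id=table.sample_id, grid=grid, table=tab)


def beta_to_m(beta: np.ndarray | float, epsilon: float = 1e-3) -> np.ndarray | float:
    """Logit-like M-value transform, clipping beta into [eps, 1-eps] first."""
    if not 0 < epsilon < 0.5:
        raise ValueError("epsilon must lie in (0, 0.5)")
    b = np.clip(np.asarray(beta, dtype=float), epsilon, 1.0 - epsilon)
    m = np.log2(b / (1.0 - b))
    return float(m) if np.isscalar(beta) else m


class GaussianMixture1D:
    """Univariate Gaussian mixture fit by EM with restarts.

    Components are unconstrained in variance (floored at ``var_floor``);
    initialisation is k-means++-style on the data points. After fitting,
    components are reported in ascending-mean order so that with k=3 the
    indices 0/1/2 correspond to the low/intermediate/high labels.

    Attributes (after ``fit``): ``weights_``, ``means_``, ``variances_``
    (ascending-mean order), ``responsibilities_`` (n x k), ``log_likelihood_``,
    ``trace_`` (per-iteration log-likelihood of the winning restart),
    ``converged_``, ``n_iter_``.
    """

    def __init__(
        self,
        n_components: int = 3,
        n_restarts: int = 10,
        tol: float = 1e-8,
        max_iter: int = 1000,
        var_floor: float = 1e-6,
        seed: int = 0,
    ):
        self.n_components = n_components
        self.n_restarts = n_restarts
        self.tol = tol
        self.max_iter = max_iter
        self.var_floor = var_floor
        self.seed = seed

    # -- internals -----------------------------------------------------------
    def _init_means(self, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """k-means++ style: spread initial centers by squared distance."""
        centers = [x[rng.integers(x.size)]]
        for _ in range(self.n_components - 1):
            d2 = np.min([(x - c) ** 2 for c in centers], axis=0)
            total = d2.sum()
            if total <= 0:
                centers.append(x[rng.integers(x.size)])
                continue
            centers.append(x[rng.choice(x.size, p=d2 / total)])
        return np.asarray(centers, dtype=float)

    def _em_once(
        self, x: np.ndarray, rng: np.random.Generator
    ) -> tuple[float, dict] | None:
        k = self.n_components
        n = x.size
        means = self._init_means(x, rng)
        variances = np.full(k, max(np.var(x), self.var_floor))
        weights = np.full(k, 1.0 / k)
        trace: list[float] = []
        converged = False
        resp = np.full((n, k), 1.0 / k)
        for it in range(self.max_iter):
            # E step (log domain)
            log_pdf = (
                -0.5 * np.log(2 * np.pi * variances)[None, :]
                - 0.5 * (x[:, None] - means[None, :]) ** 2 / variances[None, :]
            )
            log_joint = np.log(weights)[None, :] + log_pdf
            log_norm = logsumexp(log_joint, axis=1)
            ll = float(log_norm.sum())
            if not np.isfinite(ll):
                return None  # collapsed: trigger a restart
            if trace and ll + 1e-12 < trace[-1] - abs(trace[-1]) * 1e-12:
                # numerically impossible for exact EM; guards float drift
                ll = trace[-1]
            resp = np.exp(log_joint - log_norm[:, None])
            if trace and abs(ll - trace[-1]) <= self.tol * (abs(trace[-1]) + 1e-12):
                trace.append(ll)
                converged = True
                break
            trace.append(ll)
            # M step
            nk = resp.sum(axis=0)
            if np.any(nk < 1e-10):
                return None
            weights = nk / n
            means = (resp * x[:, None]).sum(axis=0) / nk
            variances = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
            variances = np.maximum(variances, self.var_floor)
        order = np.argsort(means)
        return trace[-1], {
            "weights": weights[order],
            "means": means[order],
            "variances": variances[order],
            "resp": resp[:, order],
            "trace": trace,
            "converged": converged,
        }

    # -- api -----------------------------------------------------------------
    def fit(self, x: np.ndarray) -> "GaussianMixture1D":
        x = np.asarray(x, dtype=float).ravel()
        if x.size < 30:
            raise ValueError(
                f"only {x.size} informative bins; need >= 30 — use smaller bins "
                "or pool samples"
            )
        rng = np.random.default_rng(self.seed)
        best = None
        failures = []
        for r in range(self.n_restarts):
            res = self._em_once(x, rng)
            if res is None:
                failures.append(r)
                continue
            if best is None or res[0] > best[0]:
                best = res
        if best is None:
            raise RuntimeError(
                f"all {self.n_restarts} EM restarts collapsed "
                f"(n={x.size}, var={np.var(x):.3g}, var_floor={self.var_floor:g})"
            )
        ll, params = best
        self.weights_ = params["weights"]
        self.means_ = params["means"]
        self.variances_ = params["variances"]
        self.responsibilities_ = params["resp"]
        self.trace_ = np.asarray(params["trace"])
        self.log_likelihood_ = ll
        self.converged_ = params["converged"]
        self.n_iter_ = len(params["trace"])
        return self

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float).ravel()
        log_pdf = (
            -0.5 * np.log(2 * np.pi * self.variances_)[None, :]
            - 0.5 * (x[:, None] - self.means_[None, :]) ** 2 / self.variances_[None, :]
        )
        log_joint = np.log(self.weights_)[None, :] + log_pdf
        return np.exp(log_joint - logsumexp(log_joint, axis=1)[:, None])


def fit_gmm3(
    m_values: np.ndarray,
    n_restarts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 1000,
    seed: int = 0,
    var_floor: float = 1e-6,
) -> GaussianMixture1D:
    """Fit the 3-component mixture to a sample's informative bin M-values."""
    gm = GaussianMixture1D(
        n_components=3,
        n_restarts=n_restarts,
        tol=tol,
        max_iter=max_iter,
        var_floor=var_floor,
        seed=seed,
    )
    return gm.fit(m_values)


def call_pmds(
    profile: BinProfile,
    fit: GaussianMixture1D,
    p_high_cutoff: float = 0.01,
    epsilon: float = 1e-3,
    max_gap_bins: int = 0,
) -> PMDCallSet:
    """Label bins PMD where P(high component) < cutoff and merge runs.

    Missing bins are never PMD and break runs (unless ``max_gap_bins``
    allows bridging that many consecutive missing bins).
    """
    tab = profile.table.copy()
    m = beta_to_m(tab["mean_beta"].to_numpy(), epsilon=epsilon)
    informative = tab["mean_beta"].notna().to_numpy()
    p_high = np.full(len(tab), np.nan)
    if informative.any():
        p_high[informative] = fit.predict_proba(m[informative])[:, 2]
    tab["p_high"] = p_high
    tab["is_pmd"] = informative & (p_high < p_high_cutoff)

    records = []
    for chrom, sub in tab.groupby("chrom", sort=False):
        run_start = None
        run_end = None
        gap = 0
        for row in sub.itertuples(index=False):
            if row.is_pmd:
                if run_start is None:
                    run_start, run_end = row.start, row.end
                else:
                    run_end = row.end
                gap = 0
            else:
                if run_start is not None:
                    if np.isnan(row.p_high) and gap < max_gap_bins:
                        gap += 1
                        continue
                    records.append((chrom, int(run_start), int(run_end)))
                    run_start = run_end = None
                    gap = 0
        if run_start is not None:
            records.append((chrom, int(run_start), int(run_end)))
    intervals = IntervalSet.from_records(records) if records else IntervalSet()
    cols = ["chrom", "start", "end", "p_high", "is_pmd"]
    return PMDCallSet(profile.sample_id, intervals, tab[cols])


def pmd_genome_fraction(calls: PMDCallSet, chrom_sizes: Mapping[str, int]) -> float:
    """Fraction of the genome covered by the sample's PMD calls."""
    calls.intervals.assert_disjoint()
    for chrom, (s, e) in calls.intervals.by_chrom.items():
        if chrom not in chrom_sizes:
            raise ValueError(f"PMD chromosome {chrom} not in chrom_sizes")
        if e.size and e[-1] > chrom_sizes[chrom]:
            raise ValueError(f"PMD interval exceeds {chrom} bounds")
    return calls.intervals.coverage_fraction(chrom_sizes)
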