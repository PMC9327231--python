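"""PMD caller: binning, M-transform, the 3-component EM (against a naive
independent EM oracle), posterior thresholding and interval merging."""

import numpy as np
import pandas as pd
import pytest

from pmdkit.genome import make_bins
from pmdkit.intervals import IntervalSet
from pmdkit.methylome_io import MethylomeTable
from pmdkit.pmd import (
    GaussianMixture1D,
    beta_to_m,
    bin_solo_wcgw_means,
    call_pmds,
    fit_gmm3,
    pmd_genome_fraction,
)


# -- independent naive EM oracle --------------------------------------------

def naive_em(x, means0, max_iter=5000, tol=1e-12):
    """Textbook EM, coded independently of the package implementation."""
    k = len(means0)
    means = np.array(means0, dtype=float)
    var = np.full(k, np.var(x))
    w = np.full(k, 1.0 / k)
    prev = -np.inf
    for _ in range(max_iter):
        dens = np.array(
            [
                w[j] / np.sqrt(2 * np.pi * var[j]) * np.exp(-((x - means[j]) ** 2) / (2 * var[j]))
                for j in range(k)
            ]
        )  # k x n
        tot = dens.sum(axis=0)
        ll = np.log(tot).sum()
        r = dens / tot
        nk = r.sum(axis=1)
        w = nk / x.size
        means = (r * x).sum(axis=1) / nk
        var = (r * (x - means[:, None]) ** 2).sum(axis=1) / nk
        if abs(ll - prev) < tol * max(1.0, abs(ll)):
            break
        prev = ll
    order = np.argsort(means)
    return means[order], var[order], w[order]


def mixture_sample(rng, n=500, means=(-3.5, 1.0, 3.0), sd=0.6, weights=(0.3, 0.2, 0.5)):
    comp = rng.choice(3, size=n, p=weights)
    return rng.normal(np.asarray(means)[comp], sd)


# -- binning -----------------------------------------------------------------

def profile_from(rows, sites, grid, min_sites=1):
    df = pd.DataFrame(rows, columns=["chrom", "pos", "beta", "coverage"])
    table = MethylomeTable("s", df)
    return bin_solo_wcgw_means(table, sites, grid, min_sites=min_sites)


def test_bin_means_average_and_missing():
    grid = make_bins({"c1": 300_000}, width=100_000)
    sites = pd.DataFrame(
        {"chrom": "c1", "pos": [10, 20, 150_000], "is_solo_wcgw": [True, True, True]}
    )
    prof = profile_from(
        [("c1", 10, 0.2, 10), ("c1", 20, 0.4, 10), ("c1", 150_000, 0.9, 10)],
        sites,
        grid,
    )
    mb = prof.table["mean_beta"]
    assert mb.iloc[0] == pytest.approx(0.3)
    assert mb.iloc[1] == pytest.approx(0.9)
    assert np.isnan(mb.iloc[2])  # no covered solo CpGs
    assert list(prof.table["n_solo_wcgw"]) == [2, 1, 0]


def test_bin_means_respect_min_sites_and_solo_flag():
    grid = make_bins({"c1": 100_000}, width=100_000)
    sites = pd.DataFrame(
        {"chrom": "c1", "pos": [10, 20, 30], "is_solo_wcgw": [True, True, False]}
    )
    prof = profile_from(
        [("c1", 10, 0.0, 10), ("c1", 20, 0.5, 10), ("c1", 30, 1.0, 10)],
        sites,
        grid,
        min_sites=3,
    )
    assert np.isnan(prof.table["mean_beta"].iloc[0])  # only 2 solo CpGs covered
    prof2 = profile_from(
        [("c1", 10, 0.0, 10), ("c1", 20, 0.5, 10), ("c1", 30, 1.0, 10)],
        sites,
        grid,
        min_sites=2,
    )
    assert prof2.table["mean_beta"].iloc[0] == pytest.approx(0.25)  # non-solo excluded


def test_bin_means_match_bruteforce_groupby():
    rng = np.random.default_rng(2)
    grid = make_bins({"c1": 1_000_000}, width=100_000)
    pos = np.sort(rng.choice(1_000_000, size=400, replace=False))
    solo = rng.random(400) < 0.7
    sites = pd.DataFrame({"chrom": "c1", "pos": pos, "is_solo_wcgw": solo})
    betas = rng.random(400)
    rows = [("c1", int(p), float(b), 10) for p, b in zip(pos, betas)]
    prof = profile_from(rows, sites, grid, min_sites=1)
    # brute-force interval assignment
    for bi, row in prof.table.iterrows():
        vals = [
            b
            for p, b, s in zip(pos, betas, solo)
            if s and row["start"] <= p < row["end"]
        ]
        if vals:
            assert row["mean_beta"] == pytest.approx(np.mean(vals))
        else:
            assert np.isnan(row["mean_beta"])


def test_bin_means_rejects_unknown_chromosome():
    grid = make_bins({"c1": 100_000})
    sites = pd.DataFrame({"chrom": "c1", "pos": [10], "is_solo_wcgw": [True]})
    with pytest.raises(ValueError, match="c9"):
        profile_from([("c9", 10, 0.5, 10)], sites, grid)


# -- M-values ----------------------------------------------------------------

def test_beta_to_m_reference_points():
    assert beta_to_m(0.5) == pytest.approx(0.0)
    assert beta_to_m(0.8) == pytest.approx(2.0)
    assert beta_to_m(0.2) == pytest.approx(-2.0)


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=100, deadline=None, derandomize=True)
@given(beta=st.floats(0.0, 1.0))
def test_beta_to_m_antisymmetric(beta):
    assert beta_to_m(beta) == pytest.approx(-beta_to_m(1.0 - beta), abs=1e-9)


def test_beta_to_m_clips_extremes_and_is_monotone():
    eps = 1e-3
    assert beta_to_m(0.0, eps) == beta_to_m(eps, eps)
    assert beta_to_m(1.0, eps) == -beta_to_m(0.0, eps)
    b = np.linspace(0, 1, 101)
    m = beta_to_m(b)
    assert np.all(np.diff(m) >= 0)
    with pytest.raises(ValueError):
        beta_to_m(0.5, epsilon=0.7)


# -- EM ----------------------------------------------------------------------

def test_gmm_matches_naive_em_oracle():
    rng = np.random.default_rng(42)
    x = mixture_sample(rng)
    fit = fit_gmm3(x, seed=0)
    oracle_means, _, oracle_w = naive_em(x, means0=(-3.5, 1.0, 3.0))
    assert np.all(np.abs(fit.means_ - oracle_means) <= 0.15)
    assert np.all(np.diff(fit.means_) > 0)  # labeled by ascending mean
    assert fit.weights_.sum() == pytest.approx(1.0)
    assert np.allclose(fit.responsibilities_.sum(axis=1), 1.0)


def test_gmm_trace_monotone_nondecreasing():
    rng = np.random.default_rng(1)
    for _ in range(3):
        x = mixture_sample(rng, n=300)
        fit = fit_gmm3(x, seed=3)
        assert np.all(np.diff(fit.trace_) >= -1e-9)


def test_gmm_single_tight_cluster_engages_floor():
    rng = np.random.default_rng(2)
    x = rng.normal(1.0, 0.01, size=200)
    fit = fit_gmm3(x, seed=0)
    assert fit.weights_.max() >= 0.99 or np.all(np.abs(fit.means_ - 1.0) < 0.05)
    assert np.all(fit.variances_ >= 1e-6)  # floor respected


def test_gmm_requires_30_bins():
    with pytest.raises(ValueError, match="30"):
        fit_gmm3(np.zeros(10))


def test_gmm_deterministic_under_seed():
    rng = np.random.default_rng(3)
    x = mixture_sample(rng)
    f1 = fit_gmm3(x, seed=5)
    f2 = fit_gmm3(x, seed=5)
    assert np.array_equal(f1.means_, f2.means_)
    assert np.array_equal(f1.trace_, f2.trace_)


# -- calling -----------------------------------------------------------------

def synthetic_profile_and_fit(seed=0, n_bins=60, pmd_bins=(5, 6, 7, 20, 21)):
    rng = np.random.default_rng(seed)
    grid = make_bins({"c1": n_bins * 100_000}, width=100_000)
    beta = np.full(n_bins, np.nan)
    for i in range(n_bins):
        beta[i] = rng.normal(0.5 if i in pmd_bins else 0.88, 0.01)
    tab = grid.bins.copy()
    tab["mean_beta"] = np.clip(beta, 0.01, 0.99)
    tab["n_solo_wcgw"] = 50
    from pmdkit.pmd import BinProfile

    profile = BinProfile("s", grid, tab)
    fit = fit_gmm3(
        np.concatenate(
            [
                rng.normal(-0.6, 0.2, 40),
                rng.normal(0.8, 0.2, 40),
                rng.normal(2.9, 0.1, 100),
            ]
        ),
        seed=0,
    )
    return profile, fit


def test_call_pmds_threshold_and_merge():
    profile, fit = synthetic_profile_and_fit()
    calls = call_pmds(profile, fit, p_high_cutoff=0.01)
    got = list(calls.intervals)
    assert ("c1", 500_000, 800_000) in got  # 3 consecutive bins merged
    assert ("c1", 2_000_000, 2_200_000) in got
    assert len(got) == 2
    # per-bin posterior behaviour
    tab = calls.bin_p_high
    assert (tab.loc[tab["is_pmd"], "p_high"] < 0.01).all()
    assert (tab.loc[~tab["is_pmd"] & tab["p_high"].notna(), "p_high"] >= 0.01).all()


def test_missing_bins_break_runs():
    profile, fit = synthetic_profile_and_fit(pmd_bins=(5, 6, 7))
    profile.table.loc[6, "mean_beta"] = np.nan
    calls = call_pmds(profile, fit)
    got = list(calls.intervals)
    assert ("c1", 500_000, 600_000) in got
    assert ("c1", 700_000, 800_000) in got


def test_cutoff_monotonicity():
    profile, fit = synthetic_profile_and_fit()
    small = call_pmds(profile, fit, p_high_cutoff=0.001).intervals.total_length()
    large = call_pmds(profile, fit, p_high_cutoff=0.05).intervals.total_length()
    assert small <= large


def test_genome_fraction_examples_and_bitmask():
    calls_ivs = IntervalSet.from_records([("c1", 0, 300_000)])
    from pmdkit.pmd import PMDCallSet

    grid = make_bins({"c1": 1_000_000})
    tab = grid.bins.copy()
    tab["p_high"] = 0.5
    tab["is_pmd"] = False
    calls = PMDCallSet("s", calls_ivs, tab)
    assert pmd_genome_fraction(calls, {"c1": 1_000_000}) == pytest.approx(0.30)
    empty = PMDCallSet("s", IntervalSet(), tab)
    assert pmd_genome_fraction(empty, {"c1": 1_000_000}) == 0.0

    rng = np.random.default_rng(4)
    starts = np.sort(rng.choice(np.arange(0, 900_000, 10_000), 12, replace=False))
    recs = [("c1", int(s), int(s + rng.integers(1, 9000))) for s in starts]
    ivs = IntervalSet.from_records(recs)
    mask = np.zeros(1_000_000, dtype=bool)
    for _, s, e in recs:
        mask[s:e] = True
    frac = pmd_genome_fraction(PMDCallSet("s", ivs, tab), {"c1": 1_000_000})
    assert frac == pytest.approx(mask.sum() / 1_000_000)


def test_fraction_rejects_out_of_bounds():
    from pmdkit.pmd import PMDCallSet

    grid = make_bins({"c1": 100_000})
    tab = grid.bins.copy()
    tab["p_high"] = 0.5
    tab["is_pmd"] = False
    calls = PMDCallSet("s", IntervalSet.from_records([("c1", 0, 200_000)]), tab)
    with pytest.raises(ValueError):
        pmd_genome_fraction(calls, {"c1": 100_000})
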