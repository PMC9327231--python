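"""Variable-CpG selection, PCA, distances, rank tests and the
hypergeometric gene-set test, each against an independent oracle."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from pmdkit.heterogeneity import (
    CpGMatrix,
    intersect_mqtls,
    intra_inter_test,
    pairwise_distances,
    pc_solowcgw_correlation,
    pca_embed,
    pmd_gene_set_test,
    top_variable_cpgs,
)
from pmdkit.intervals import IntervalSet
from pmdkit.methylome_io import MethylomeTable


def table_from_vector(sample_id, betas, coverage=20):
    df = pd.DataFrame(
        {
            "chrom": "c1",
            "pos": np.arange(len(betas)),
            "beta": betas,
            "coverage": coverage,
        }
    )
    return MethylomeTable(sample_id, df)


def matrix_from(values, sample_ids=None):
    values = np.asarray(values, dtype=float)
    ids = sample_ids or [f"s{i}" for i in range(values.shape[1])]
    idx = pd.MultiIndex.from_tuples([("c1", i) for i in range(values.shape[0])])
    return CpGMatrix(values=pd.DataFrame(values, index=idx, columns=ids))


# -- top variable CpGs -------------------------------------------------------

def test_top_variable_selects_by_variance():
    t1 = table_from_vector("a", [0.0, 0.5, 0.5])
    t2 = table_from_vector("b", [1.0, 0.5, 0.6])
    mat = top_variable_cpgs([t1, t2], k=2, min_cov=10)
    assert list(mat.values.index) == [("c1", 0), ("c1", 2)]  # constant site last


def test_top_variable_requires_coverage_in_every_sample():
    t1 = table_from_vector("a", [0.0, 0.5], coverage=20)
    t2 = MethylomeTable(
        "b",
        pd.DataFrame(
            [("c1", 0, 1.0, 5), ("c1", 1, 0.5, 20)],
            columns=["chrom", "pos", "beta", "coverage"],
        ),
    )
    mat = top_variable_cpgs([t1, t2], k=10, min_cov=10)
    assert list(mat.values.index) == [("c1", 1)]


def test_top_variable_matches_bruteforce_sort():
    rng = np.random.default_rng(0)
    tables = [table_from_vector(f"s{i}", rng.random(50)) for i in range(4)]
    k = 10
    mat = top_variable_cpgs(tables, k=k, min_cov=10)
    stacked = np.vstack([t.df["beta"].to_numpy() for t in tables])
    var = stacked.var(axis=0, ddof=1)
    expected = set(np.argsort(-var, kind="stable")[:k])
    assert {p for _, p in mat.values.index} == expected


def test_top_variable_warns_when_fewer_than_k():
    t1 = table_from_vector("a", [0.0, 0.5])
    t2 = table_from_vector("b", [1.0, 0.5])
    with pytest.warns(UserWarning, match="eligible"):
        mat = top_variable_cpgs([t1, t2], k=100)
    assert len(mat) == 2


# -- PCA ---------------------------------------------------------------------

def test_pca_identical_samples_zero_distance():
    mat = matrix_from(np.tile([[0.2], [0.8], [0.5]], (1, 3)))
    scores, evr = pca_embed(mat)
    assert np.allclose(scores.to_numpy(), 0.0)


def test_pca_single_direction_explains_everything():
    t = np.linspace(0, 1, 5)
    mat = matrix_from(np.outer([0.3, 0.9, 0.1, 0.4], t).T)
    scores, evr = pca_embed(mat)
    assert evr[0] == pytest.approx(1.0, abs=1e-10)


def test_pca_matches_covariance_eigensolver():
    rng = np.random.default_rng(1)
    X = rng.random((40, 6))  # sites x samples
    mat = matrix_from(X)
    scores, evr = pca_embed(mat, n_pcs=5)
    # independent route: eigendecomposition of the sample covariance
    Y = X.T - X.T.mean(axis=0)
    C = Y @ Y.T
    w, v = np.linalg.eigh(C)
    w, v = w[::-1], v[:, ::-1]
    for j in range(5):
        proj = v[:, j] * np.sqrt(w[j])
        got = scores.iloc[:, j].to_numpy()
        assert np.allclose(np.abs(got), np.abs(proj), atol=1e-8)
    assert np.allclose(evr[:5], w[:5] / w.sum(), atol=1e-12)
    assert np.all(np.diff(evr) <= 1e-12)  # non-increasing


def test_pca_sign_convention_deterministic():
    rng = np.random.default_rng(2)
    X = rng.random((30, 5))
    s1, _ = pca_embed(matrix_from(X))
    s2, _ = pca_embed(matrix_from(X))
    assert np.array_equal(s1.to_numpy(), s2.to_numpy())


# -- correlation -------------------------------------------------------------

def test_pc_solo_correlation_linear_and_oracle():
    scores = pd.DataFrame({"PC1": [1.0, 2.0, 3.0, 4.0]}, index=list("abcd"))
    solo = {"a": 0.1, "b": 0.2, "c": 0.3, "d": 0.4}
    r, p = pc_solowcgw_correlation(scores, solo)
    assert r == pytest.approx(1.0)

    rng = np.random.default_rng(3)
    x = rng.random(20)
    y = rng.random(20)
    scores = pd.DataFrame({"PC1": x}, index=[f"s{i}" for i in range(20)])
    solo = {f"s{i}": y[i] for i in range(20)}
    r, p = pc_solowcgw_correlation(scores, solo)
    # textbook formula
    rx = (x - x.mean()) / x.std()
    ry = (y - y.mean()) / y.std()
    assert r == pytest.approx(float((rx * ry).mean()))


def test_pc_solo_correlation_degenerate():
    scores = pd.DataFrame({"PC1": [1.0, 1.0, 1.0]}, index=list("abc"))
    with pytest.warns(UserWarning):
        r, p = pc_solowcgw_correlation(scores, {"a": 0.1, "b": 0.2, "c": 0.3})
    assert math.isnan(r)


# -- distances ---------------------------------------------------------------

def test_distances_examples_and_oracle():
    mat = matrix_from(np.array([[0.0, 3.0, 0.0], [0.0, 4.0, 0.0]]), ["a", "b", "c"])
    pat = {"a": "p1", "b": "p2", "c": "p1"}
    d = pairwise_distances(mat, pat, {"a": 0.5, "b": 0.2, "c": 0.5})
    ab = d[(d.sample_a == "a") & (d.sample_b == "b")].iloc[0]
    assert ab.distance == pytest.approx(5.0)
    assert ab.pair_class == "inter"
    assert ab.d_solo_wcgw == pytest.approx(0.3)
    ac = d[(d.sample_a == "a") & (d.sample_b == "c")].iloc[0]
    assert ac.distance == 0.0
    assert ac.pair_class == "intra"


def test_distances_match_double_loop_and_triangle():
    rng = np.random.default_rng(4)
    X = rng.random((30, 6))
    ids = [f"s{i}" for i in range(6)]
    mat = matrix_from(X, ids)
    d = pairwise_distances(mat, {s: s for s in ids})
    lut = {(r.sample_a, r.sample_b): r.distance for r in d.itertuples(index=False)}
    for i, j in itertools.combinations(range(6), 2):
        naive = math.sqrt(((X[:, i] - X[:, j]) ** 2).sum())
        assert lut[(ids[i], ids[j])] == pytest.approx(naive)
    # triangle inequality on sampled triples
    full = {**lut, **{(b, a): v for (a, b), v in lut.items()}}
    for a, b, c in itertools.combinations(ids, 3):
        assert full[(a, c)] <= full[(a, b)] + full[(b, c)] + 1e-9


def test_distances_require_patient_labels():
    mat = matrix_from(np.zeros((3, 2)), ["a", "b"])
    with pytest.raises(ValueError, match="patient"):
        pairwise_distances(mat, {"a": "p1"})


# -- intra vs inter ----------------------------------------------------------

def dist_frame(intra, inter):
    rows = [("i%d" % k, "j%d" % k, v, "intra", 0.0) for k, v in enumerate(intra)]
    rows += [("x%d" % k, "y%d" % k, v, "inter", 0.0) for k, v in enumerate(inter)]
    return pd.DataFrame(
        rows, columns=["sample_a", "sample_b", "distance", "pair_class", "d_solo_wcgw"]
    )


def test_intra_inter_exact_small_sample():
    # all 2-vs-3 splits: the observed extreme split has probability 1/C(5,2)
    res = intra_inter_test(dist_frame([1, 2], [10, 11, 12]))
    assert res["p_value"].iloc[0] == pytest.approx(0.1)


def test_intra_inter_all_ties_p_one():
    res = intra_inter_test(dist_frame([5, 5, 5], [5, 5, 5]))
    assert res["p_value"].iloc[0] == pytest.approx(1.0)


def test_intra_inter_strata_and_empty():
    d = dist_frame([1], [2, 3])
    d["sample_a"] = ["a", "a", "a"]
    d["sample_b"] = ["b", "b", "b"]
    res = intra_inter_test(d, groups={"a": "g1", "b": "g1"})
    assert list(res["stratum"]) == ["g1"]
    with pytest.warns(UserWarning, match="skipped"):
        res2 = intra_inter_test(d, groups={"a": "g2", "b": "g3"})
    assert res2.empty


# -- mQTL intersection -------------------------------------------------------

def test_mqtl_intersection_strict_cutoff():
    sel = pd.DataFrame({"chrom": ["c1"] * 3, "pos": [10, 20, 30]})
    mq = pd.DataFrame(
        {
            "chrom": ["c1", "c1", "c1"],
            "pos": [10, 20, 30],
            "p_value": [1e-9, 5.0e-8, 4.9e-8],
        }
    )
    n, frac, overlap = intersect_mqtls(sel, mq)
    assert n == 2  # p exactly 5.0e-8 excluded (strict <)
    assert frac == pytest.approx(2 / 3)
    assert set(overlap["pos"]) == {10, 30}
    n0, _, _ = intersect_mqtls(sel, mq.assign(pos=[100, 200, 300]))
    assert n0 == 0


# -- hypergeometric test -----------------------------------------------------

def enumeration_pvalue(N, in_pmd, gene_set, side):
    """Exhaustive enumeration over all equally likely draws of |set| genes."""
    genes = list(range(N))
    k_obs = len(set(gene_set) & set(in_pmd))
    K = len(gene_set)
    count = 0
    total = 0
    for draw in itertools.combinations(genes, K):
        k = len(set(draw) & set(in_pmd))
        total += 1
        if side == "enrichment" and k >= k_obs:
            count += 1
        if side == "depletion" and k <= k_obs:
            count += 1
    return count / total


def gene_frame(N):
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(N)],
            "chrom": "c1",
            "start": [i * 1000 for i in range(N)],
            "end": [i * 1000 + 500 for i in range(N)],
        }
    )


def test_hypergeom_spec_example():
    genes = gene_frame(10)
    pmds = IntervalSet.from_records([("c1", 0, 4500)])  # genes 0..4 overlap
    res = pmd_gene_set_test(genes, [f"g{i}" for i in range(4)], pmds, side="enrichment")
    assert res["k"] == 4 and res["n"] == 5 and res["N"] == 10 and res["K"] == 4
    assert res["p_value"] == pytest.approx(5 / 210)


@pytest.mark.parametrize("seed", range(6))
def test_hypergeom_matches_enumeration(seed):
    rng = np.random.default_rng(seed)
    N = int(rng.integers(5, 12))
    genes = gene_frame(N)
    n_in = int(rng.integers(1, N))
    in_idx = sorted(rng.choice(N, n_in, replace=False))
    pmds = IntervalSet.from_records([("c1", i * 1000, i * 1000 + 500) for i in in_idx])
    K = int(rng.integers(1, N))
    set_idx = sorted(rng.choice(N, K, replace=False))
    side = "enrichment" if rng.random() < 0.5 else "depletion"
    res = pmd_gene_set_test(genes, [f"g{i}" for i in set_idx], pmds, side=side)
    assert res["p_value"] == pytest.approx(
        enumeration_pvalue(N, in_idx, set_idx, side), abs=1e-12
    )


def test_hypergeom_guards():
    genes = gene_frame(5)
    with pytest.raises(ValueError, match="universe"):
        pmd_gene_set_test(genes, ["nope"], IntervalSet())
    with pytest.raises(ValueError):
        pmd_gene_set_test(genes.iloc[0:0], [], IntervalSet())
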