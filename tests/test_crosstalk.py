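"""Product-score arithmetic, permutation null (Monte-Carlo vs exhaustive),
theta-aggregate properties and differential condition calls."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st

from sctalk import (
    ClusterProfile,
    CrosstalkError,
    CrosstalkParams,
    NormMatrix,
    aggregate,
    differential,
    normalize,
    permutation_pvalues,
    score_all,
)
from tests.conftest import subset_condition


def make_profile(means: dict, clusters, genes=None, stratum=None):
    """ClusterProfile from {gene: [per-cluster means]}."""
    genes = genes or list(means)
    arr = np.array([means[g] for g in genes], dtype=float)
    return ClusterProfile(
        genes=list(genes),
        clusters=list(clusters),
        means=arr,
        n_cells=np.full(len(clusters), 100),
        stratum=stratum,
    )


def make_lrdb(pairs, categories=None):
    return pd.DataFrame(
        {
            "ligand_gene": [p[0] for p in pairs],
            "receptor_gene": [p[1] for p in pairs],
            "category": categories or ["other"] * len(pairs),
        }
    )


def make_norm(values, cells=None):
    values = np.asarray(values, dtype=float)
    return NormMatrix(
        genes=[f"g{i}" for i in range(values.shape[0])],
        cells=cells or [f"c{i}" for i in range(values.shape[1])],
        matrix=sp.csr_matrix(values),
    )


def make_meta(cells, clusters):
    return pd.DataFrame(
        {
            "cell_id": cells,
            "sample": ["s1"] * len(cells),
            "condition": ["normal"] * len(cells),
            "zone": ["inner"] * len(cells),
            "cluster": clusters,
            "doublet_score": [np.nan] * len(cells),
        }
    )


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def test_score_is_product_of_means():
    prof = make_profile({"L1": [2.0, 0.5], "R1": [0.1, 0.8]}, ["A", "B"])
    scores = score_all(prof, make_lrdb([("L1", "R1")]))
    row = scores.set_index(["sender", "receiver"]).loc[("A", "B")]
    assert row["score"] == pytest.approx(2.0 * 0.8)
    assert bool(row["passes_theta"])  # 1.6 > 1.5
    # autocrine pair included
    assert ("A", "A") in scores.set_index(["sender", "receiver"]).index


def test_zero_expression_scores_zero_and_fails_theta():
    prof = make_profile({"L1": [0.0, 0.0], "R1": [1.0, 1.0]}, ["A", "B"])
    scores = score_all(prof, make_lrdb([("L1", "R1")]))
    assert (scores["score"] == 0).all()
    assert not scores["passes_theta"].any()


def test_missing_gene_pairs_skipped_and_counted():
    prof = make_profile({"L1": [1.0], "R1": [1.0]}, ["A"])
    scores = score_all(prof, make_lrdb([("L1", "R1"), ("GHOST", "R1")]))
    assert len(scores) == 1
    assert scores.attrs["n_pairs_skipped"] == 1


def test_empty_lr_overlap_is_error_naming_missing_genes():
    prof = make_profile({"X": [1.0]}, ["A"])
    with pytest.raises(CrosstalkError, match="GHOST"):
        score_all(prof, make_lrdb([("GHOST", "SPIRIT")]))


def test_scores_invariant_to_gene_and_cluster_order():
    means = {"L1": [2.0, 0.5], "R1": [0.1, 0.8], "L2": [1.0, 1.5], "R2": [0.3, 0.9]}
    lrdb = make_lrdb([("L1", "R1"), ("L2", "R2")])
    a = score_all(make_profile(means, ["A", "B"], genes=["L1", "R1", "L2", "R2"]), lrdb)
    shuffled = {g: [means[g][1], means[g][0]] for g in means}
    b = score_all(make_profile(shuffled, ["B", "A"], genes=["R2", "L1", "R1", "L2"]), lrdb)
    key = ["sender", "receiver", "ligand", "receptor"]
    merged = a.merge(b, on=key, suffixes=("_a", "_b"))
    assert len(merged) == len(a)
    np.testing.assert_allclose(merged["score_a"], merged["score_b"])


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------


def test_identical_cells_give_p_one():
    values = np.ones((4, 10))
    norm = make_norm(values)
    meta = make_meta(norm.cells, ["A"] * 5 + ["B"] * 5)
    lrdb = make_lrdb([("g0", "g1"), ("g2", "g3")])
    res = permutation_pvalues(norm, meta, lrdb, CrosstalkParams(n_perm=200, seed=1))
    assert (res["p_empirical"] == 1.0).all()


def test_exhaustive_counts_all_distinct_assignments():
    rng = np.random.default_rng(0)
    norm = make_norm(rng.gamma(1, 1, size=(4, 6)))
    meta = make_meta(norm.cells, ["A"] * 3 + ["B"] * 3)
    lrdb = make_lrdb([("g0", "g1")])
    res = permutation_pvalues(
        norm, meta, lrdb, CrosstalkParams(exhaustive=True, seed=0)
    )
    # 6 cells in two clusters of 3 -> C(6,3) = 20 distinct assignments;
    # the identity is included so p is a multiple of 1/20 and never 0
    assert ((res["p_empirical"] * 20).round() == res["p_empirical"] * 20).all()
    assert (res["p_empirical"] > 0).all()
    assert (res["p_empirical"] <= 1).all()


def test_exhaustive_limit_enforced():
    rng = np.random.default_rng(0)
    norm = make_norm(rng.gamma(1, 1, size=(2, 16)))
    meta = make_meta(norm.cells, ["A"] * 8 + ["B"] * 8)
    with pytest.raises(CrosstalkError, match="exceed"):
        permutation_pvalues(
            norm, meta, make_lrdb([("g0", "g1")]),
            CrosstalkParams(exhaustive=True, exhaustive_limit=100),
        )


def test_small_n_perm_without_exhaustive_rejected():
    with pytest.raises(CrosstalkError, match="n_perm"):
        CrosstalkParams(n_perm=50).validate()


@pytest.mark.parametrize("sizes", [(3, 3), (4, 4), (2, 5)])
def test_monte_carlo_agrees_with_exhaustive_oracle(sizes):
    """On every instance small enough to enumerate, the Monte-Carlo p lies
    within 3 standard errors of the exact enumeration p."""
    rng = np.random.default_rng(sizes[0] * 10 + sizes[1])
    n = sum(sizes)
    norm = make_norm(rng.gamma(1, 1, size=(6, n)))
    meta = make_meta(norm.cells, ["A"] * sizes[0] + ["B"] * sizes[1])
    lrdb = make_lrdb([("g0", "g1"), ("g2", "g3"), ("g4", "g5")])
    exact = permutation_pvalues(norm, meta, lrdb, CrosstalkParams(exhaustive=True))
    n_perm = 1000
    mc = permutation_pvalues(norm, meta, lrdb, CrosstalkParams(n_perm=n_perm, seed=99))
    key = ["sender", "receiver", "ligand", "receptor"]
    merged = exact.merge(mc, on=key, suffixes=("_ex", "_mc"))
    q = merged["p_empirical_ex"].to_numpy()
    se = np.sqrt(q * (1 - q) / n_perm)
    tol = 3 * se + 1.0 / (n_perm + 1)  # +1/(N+1) absorbs the pseudocount bias
    assert (np.abs(merged["p_empirical_mc"] - q) <= tol).all()


def test_planted_pair_significant_null_pairs_not(planted_ds):
    norm = normalize(planted_ds.counts)
    sub, meta = subset_condition(norm, planted_ds.metadata, "normal")
    res = permutation_pvalues(
        sub, meta, planted_ds.lr_database, CrosstalkParams(n_perm=200, seed=5)
    )
    pi = planted_ds.truth.planted_interactions[0]
    row = res.set_index(["sender", "receiver", "ligand", "receptor"]).loc[
        (pi.sender, pi.receiver, pi.ligand, pi.receptor)
    ]
    assert row["p_empirical"] <= 0.05
    assert row["score"] > 1.5
    assert (res["p_adjusted"] >= res["p_empirical"] - 1e-12).all()


# ---------------------------------------------------------------------------
# aggregate
# ---------------------------------------------------------------------------


def test_aggregate_hand_computed_toy():
    """Two qualifying pairs for (A,B): 1.6 + 2.0 = 3.6 at theta=1.5; the
    failing third pair contributes nothing."""
    scores = pd.DataFrame(
        {
            "sender": ["A", "A", "A"],
            "receiver": ["B", "B", "B"],
            "ligand": ["L1", "L2", "L3"],
            "receptor": ["R1", "R2", "R3"],
            "score": [1.6, 2.0, 1.4],
        }
    )
    agg = aggregate(scores, CrosstalkParams(theta=1.5), clusters=["A", "B"])
    assert agg.loc["A", "B"] == pytest.approx(3.6)
    assert agg.loc["B", "A"] == 0.0


def test_aggregate_theta_limits(planted_ds):
    norm = normalize(planted_ds.counts)
    sub, meta = subset_condition(norm, planted_ds.metadata, "normal")
    from sctalk import cluster_means

    prof = cluster_means(sub, meta)
    scores = score_all(prof, planted_ds.lr_database)
    full = aggregate(scores, CrosstalkParams(theta=0.0))
    zero = aggregate(scores, CrosstalkParams(theta=np.inf))
    assert (zero.to_numpy() == 0).all()
    by_hand = scores.groupby(["sender", "receiver"])["score"].sum().unstack()
    np.testing.assert_allclose(full.to_numpy(), by_hand.to_numpy())


@settings(max_examples=20, deadline=None, derandomize=True)
@given(theta_lo=st.floats(0, 3), gap=st.floats(0, 3))
def test_aggregate_monotone_non_increasing_in_theta(theta_lo, gap):
    rng = np.random.default_rng(12)
    scores = pd.DataFrame(
        {
            "sender": rng.choice(["A", "B"], 50),
            "receiver": rng.choice(["A", "B"], 50),
            "ligand": [f"L{i}" for i in range(50)],
            "receptor": [f"R{i}" for i in range(50)],
            "score": rng.gamma(2.0, 1.0, 50),
        }
    )
    lo = aggregate(scores, CrosstalkParams(theta=theta_lo))
    hi = aggregate(scores, CrosstalkParams(theta=theta_lo + gap))
    assert (lo.to_numpy() >= hi.to_numpy() - 1e-12).all()
    assert (lo.to_numpy() >= 0).all()


# ---------------------------------------------------------------------------
# differential
# ---------------------------------------------------------------------------


def test_identical_profiles_all_unchanged():
    prof = make_profile({"L1": [2.0, 1.0], "R1": [1.0, 2.0]}, ["A", "B"])
    records, summary = differential(prof, prof, make_lrdb([("L1", "R1")]))
    assert (records["difference"] == 0).all()
    assert (records["call"] == "unchanged").all()
    assert summary["unchanged"].sum() == len(records)


def test_differential_call_arithmetic():
    """score_normal 2.0 vs score_degenerated 0.1 at theta=1.5, delta=0.5
    must come out high_in_normal."""
    prof_n = make_profile({"L1": [2.0], "R1": [1.0]}, ["A"])
    prof_d = make_profile({"L1": [0.5], "R1": [0.2]}, ["A"])
    records, _ = differential(prof_n, prof_d, make_lrdb([("L1", "R1")]))
    row = records.iloc[0]
    assert row["score_normal"] == pytest.approx(2.0)
    assert row["score_degenerated"] == pytest.approx(0.1)
    assert row["call"] == "high_in_normal"


def test_differential_requires_common_clusters():
    prof_n = make_profile({"L1": [2.0], "R1": [1.0]}, ["A"])
    prof_d = make_profile({"L1": [2.0], "R1": [1.0]}, ["B"])
    with pytest.raises(CrosstalkError, match="share no clusters"):
        differential(prof_n, prof_d, make_lrdb([("L1", "R1")]))


def test_differential_category_summary_counts():
    prof_n = make_profile({"L1": [2.0], "R1": [2.0], "L2": [0.1], "R2": [0.1]}, ["A"])
    prof_d = make_profile({"L1": [0.1], "R1": [0.1], "L2": [2.0], "R2": [2.0]}, ["A"])
    lrdb = make_lrdb([("L1", "R1"), ("L2", "R2")], categories=["ECM", "TNF"])
    records, summary = differential(prof_n, prof_d, lrdb)
    assert summary.loc["ECM", "high_in_normal"] == 1
    assert summary.loc["TNF", "high_in_degenerated"] == 1


def test_planted_condition_specific_interaction_called(diff_ds):
    """A degenerated-only fold-4 planted pair is called high_in_degenerated
    at the defaults."""
    norm = normalize(diff_ds.counts)
    from sctalk import cluster_means_stratified

    profs = cluster_means_stratified(norm, diff_ds.metadata)
    records, _ = differential(
        profs[("normal",)], profs[("degenerated",)], diff_ds.lr_database
    )
    idx = records.set_index(["sender", "receiver", "ligand", "receptor"])
    for pi in diff_ds.truth.planted_interactions[:3]:
        assert pi.condition_specific == "degenerated_only"
        assert idx.loc[(pi.sender, pi.receiver, pi.ligand, pi.receptor), "call"] == (
            "high_in_degenerated"
        )
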