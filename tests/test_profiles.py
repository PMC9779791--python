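"""Normalization arithmetic, cluster-profile invariances, rank-sum testing
(against an exhaustive rank-enumeration oracle) and composition statistics."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from sctalk import (
    CountMatrix,
    NormMatrix,
    cluster_means,
    cluster_means_stratified,
    compare_composition,
    composition_stats,
    normalize,
    rank_sum_markers,
)
import scipy.sparse as sp


def exhaustive_ranksum_p(x, y):
    """Exact two-sided rank-sum p by enumerating every assignment of the
    pooled values into a group of len(x); independent of scipy."""
    pooled = np.concatenate([x, y])
    n = len(pooled)
    ranks = pd.Series(pooled).rank().to_numpy()
    obs = ranks[: len(x)].sum()
    mu = len(x) * (n + 1) / 2
    count = total = 0
    for idx in combinations(range(n), len(x)):
        total += 1
        if abs(ranks[list(idx)].sum() - mu) >= abs(obs - mu) - 1e-9:
            count += 1
    return count / total


def _meta(cells, clusters, conditions=None, samples=None, zones=None):
    n = len(cells)
    return pd.DataFrame(
        {
            "cell_id": cells,
            "sample": samples or ["s1"] * n,
            "condition": conditions or ["normal"] * n,
            "zone": zones or ["inner"] * n,
            "cluster": clusters,
            "doublet_score": [np.nan] * n,
        }
    )


def _norm_from_values(values, genes=None, cells=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cells = cells or [f"c{i}" for i in range(values.shape[1])]
    return NormMatrix(genes=genes, cells=cells, matrix=sp.csr_matrix(values))


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def test_normalize_closed_form_single_gene_cell():
    cm = CountMatrix(genes=["g1", "g2"], cells=["c1"], matrix=np.array([[10], [0]]))
    norm = normalize(cm)
    assert norm.matrix[0, 0] == pytest.approx(np.log1p(10000))
    assert norm.matrix[1, 0] == 0.0


def test_normalize_depth_invariance_and_zero_gene(planted_ds):
    cm = planted_ds.counts
    doubled = CountMatrix(genes=cm.genes, cells=cm.cells, matrix=cm.matrix * 2)
    a = normalize(cm).matrix[:, 0].toarray()
    b = normalize(doubled).matrix[:, 0].toarray()
    np.testing.assert_allclose(a, b, rtol=1e-12)


def test_normalize_cp10k_sums(planted_ds):
    norm = normalize(planted_ds.counts)
    dense = norm.matrix.toarray()
    sums = np.expm1(dense).sum(axis=0)
    np.testing.assert_allclose(sums, 1e4, rtol=1e-6)
    assert norm.provenance == {"scale_factor": 1e4, "transform": "log1p"}


def test_normalize_zero_count_cell_names_offender():
    cm = CountMatrix(genes=["g1"], cells=["ok", "empty"], matrix=np.array([[3, 0]]))
    with pytest.raises(ValueError, match="empty"):
        normalize(cm)


# ---------------------------------------------------------------------------
# cluster means
# ---------------------------------------------------------------------------


def test_cluster_mean_arithmetic():
    norm = _norm_from_values([[1.0, 3.0, 5.0]])
    meta = _meta(["c0", "c1", "c2"], ["A", "A", "B"])
    prof = cluster_means(norm, meta, min_cells=1)
    assert prof.mean_of("g0", "A") == 2.0
    assert prof.mean_of("g0", "B") == 5.0


def test_cluster_means_invariant_to_cell_order_and_duplication():
    rng = np.random.default_rng(3)
    values = rng.gamma(1.0, 1.0, size=(5, 40))
    cells = [f"c{i}" for i in range(40)]
    clusters = ["A" if i < 25 else "B" for i in range(40)]
    prof = cluster_means(_norm_from_values(values, cells=cells), _meta(cells, clusters), min_cells=1)

    perm = rng.permutation(40)
    prof_perm = cluster_means(
        _norm_from_values(values[:, perm], cells=[cells[i] for i in perm]),
        _meta(cells, clusters),
        min_cells=1,
    )
    np.testing.assert_allclose(prof.means, prof_perm.means)

    cells2 = cells + [f"d{i}" for i in range(40)]
    prof_dup = cluster_means(
        _norm_from_values(np.hstack([values, values]), cells=cells2),
        _meta(cells2, clusters + clusters),
        min_cells=1,
    )
    np.testing.assert_allclose(prof.means, prof_dup.means)


def test_cluster_means_drops_small_clusters():
    values = np.ones((2, 12))
    cells = [f"c{i}" for i in range(12)]
    clusters = ["A"] * 10 + ["tiny"] * 2
    with pytest.warns(UserWarning, match="tiny"):
        prof = cluster_means(_norm_from_values(values, cells=cells), _meta(cells, clusters))
    assert prof.clusters == ["A"]


def test_stratified_profiles_partition_conditions(planted_ds):
    norm = normalize(planted_ds.counts)
    profs = cluster_means_stratified(norm, planted_ds.metadata, stratify_by=("condition",))
    assert set(profs) == {("normal",), ("degenerated",)}
    assert profs[("normal",)].clusters == profs[("degenerated",)].clusters
    total = sum(int(p.n_cells.sum()) for p in profs.values())
    assert total == planted_ds.counts.n_cells


def test_stratified_unknown_key_rejected(planted_ds):
    norm = normalize(planted_ds.counts)
    with pytest.raises(ValueError, match="unknown stratification"):
        cluster_means_stratified(norm, planted_ds.metadata, stratify_by=("sample",))


# ---------------------------------------------------------------------------
# rank-sum markers
# ---------------------------------------------------------------------------


def test_identical_groups_give_p_one():
    values = np.ones((1, 10))
    cells = [f"c{i}" for i in range(10)]
    meta = _meta(cells, ["A"] * 5 + ["B"] * 5)
    degs = rank_sum_markers(_norm_from_values(values, cells=cells), meta, group="A")
    assert degs["p_value"].iloc[0] == 1.0


def test_complete_separation_exact_p_matches_enumeration_oracle():
    """4 vs 4 distinct, fully separated values: the exact two-sided rank-sum
    p equals 2/70, verified against exhaustive enumeration of C(8,4)
    assignments."""
    x = np.array([1.0, 2.0, 3.0, 4.0])
    y = np.array([11.0, 12.0, 13.0, 14.0])
    oracle = exhaustive_ranksum_p(x, y)
    assert oracle == pytest.approx(2 / 70)

    values = np.concatenate([x, y])[None, :]
    cells = [f"c{i}" for i in range(8)]
    meta = _meta(cells, ["A"] * 4 + ["B"] * 4)
    degs = rank_sum_markers(_norm_from_values(values, cells=cells), meta, group="A")
    assert degs["p_value"].iloc[0] == pytest.approx(oracle, abs=1e-12)
    assert degs["log2_fold_change"].iloc[0] < 0


def test_planted_marker_detected(planted_ds):
    """A fold-3 cluster marker at n=200/side comes out with adjusted p < 0.05
    and a positive log2 fold change."""
    norm = normalize(planted_ds.counts)
    marker = planted_ds.catalog.markers["c0"][0]
    degs = rank_sum_markers(norm, planted_ds.metadata, group="c0")
    row = degs[degs["gene"] == marker].iloc[0]
    assert row["adjusted_p"] < 0.05
    assert row["log2_fold_change"] > 0
    assert (degs["adjusted_p"] >= degs["p_value"] - 1e-12).all()
    assert degs["pct_in"].between(0, 100).all()


def test_null_condition_contrast_calibrated(null_ds):
    """With nothing planted, conditions are exchangeable: the raw-p < 0.05
    fraction over >= 500 tested genes stays near the nominal 5%."""
    norm = normalize(null_ds.counts)
    degs = rank_sum_markers(norm, null_ds.metadata, contrast="condition_overall")
    assert len(degs) >= 500
    frac = (degs["p_value"] < 0.05).mean()
    assert 0.03 <= frac <= 0.07


def test_degenerate_contrast_rejected():
    values = np.ones((1, 6))
    cells = [f"c{i}" for i in range(6)]
    meta = _meta(cells, ["A"] * 6)
    with pytest.raises(ValueError, match=">= 3 cells"):
        rank_sum_markers(_norm_from_values(values, cells=cells), meta, group="A")


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------


def test_composition_percentages_sum_to_100(planted_ds):
    table = composition_stats(planted_ds.metadata)
    sums = table.groupby("sample")["percent"].sum()
    np.testing.assert_allclose(sums.to_numpy(), 100.0, rtol=1e-9)


def _composition_table(normal, degenerated):
    rows = []
    for i, p in enumerate(normal):
        rows.append((f"n{i}", "normal", "inner", "T", p))
    for i, p in enumerate(degenerated):
        rows.append((f"d{i}", "degenerated", "inner", "T", p))
    return pd.DataFrame(rows, columns=["sample", "condition", "zone", "cell_type", "percent"])


def test_composition_identical_percentages_give_p_one():
    table = _composition_table([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
    assert compare_composition(table, "T").p_value == 1.0


def test_composition_exact_p_matches_enumeration_oracle():
    normal, degen = [1.0, 2.0, 3.0, 4.0], [11.0, 12.0, 13.0, 14.0]
    oracle = exhaustive_ranksum_p(np.array(normal), np.array(degen))
    res = compare_composition(_composition_table(normal, degen), "T")
    assert res.method == "exact"
    assert res.p_value == pytest.approx(oracle) == pytest.approx(2 / 70)


def test_composition_single_sample_condition_is_na():
    table = _composition_table([5.0], [4.0, 6.0])
    with pytest.warns(UserWarning, match="fewer than 2 samples"):
        res = compare_composition(table, "T")
    assert np.isnan(res.p_value)
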