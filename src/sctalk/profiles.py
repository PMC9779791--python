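"""Normalization, per-cluster expression profiles, rank-sum marker tests and
per-sample composition statistics.

Normalization is counts-per-10k followed by natural log1p (CP10K/log1p),
the de-facto convention of the droplet toolchains.  The per-cluster profile
holds, for every gene g and cluster i, the arithmetic mean of the
normalized values over the cluster's cells — for a ligand gene this is the
E_L,i entering the crosstalk product, for a receptor gene the E_R,j.
Averaging is done in log space by default (robust to outlier cells); a
linear-space alternative is exposed via ``space="linear"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu, false_discovery_control

from .io import CountMatrix, align_metadata

SCALE_FACTOR = 1e4
#: clusters with fewer cells than this are dropped from profiles
MIN_CELLS_DEFAULT = 10
#: genes expressed in less than this fraction of both sides are not tested
MIN_PCT_EXPRESSED = 0.10
LOG2FC_PSEUDOCOUNT = 1e-9

CONTRASTS = ("group_vs_rest", "condition_within_group", "condition_overall")


@dataclass
class NormMatrix:
    """Genes x cells normalized expression with its provenance."""

    genes: list[str]
    cells: list[str]
    matrix: sp.csr_matrix = field(repr=False)
    provenance: dict = field(
        default_factory=lambda: {"scale_factor": SCALE_FACTOR, "transform": "log1p"}
    )

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def gene_index(self, genes) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.genes)}
        return np.array([lookup[g] for g in genes], dtype=int)


@dataclass
class ClusterProfile:
    """Mean normalized expression per gene per cluster (the E values)."""

    genes: list[str]
    clusters: list[str]
    means: np.ndarray = field(repr=False)  # genes x clusters
    n_cells: np.ndarray = field(repr=False)  # per cluster
    stratum: dict | None = None

    def mean_of(self, gene: str, cluster: str) -> float:
        return float(self.means[self.genes.index(gene), self.clusters.index(cluster)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.means, index=self.genes, columns=self.clusters)


def normalize(counts: CountMatrix) -> NormMatrix:
    """CP10K/log1p: value[g,c] = log1p(1e4 * count[g,c] / n_counts[c]).

    Zero-count cells cannot be normalized; they should have been removed by
    QC, and raising here names the first offender.
    """
    depth = np.asarray(counts.matrix.sum(axis=0)).ravel().astype(float)
    if np.any(depth == 0):
        bad = counts.cells[int(np.argmax(depth == 0))]
        raise ValueError(
            f"cell {bad!r} has zero counts and cannot be normalized; "
            "run QC filtering first"
        )
    mat = counts.matrix.astype(float).tocsc()
    mat = mat.multiply(SCALE_FACTOR / depth[None, :]).tocsr()
    mat.data = np.log1p(mat.data)
    return NormMatrix(genes=list(counts.genes), cells=list(counts.cells), matrix=mat)


def _group_means(mat: sp.csr_matrix, group_idx: np.ndarray, k: int) -> np.ndarray:
    """Column-group means of a sparse matrix via an indicator product."""
    n = mat.shape[1]
    indicator = sp.csr_matrix(
        (np.ones(n), (np.arange(n), group_idx)), shape=(n, k)
    )
    sums = np.asarray((mat @ indicator).todense())
    sizes = np.bincount(group_idx, minlength=k).astype(float)
    return sums / sizes[None, :]


def cluster_means(
    norm: NormMatrix,
    metadata: pd.DataFrame,
    min_cells: int = MIN_CELLS_DEFAULT,
    cluster_key: str = "cluster",
    space: str = "log",
    stratum: dict | None = None,
) -> ClusterProfile:
    """Arithmetic mean normalized expression per cluster.

    ``space="log"`` averages the log1p values directly (default);
    ``space="linear"`` averages expm1 of the values and re-logs the mean.
    Clusters with fewer than ``min_cells`` cells are dropped with a warning.
    """
    meta = metadata.set_index("cell_id").loc[norm.cells]
    labels = meta[cluster_key].astype(str)
    clusters = sorted(labels.unique())
    sizes = labels.value_counts()
    small = [c for c in clusters if sizes[c] < min_cells]
    if small:
        warnings.warn(
            f"dropping cluster(s) {small} with fewer than {min_cells} cells", stacklevel=2
        )
        clusters = [c for c in clusters if c not in small]
    if not clusters:
        raise ValueError("no cluster meets the minimum cell count")
    keep = labels.isin(clusters).to_numpy()
    mat = norm.matrix[:, keep]
    lab = labels[keep]
    cmap = {c: i for i, c in enumerate(clusters)}
    gidx = lab.map(cmap).to_numpy()
    if space == "log":
        means = _group_means(mat, gidx, len(clusters))
    elif space == "linear":
        lin = mat.copy()
        lin.data = np.expm1(lin.data)
        means = np.log1p(_group_means(lin, gidx, len(clusters)))
    else:
        raise ValueError(f"unknown averaging space {space!r}")
    return ClusterProfile(
        genes=list(norm.genes),
        clusters=clusters,
        means=means,
        n_cells=np.bincount(gidx, minlength=len(clusters)),
        stratum=stratum,
    )


def cluster_means_stratified(
    norm: NormMatrix,
    metadata: pd.DataFrame,
    stratify_by=("condition",),
    **kwargs,
) -> dict[tuple, ClusterProfile]:
    """One :func:`cluster_means` profile per stratum of the metadata.

    ``stratify_by`` is a subset of {"condition", "zone"}; the returned dict
    is keyed by tuples of stratum values in that order.
    """
    stratify_by = list(stratify_by)
    bad = set(stratify_by) - {"condition", "zone"}
    if bad:
        raise ValueError(f"unknown stratification key(s) {sorted(bad)}")
    if not stratify_by:
        raise ValueError("stratify_by must name at least one key")
    meta = metadata.set_index("cell_id").loc[norm.cells].reset_index()
    out: dict[tuple, ClusterProfile] = {}
    for key, grp in meta.groupby(stratify_by, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        mask = np.zeros(len(meta), dtype=bool)
        mask[grp.index.to_numpy()] = True
        sub = NormMatrix(
            genes=norm.genes,
            cells=[c for c, m in zip(norm.cells, mask) if m],
            matrix=norm.matrix[:, mask],
            provenance=norm.provenance,
        )
        out[key] = cluster_means(
            sub, grp, stratum=dict(zip(stratify_by, key)), **kwargs
        )
    return out


# ---------------------------------------------------------------------------
# rank-sum differential expression
# ---------------------------------------------------------------------------


def _ranksum_rows(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p per row of X (group) vs Y (rest).

    Exact null when both sides are small and the row is tie-free,
    normal approximation with tie correction otherwise.  Rows whose values
    are all identical across both sides get p = 1 (complete ties).
    """
    n1, n2 = X.shape[1], Y.shape[1]
    pooled = np.concatenate([X, Y], axis=1)
    all_tied = np.all(pooled == pooled[:, [0]], axis=1)
    pvals = np.ones(X.shape[0])
    todo = ~all_tied
    if not todo.any():
        return pvals
    if min(n1, n2) <= 8:
        for i in np.flatnonzero(todo):
            row_ties = len(np.unique(pooled[i])) < n1 + n2
            method = "asymptotic" if row_ties else "exact"
            res = mannwhitneyu(X[i], Y[i], alternative="two-sided", method=method)
            pvals[i] = res.pvalue
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = mannwhitneyu(
                X[todo], Y[todo], alternative="two-sided", method="asymptotic", axis=1
            )
        p = np.atleast_1d(res.pvalue)
        p[np.isnan(p)] = 1.0
        pvals[todo] = p
    return np.clip(pvals, 0.0, 1.0)


def _test_two_sides(norm: NormMatrix, in_mask: np.ndarray, group_label: str) -> pd.DataFrame:
    n_in, n_out = int(in_mask.sum()), int((~in_mask).sum())
    if n_in < 3 or n_out < 3:
        raise ValueError(
            f"contrast {group_label!r} needs >= 3 cells on each side "
            f"(got {n_in} vs {n_out})"
        )
    X = np.asarray(norm.matrix[:, in_mask].todense())
    Y = np.asarray(norm.matrix[:, ~in_mask].todense())
    pct_in = 100.0 * (X > 0).mean(axis=1)
    pct_out = 100.0 * (Y > 0).mean(axis=1)
    tested = (pct_in >= 100 * MIN_PCT_EXPRESSED) | (pct_out >= 100 * MIN_PCT_EXPRESSED)
    if not tested.any():
        return pd.DataFrame(
            columns=["gene", "group", "log2_fold_change", "p_value", "adjusted_p",
                     "pct_in", "pct_out"]
        )
    p = _ranksum_rows(X[tested], Y[tested])
    mean_in = np.expm1(X[tested]).mean(axis=1)
    mean_out = np.expm1(Y[tested]).mean(axis=1)
    lfc = np.log2((mean_in + LOG2FC_PSEUDOCOUNT) / (mean_out + LOG2FC_PSEUDOCOUNT))
    adj = false_discovery_control(p, method="bh")
    genes = np.asarray(norm.genes)[tested]
    return pd.DataFrame(
        {
            "gene": genes,
            "group": group_label,
            "log2_fold_change": lfc,
            "p_value": p,
            "adjusted_p": np.maximum(adj, p),
            "pct_in": pct_in[tested],
            "pct_out": pct_out[tested],
        }
    )


def rank_sum_markers(
    norm: NormMatrix,
    metadata: pd.DataFrame,
    contrast: str = "group_vs_rest",
    group: str | None = None,
    cluster_key: str = "cluster",
) -> pd.DataFrame:
    """Wilcoxon rank-sum differential expression.

    Contrasts:

    * ``group_vs_rest`` — each cluster (or the one named by ``group``)
      against all other cells; the marker-gene contrast.
    * ``condition_within_group`` — degenerated vs normal cells inside the
      cluster named by ``group``.
    * ``condition_overall`` — degenerated vs normal over all cells.

    Genes expressed in fewer than 10% of the cells on both sides are not
    tested.  BH adjustment is computed over the tested genes of each
    contrast.  log2 fold changes compare expm1-means with a tiny
    pseudocount; positive values mean higher in the named group
    (degenerated, for condition contrasts).
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; expected one of {CONTRASTS}")
    meta = metadata.set_index("cell_id").loc[norm.cells].reset_index()
    labels = meta[cluster_key].astype(str).to_numpy()
    condition = meta["condition"].to_numpy()

    frames = []
    if contrast == "group_vs_rest":
        targets = [group] if group is not None else sorted(set(labels))
        for g in targets:
            in_mask = labels == g
            if not in_mask.any():
                raise ValueError(f"cluster {g!r} has no cells")
            frames.append(_test_two_sides(norm, in_mask, str(g)))
    elif contrast == "condition_within_group":
        if group is None:
            raise ValueError("condition_within_group requires a group")
        sub = labels == group
        if not sub.any():
            raise ValueError(f"cluster {group!r} has no cells")
        sub_norm = NormMatrix(
            genes=norm.genes,
            cells=[c for c, m in zip(norm.cells, sub) if m],
            matrix=norm.matrix[:, sub],
            provenance=norm.provenance,
        )
        in_mask = condition[sub] == "degenerated"
        frames.append(
            _test_two_sides(sub_norm, in_mask, f"{group}:degenerated_vs_normal")
        )
    else:  # condition_overall
        in_mask = condition == "degenerated"
        frames.append(_test_two_sides(norm, in_mask, "degenerated_vs_normal"))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------


def composition_stats(metadata: pd.DataFrame, cluster_key: str = "cluster") -> pd.DataFrame:
    """Per-sample cell-type percentages.

    Rows are (sample, condition, zone, cell_type, percent); the percents of
    one sample sum to 100 across its (zone, cell_type) combinations.
    """
    counts = (
        metadata.groupby(["sample", "condition", "zone", cluster_key], observed=True)
        .size()
        .rename("n")
        .reset_index()
        .rename(columns={cluster_key: "cell_type"})
    )
    totals = counts.groupby("sample")["n"].transform("sum")
    counts["percent"] = 100.0 * counts["n"] / totals
    return counts.drop(columns="n")


@dataclass
class CompositionTest:
    cell_type: str
    p_value: float
    method: str
    percents_normal: list[float]
    percents_degenerated: list[float]


def compare_composition(table: pd.DataFrame, cell_type: str) -> CompositionTest:
    """Two-sided Wilcoxon rank-sum on per-sample percentages between conditions.

    Exact null when the total number of samples is <= 20 and the
    percentages are tie-free; normal approximation otherwise.  A condition
    with fewer than 2 samples yields p = NA with a warning.
    """
    samples = table[["sample", "condition"]].drop_duplicates()
    per_sample = (
        table[table["cell_type"] == cell_type]
        .groupby("sample")["percent"]
        .sum()
        .reindex(samples["sample"])
        .fillna(0.0)
    )
    sides = {}
    for cond in ("normal", "degenerated"):
        ids = samples.loc[samples["condition"] == cond, "sample"]
        sides[cond] = per_sample.loc[ids].to_numpy()
    if min(len(sides["normal"]), len(sides["degenerated"])) < 2:
        warnings.warn(
            f"fewer than 2 samples in a condition for {cell_type!r}; p set to NA",
            stacklevel=2,
        )
        return CompositionTest(cell_type, np.nan, "NA",
                               list(sides["normal"]), list(sides["degenerated"]))
    pooled = np.concatenate([sides["normal"], sides["degenerated"]])
    if np.all(pooled == pooled[0]):
        return CompositionTest(cell_type, 1.0, "degenerate",
                               list(sides["normal"]), list(sides["degenerated"]))
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 20 and tie_free) else "asymptotic"
    res = mannwhitneyu(
        sides["degenerated"], sides["normal"], alternative="two-sided", method=method
    )
    return CompositionTest(cell_type, float(res.pvalue), method,
                           list(sides["normal"]), list(sides["degenerated"]))
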