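"""Cluster-level ligand-receptor crosstalk scoring.

The crosstalk between a sender cluster i and a receiver cluster j through a
ligand-receptor pair L-R is the product E_L,i * E_R,j of the sender's mean
normalized ligand expression and the receiver's mean normalized receptor
expression.  Significance is assessed empirically by shuffling the cluster
labels over cells (cluster sizes preserved), recomputing the E values and
counting null products at least as large as the observed one.  The overall
crosstalk level between clusters i and j aggregates the products over all
pairs whose product exceeds a threshold theta (default 1.5).  Differential
crosstalk between two conditions subtracts the per-pair products and calls
a pair high-in-degenerated / high-in-normal when the difference clears a
configurable band and the higher side clears theta.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control

from .profiles import ClusterProfile, NormMatrix

DIFF_CALLS = ("high_in_degenerated", "high_in_normal", "unchanged")


class CrosstalkError(ValueError):
    pass


@dataclass
class CrosstalkParams:
    """Tunables of the crosstalk computation.

    theta is the product threshold entering the aggregate (and the
    differential call); n_perm the number of label shuffles; alpha the
    significance level on empirical p-values; diff_delta the half-width of
    the "unchanged" band on score differences.  ``exhaustive`` switches the
    permutation null to exact enumeration of all distinct label assignments
    when their number is at most ``exhaustive_limit``.  ``tail`` controls
    how "more extreme" is counted: "greater" (default, enhanced crosstalk)
    or "two_sided".
    """

    theta: float = 1.5
    n_perm: int = 1000
    alpha: float = 0.05
    diff_delta: float = 0.5
    seed: int = 0
    exhaustive: bool = False
    exhaustive_limit: int = 100_000
    tail: str = "greater"
    require_significant: bool = False

    def validate(self) -> None:
        if self.theta < 0:
            raise CrosstalkError("theta must be >= 0")
        if not 0 < self.alpha < 1:
            raise CrosstalkError("alpha must lie in (0, 1)")
        if self.diff_delta < 0:
            raise CrosstalkError("diff_delta must be >= 0")
        if self.tail not in ("greater", "two_sided"):
            raise CrosstalkError(f"unknown tail {self.tail!r}")
        if not self.exhaustive and self.n_perm < 100:
            raise CrosstalkError(
                f"n_perm={self.n_perm} is too small for a stable empirical p; "
                "use >= 100 or exhaustive=True"
            )


def _pair_indices(genes, lrdb: pd.DataFrame):
    """Row indices of ligand/receptor genes present in ``genes``.

    Returns (pairs_df, lig_idx, rec_idx, n_skipped); raises when no pair
    survives, naming example missing genes.
    """
    lookup = {g: i for i, g in enumerate(genes)}
    present = lrdb["ligand_gene"].isin(lookup) & lrdb["receptor_gene"].isin(lookup)
    n_skipped = int((~present).sum())
    pairs = lrdb.loc[present].reset_index(drop=True)
    if pairs.empty:
        missing = sorted(
            set(lrdb["ligand_gene"]).union(lrdb["receptor_gene"]) - set(lookup)
        )[:5]
        raise CrosstalkError(
            "no ligand-receptor pair has both genes in the matrix "
            f"(missing e.g. {missing})"
        )
    lig_idx = np.array([lookup[g] for g in pairs["ligand_gene"]], dtype=int)
    rec_idx = np.array([lookup[g] for g in pairs["receptor_gene"]], dtype=int)
    return pairs, lig_idx, rec_idx, n_skipped


def _score_tensor(E: np.ndarray, lig_idx: np.ndarray, rec_idx: np.ndarray) -> np.ndarray:
    """(n_pairs, k, k) products E_L,i * E_R,j from a genes x k mean matrix."""
    return E[lig_idx][:, :, None] * E[rec_idx][:, None, :]


def _tensor_to_frame(
    scores: np.ndarray, pairs: pd.DataFrame, clusters, theta: float
) -> pd.DataFrame:
    n_pairs, k, _ = scores.shape
    senders = np.tile(np.repeat(clusters, k), n_pairs)
    receivers = np.tile(clusters, k * n_pairs)
    df = pd.DataFrame(
        {
            "sender": senders,
            "receiver": receivers,
            "ligand": np.repeat(pairs["ligand_gene"].to_numpy(), k * k),
            "receptor": np.repeat(pairs["receptor_gene"].to_numpy(), k * k),
            "category": np.repeat(pairs["category"].to_numpy(), k * k),
            "score": scores.reshape(-1),
        }
    )
    df["passes_theta"] = df["score"] > theta
    return df


def score_all(
    profile: ClusterProfile, lrdb: pd.DataFrame, params: CrosstalkParams | None = None
) -> pd.DataFrame:
    """Product scores for every (sender, receiver, ligand, receptor).

    Includes autocrine pairs (sender == receiver).  Database pairs whose
    ligand or receptor is absent from the profile are skipped; the count is
    available as ``df.attrs["n_pairs_skipped"]``.
    """
    params = params or CrosstalkParams()
    params.validate()
    pairs, lig_idx, rec_idx, n_skipped = _pair_indices(profile.genes, lrdb)
    scores = _score_tensor(profile.means, lig_idx, rec_idx)
    df = _tensor_to_frame(scores, pairs, np.asarray(profile.clusters), params.theta)
    df.attrs["n_pairs_skipped"] = n_skipped
    return df


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------


def _distinct_assignment_count(sizes) -> int:
    n = int(sum(sizes))
    total = math.factorial(n)
    for s in sizes:
        total //= math.factorial(int(s))
    return total


def _iter_multiset_permutations(counts: np.ndarray):
    """Yield every distinct arrangement of a label multiset.

    ``counts[s]`` is the multiplicity of symbol s; arrangements are emitted
    in lexicographic order as int arrays.  Classic counting recursion; the
    caller bounds the total via :func:`_distinct_assignment_count`.
    """
    n = int(counts.sum())
    out = np.empty(n, dtype=int)
    counts = counts.copy()

    def rec(pos: int):
        if pos == n:
            yield out.copy()
            return
        for s in range(len(counts)):
            if counts[s] == 0:
                continue
            counts[s] -= 1
            out[pos] = s
            yield from rec(pos + 1)
            counts[s] += 1

    yield from rec(0)


def _group_means_dense(X: np.ndarray, gidx: np.ndarray, k: int, sizes: np.ndarray) -> np.ndarray:
    onehot = np.zeros((X.shape[1], k))
    onehot[np.arange(X.shape[1]), gidx] = 1.0
    return (X @ onehot) / sizes[None, :]


def permutation_pvalues(
    norm: NormMatrix,
    metadata: pd.DataFrame,
    lrdb: pd.DataFrame,
    params: CrosstalkParams | None = None,
    cluster_key: str = "cluster",
) -> pd.DataFrame:
    """Product scores with empirical permutation p-values.

    Cluster labels are shuffled uniformly over the cells of ``norm``
    (cluster sizes preserved); E values are recomputed on the shuffled
    labels and null products compared against the observed ones.  With the
    Monte-Carlo null, p = (1 + #{null >= observed}) / (n_perm + 1), so p is
    never 0; with ``exhaustive=True`` all distinct assignments are
    enumerated and p is the exact tail fraction, the identity assignment
    included in numerator and denominator.

    When the data are stratified by condition, call this once per stratum:
    the shuffle then stays within the stratum, preserving the design.

    BH-adjusted p-values are provided within each (sender, receiver)
    family as ``p_adjusted``.
    """
    params = params or CrosstalkParams()
    params.validate()
    meta = metadata.set_index("cell_id").loc[norm.cells]
    labels = meta[cluster_key].astype(str).to_numpy()
    clusters = np.array(sorted(set(labels)))
    cmap = {c: i for i, c in enumerate(clusters)}
    gidx = np.array([cmap[l] for l in labels])
    k = len(clusters)
    sizes = np.bincount(gidx, minlength=k).astype(float)
    if np.any(sizes < 2):
        small = [c for c, s in zip(clusters, sizes) if s < 2]
        warnings.warn(
            f"cluster(s) {small} have fewer than 2 cells; empirical p is unstable",
            stacklevel=2,
        )

    pairs, lig_idx, rec_idx, n_skipped = _pair_indices(norm.genes, lrdb)
    need = np.unique(np.concatenate([lig_idx, rec_idx]))
    remap = {g: i for i, g in enumerate(need)}
    X = np.asarray(norm.matrix[need, :].todense())
    lig_r = np.array([remap[g] for g in lig_idx])
    rec_r = np.array([remap[g] for g in rec_idx])

    E_obs = _group_means_dense(X, gidx, k, sizes)
    obs = _score_tensor(E_obs, lig_r, rec_r)

    ge = np.zeros_like(obs)
    le = np.zeros_like(obs)
    if params.exhaustive:
        total = _distinct_assignment_count(sizes)
        if total > params.exhaustive_limit:
            raise CrosstalkError(
                f"{total} distinct label assignments exceed the exhaustive "
                f"limit of {params.exhaustive_limit}"
            )
        counts = np.bincount(gidx, minlength=k)
        for assign in _iter_multiset_permutations(counts):
            E_null = _group_means_dense(X, assign, k, sizes)
            null = _score_tensor(E_null, lig_r, rec_r)
            ge += null >= obs
            le += null <= obs
        p_greater = ge / total
        p_less = le / total
    else:
        rng = np.random.default_rng(params.seed)
        for _ in range(params.n_perm):
            perm = rng.permutation(gidx)
            E_null = _group_means_dense(X, perm, k, sizes)
            null = _score_tensor(E_null, lig_r, rec_r)
            ge += null >= obs
            le += null <= obs
        p_greater = (1.0 + ge) / (params.n_perm + 1.0)
        p_less = (1.0 + le) / (params.n_perm + 1.0)

    if params.tail == "greater":
        p = p_greater
    else:
        p = np.minimum(1.0, 2.0 * np.minimum(p_greater, p_less))

    df = _tensor_to_frame(obs, pairs, clusters, params.theta)
    df["p_empirical"] = p.reshape(-1)
    df["p_adjusted"] = (
        df.groupby(["sender", "receiver"], sort=False)["p_empirical"]
        .transform(lambda s: false_discovery_control(s.to_numpy(), method="bh"))
    )
    df.attrs["n_pairs_skipped"] = n_skipped
    df.attrs["null"] = "exhaustive" if params.exhaustive else f"monte_carlo:{params.n_perm}"
    return df


# ---------------------------------------------------------------------------
# aggregate and differential
# ---------------------------------------------------------------------------


def aggregate(
    scores: pd.DataFrame,
    params: CrosstalkParams | None = None,
    clusters=None,
) -> pd.DataFrame:
    """Overall crosstalk matrix: entry (i, j) sums the products strictly
    greater than theta over all ligand-receptor pairs from sender i to
    receiver j.  Pairs failing theta contribute zero regardless of their
    p-value; with ``require_significant=True`` (a sensitivity analysis, not
    the headline definition) pairs must additionally have
    p_empirical <= alpha.
    """
    params = params or CrosstalkParams()
    params.validate()
    if clusters is None:
        clusters = sorted(set(scores["sender"]).union(scores["receiver"]))
    qual = scores[scores["score"] > params.theta]
    if params.require_significant:
        if "p_empirical" not in qual.columns:
            raise CrosstalkError("require_significant needs p_empirical in the scores")
        qual = qual[qual["p_empirical"] <= params.alpha]
    mat = (
        qual.pivot_table(
            index="sender", columns="receiver", values="score", aggfunc="sum", fill_value=0.0
        )
        .reindex(index=clusters, columns=clusters, fill_value=0.0)
        .astype(float)
    )
    mat.index.name = "sender"
    mat.columns.name = "receiver"
    return mat


def differential(
    profile_normal: ClusterProfile,
    profile_degenerated: ClusterProfile,
    lrdb: pd.DataFrame,
    params: CrosstalkParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-pair condition subtraction with categorical calls.

    The difference is score_degenerated - score_normal on the common
    cluster set.  A pair is called ``high_in_degenerated`` iff the
    difference is >= diff_delta and its degenerated score exceeds theta;
    symmetrically for ``high_in_normal``; otherwise ``unchanged``.  Returns
    (records, per-category call counts); clusters present in only one
    condition are dropped and reported via ``records.attrs["dropped_clusters"]``.
    """
    params = params or CrosstalkParams()
    params.validate()
    common = sorted(set(profile_normal.clusters) & set(profile_degenerated.clusters))
    dropped = sorted(
        set(profile_normal.clusters) ^ set(profile_degenerated.clusters)
    )
    if not common:
        raise CrosstalkError("the two condition profiles share no clusters")
    if profile_normal.genes != profile_degenerated.genes:
        raise CrosstalkError("condition profiles were built over different gene lists")

    pairs, lig_idx, rec_idx, n_skipped = _pair_indices(profile_normal.genes, lrdb)
    cols_n = [profile_normal.clusters.index(c) for c in common]
    cols_d = [profile_degenerated.clusters.index(c) for c in common]
    s_n = _score_tensor(profile_normal.means[:, cols_n], lig_idx, rec_idx)
    s_d = _score_tensor(profile_degenerated.means[:, cols_d], lig_idx, rec_idx)

    base = _tensor_to_frame(s_n, pairs, np.asarray(common), params.theta)
    records = base[["sender", "receiver", "ligand", "receptor", "category"]].copy()
    records["score_normal"] = s_n.reshape(-1)
    records["score_degenerated"] = s_d.reshape(-1)
    records["difference"] = records["score_degenerated"] - records["score_normal"]

    call = np.full(len(records), "unchanged", dtype=object)
    up = (records["difference"] >= params.diff_delta) & (
        records["score_degenerated"] > params.theta
    )
    down = (-records["difference"] >= params.diff_delta) & (
        records["score_normal"] > params.theta
    )
    call[up.to_numpy()] = "high_in_degenerated"
    call[down.to_numpy()] = "high_in_normal"
    records["call"] = call
    records.attrs["dropped_clusters"] = dropped
    records.attrs["n_pairs_skipped"] = n_skipped

    summary = (
        records.groupby(["category", "call"], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=list(DIFF_CALLS), fill_value=0)
    )
    summary.columns.name = None
    return records, summary
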