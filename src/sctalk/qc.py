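"""Cell-level quality control: per-cell metrics, threshold filtering, and
tiny-outlier-group flagging on precomputed cluster labels.

Filtering follows the standard droplet-QC recipe: remove cells with extreme
n_genes (observed genes per cell), n_counts (UMI per cell), percent_mito
(mitochondrial fraction of counts) or dissociation score (fraction of
counts from a dissociation-stress gene list).  Doublet scores are consumed
as externally computed metadata, never computed here.

Group flagging implements the divide-and-conquer rule: within-population
subclustering concentrates low-quality cells into tiny groups, so a cluster
is *flagged* (not removed — removal is the caller's decision) when it is
small relative to the dataset and its median doublet score, mitochondrial
fraction or dissociation score is extreme against the whole-dataset
distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import CountMatrix

#: quantile used when an upper threshold is "auto"
AUTO_UPPER_QUANTILE = 0.99
#: "auto" max_percent_mito never drops below this absolute percentage;
#: cells under 20% mito are within normal biological variation
MITO_ABSOLUTE_FLOOR = 20.0
AUTO_MIN_N_GENES = 200.0
AUTO_MIN_N_COUNTS = 500.0

METRIC_COLUMNS = ("n_counts", "n_genes", "percent_mito", "dissociation_score", "doublet_score")


class QCError(ValueError):
    """Raised when filtering would leave no usable cells."""


@dataclass
class QCThresholds:
    """Filtering thresholds; each is a number or ``"auto"``.

    ``auto`` resolves upper thresholds to the dataset's 99th percentile
    (percent_mito additionally floored at an absolute 20), and the lower
    thresholds to min_n_genes=200, min_n_counts=500.  Set a max to
    ``numpy.inf`` or a min to 0 to disable a rule.
    """

    max_n_genes: float | str = "auto"
    max_n_counts: float | str = "auto"
    max_percent_mito: float | str = "auto"
    max_dissociation: float | str = "auto"
    min_n_genes: float | str = "auto"
    min_n_counts: float | str = "auto"


@dataclass
class ResolvedThresholds:
    max_n_genes: float
    max_n_counts: float
    max_percent_mito: float
    max_dissociation: float
    min_n_genes: float
    min_n_counts: float

    def __post_init__(self) -> None:
        for lo, hi in (("min_n_genes", "max_n_genes"), ("min_n_counts", "max_n_counts")):
            if np.isfinite(getattr(self, lo)) and np.isfinite(getattr(self, hi)):
                if getattr(self, lo) > getattr(self, hi):
                    raise QCError(f"{lo} exceeds {hi}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FilterResult:
    keep: pd.Series  # boolean, indexed by cell_id
    removed_per_rule: dict[str, int]
    thresholds: ResolvedThresholds

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())

    @property
    def n_removed(self) -> int:
        return int((~self.keep).sum())


@dataclass
class FlaggedGroup:
    cluster: str
    size: int
    fraction: float
    evidence: list[str] = field(default_factory=list)
    medians: dict[str, float] = field(default_factory=dict)


def compute_cell_metrics(
    counts: CountMatrix,
    mito_genes=None,
    dissoc_genes=(),
    metadata: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-cell QC metrics.

    ``percent_mito`` and ``dissociation_score`` are percentages of the
    cell's total counts falling in the respective gene set.  ``mito_genes``
    defaults to every gene prefixed ``MT-``.  Gene-set members absent from
    the matrix are dropped with a warning.  Cells with zero counts are
    flagged invalid and get NA fraction metrics.
    """
    if mito_genes is None:
        mito_genes = [g for g in counts.genes if g.startswith("MT-")]
    mito_genes = _present(mito_genes, counts, "mitochondrial")
    dissoc_genes = _present(dissoc_genes, counts, "dissociation")

    mat = counts.matrix
    n_counts = np.asarray(mat.sum(axis=0)).ravel()
    n_genes = np.asarray((mat > 0).sum(axis=0)).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        pct_mito = 100.0 * _set_counts(counts, mito_genes) / n_counts
        pct_dissoc = 100.0 * _set_counts(counts, dissoc_genes) / n_counts
    valid = n_counts > 0
    pct_mito[~valid] = np.nan
    pct_dissoc[~valid] = np.nan

    metrics = pd.DataFrame(
        {
            "n_counts": n_counts.astype(np.int64),
            "n_genes": n_genes.astype(np.int64),
            "percent_mito": pct_mito,
            "dissociation_score": pct_dissoc,
            "doublet_score": np.nan,
            "valid": valid,
        },
        index=pd.Index(counts.cells, name="cell_id"),
    )
    if metadata is not None and "doublet_score" in metadata.columns:
        ds = metadata.set_index("cell_id")["doublet_score"]
        metrics["doublet_score"] = ds.reindex(metrics.index).to_numpy()
    return metrics


def _present(genes, counts: CountMatrix, label: str) -> list[str]:
    genes = list(genes)
    have = set(counts.genes)
    missing = [g for g in genes if g not in have]
    if missing:
        warnings.warn(
            f"{len(missing)} {label} gene(s) absent from matrix (e.g. {missing[:3]}); dropped",
            stacklevel=3,
        )
    return [g for g in genes if g in have]


def _set_counts(counts: CountMatrix, genes) -> np.ndarray:
    if not genes:
        return np.zeros(counts.n_cells)
    idx = counts.gene_index(genes)
    return np.asarray(counts.matrix[idx, :].sum(axis=0)).ravel().astype(float)


def resolve_thresholds(metrics: pd.DataFrame, thresholds: QCThresholds) -> ResolvedThresholds:
    """Turn ``"auto"`` entries into numbers using the metric distributions."""

    def upper(name: str, column: str, floor: float | None = None) -> float:
        v = getattr(thresholds, name)
        if v != "auto":
            return float(v)
        vals = metrics.loc[metrics["valid"], column].dropna()
        q = float(vals.quantile(AUTO_UPPER_QUANTILE)) if len(vals) else np.inf
        return max(q, floor) if floor is not None else q

    def lower(name: str, default: float) -> float:
        v = getattr(thresholds, name)
        return default if v == "auto" else float(v)

    return ResolvedThresholds(
        max_n_genes=upper("max_n_genes", "n_genes"),
        max_n_counts=upper("max_n_counts", "n_counts"),
        max_percent_mito=upper("max_percent_mito", "percent_mito", floor=MITO_ABSOLUTE_FLOOR),
        max_dissociation=upper("max_dissociation", "dissociation_score"),
        min_n_genes=lower("min_n_genes", AUTO_MIN_N_GENES),
        min_n_counts=lower("min_n_counts", AUTO_MIN_N_COUNTS),
    )


_RULES = (
    ("max_n_genes", "n_genes", "gt"),
    ("max_n_counts", "n_counts", "gt"),
    ("max_percent_mito", "percent_mito", "gt"),
    ("max_dissociation", "dissociation_score", "gt"),
    ("min_n_genes", "n_genes", "lt"),
    ("min_n_counts", "n_counts", "lt"),
)


def filter_cells(
    metrics: pd.DataFrame, thresholds: QCThresholds | ResolvedThresholds | None = None
) -> FilterResult:
    """Keep-mask over cells plus per-rule removal counts.

    A cell is kept iff it violates no rule; a cell failing k rules is
    counted under each of them.  NA metrics never trigger an upper rule
    (they cannot be assessed) but zero-count cells naturally fail the
    min_n_counts rule when it is active.  Raises :class:`QCError` when
    nothing would survive.
    """
    if thresholds is None:
        thresholds = QCThresholds()
    if isinstance(thresholds, QCThresholds):
        resolved = resolve_thresholds(metrics, thresholds)
    else:
        resolved = thresholds

    removed_per_rule: dict[str, int] = {}
    violation = np.zeros(len(metrics), dtype=bool)
    for rule, column, side in _RULES:
        limit = getattr(resolved, rule)
        vals = metrics[column].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = np.greater(vals, limit) if side == "gt" else np.less(vals, limit)
        bad &= ~np.isnan(vals) if side == "gt" else True  # NaN > x is already False
        removed_per_rule[rule] = int(bad.sum())
        violation |= bad
    keep = pd.Series(~violation, index=metrics.index, name="keep")
    if not keep.any():
        raise QCError(
            "filtering removed every cell; review thresholds "
            f"(resolved: {resolved.to_dict()})"
        )
    return FilterResult(keep=keep, removed_per_rule=removed_per_rule, thresholds=resolved)


def flag_outlier_groups(
    metrics: pd.DataFrame,
    cluster_labels,
    max_group_fraction: float = 0.02,
    score_quantile: float = 0.95,
) -> list[FlaggedGroup]:
    """Flag tiny clusters dominated by low-quality cells.

    A cluster is flagged iff its size fraction is <= ``max_group_fraction``
    AND the cluster median of at least one of doublet_score, percent_mito or
    dissociation_score exceeds the ``score_quantile`` quantile of that
    metric over all cells.  Returns the flagged clusters with the metrics
    that triggered; flagged does not mean removed.
    """
    labels = pd.Series(np.asarray(cluster_labels), index=metrics.index, name="cluster")
    if labels.isna().any():
        raise ValueError("every cell must carry a cluster label")
    total = len(metrics)
    criteria = ["doublet_score", "percent_mito", "dissociation_score"]
    if metrics["doublet_score"].isna().all():
        warnings.warn("doublet scores unavailable; doublet criterion skipped", stacklevel=2)
        criteria.remove("doublet_score")
    cutoffs = {c: float(metrics[c].quantile(score_quantile)) for c in criteria}

    flagged = []
    for cl, grp in metrics.groupby(labels, sort=True):
        frac = len(grp) / total
        if frac > max_group_fraction:
            continue
        evidence = []
        medians = {}
        for c in criteria:
            med = float(grp[c].median())
            medians[c] = med
            if np.isfinite(med) and med > cutoffs[c]:
                evidence.append(c)
        if evidence:
            flagged.append(
                FlaggedGroup(
                    cluster=str(cl), size=len(grp), fraction=frac,
                    evidence=evidence, medians=medians,
                )
            )
    return flagged


def qc_report(
    result: FilterResult, flagged: list[FlaggedGroup] | None = None
) -> dict:
    """JSON-serializable summary of one QC pass."""
    return {
        "n_cells": int(len(result.keep)),
        "n_kept": result.n_kept,
        "n_removed": result.n_removed,
        "removed_per_rule": result.removed_per_rule,
        "thresholds": result.thresholds.to_dict(),
        "flagged_groups": [asdict(f) for f in (flagged or [])],
    }
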