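"""Synthetic single-cell count data with planted ground truth.

The generator emulates the statistical structure the crosstalk analysis
assumes: several clusters with marker genes, two condition groups
(normal / degenerated) with per-sample replicates, negative-binomial counts
with log-normal library-size heterogeneity, ligand genes elevated in sender
clusters and receptor genes elevated in receiver clusters with a
controllable fold change, and optional planted low-quality cells (high
mitochondrial fraction, high dissociation-stress fraction, high doublet
score).  Everything is deterministic given the spec, including its seed.

The defaults are calibrated so that on the CP10K log1p scale the background
cluster-mean expression of a ligand/receptor gene sits near 1.0 (products
around 1.0, below the crosstalk threshold theta = 1.5) while a fold-4
planted pair yields products around 5-6 — i.e. the regime in which a fixed
theta separates signal from background, and in which per-cell depth
(median ~1200 at the defaults) stays well above standard QC floors.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import (
    CountMatrix,
    LR_CATEGORIES,
    validate_metadata,
    write_matrix,
    write_metadata,
    write_lr_database,
    write_gene_list,
)

BAD_CELL_KINDS = ("high_mito", "high_dissoc", "high_doublet")
CONDITION_SPECIFIC = ("both", "normal_only", "degenerated_only")


class SimSpecError(ValueError):
    """The simulation spec is internally inconsistent."""


@dataclass(frozen=True)
class PlantedInteraction:
    """A ligand-receptor pair planted between a sender and a receiver cluster.

    ``fold`` multiplies the ligand's NB mean in the sender cluster and the
    receptor's NB mean in the receiver cluster; ``fold = 1`` encodes a null
    (unplanted) pair usable as a negative control.  ``condition_specific``
    restricts the elevation to one condition group.
    """

    ligand: str
    receptor: str
    sender: str
    receiver: str
    fold: float = 4.0
    condition_specific: str = "both"

    def active_in(self, condition: str) -> bool:
        if self.condition_specific == "both":
            return True
        return self.condition_specific == f"{condition}_only"


@dataclass
class SimSpec:
    """Parameters of one simulated dataset.

    ``n_cells_per_cluster`` applies per condition (an int, or a mapping
    cluster -> int); ``composition_shift`` optionally scales a cluster's
    cell count in the degenerated condition, creating per-condition
    composition differences.
    """

    n_genes: int = 2000
    clusters: Sequence[str] = ("c0", "c1", "c2", "c3", "c4")
    n_cells_per_cluster: int | Mapping[str, int] = 200
    n_samples_per_condition: int = 3
    conditions: Sequence[str] = ("normal", "degenerated")
    zones: Sequence[str] = ("inner", "outer")
    n_markers_per_cluster: int = 10
    n_ligands: int = 200
    n_receptors: int = 200
    n_mito: int = 10
    n_dissoc: int = 10
    baseline_mean: float = 0.6
    nb_dispersion: float = 2.0
    libsize_sigma: float = 0.3
    marker_fold: float = 3.0
    planted_interactions: Sequence[PlantedInteraction] = ()
    planted_bad_cells: Mapping[str, int] = field(default_factory=dict)
    composition_shift: Mapping[str, float] = field(default_factory=dict)
    mito_fraction_bad: float = 0.5
    dissoc_fraction_bad: float = 0.4
    doublet_score_bad: float = 0.9
    doublet_score_background_max: float = 0.3
    isolate_bad_clusters: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not isinstance(self.seed, (int, np.integer)) or isinstance(self.seed, bool):
            raise SimSpecError(f"seed must be an integer, got {self.seed!r}")
        if self.n_genes <= 0:
            raise SimSpecError("n_genes must be positive")
        if len(set(self.clusters)) != len(self.clusters):
            raise SimSpecError("cluster ids must be unique")
        if tuple(sorted(self.conditions)) != ("degenerated", "normal"):
            raise SimSpecError("conditions must be exactly {normal, degenerated}")
        if not self.zones or not set(self.zones) <= {"inner", "outer"}:
            raise SimSpecError("zones must be a non-empty subset of {inner, outer}")
        if self.n_samples_per_condition < 1:
            raise SimSpecError("n_samples_per_condition must be positive")
        for name in ("baseline_mean", "nb_dispersion"):
            if getattr(self, name) <= 0:
                raise SimSpecError(f"{name} must be strictly positive")
        if self.libsize_sigma < 0:
            raise SimSpecError("libsize_sigma must be non-negative")
        if self.marker_fold < 1:
            raise SimSpecError("marker_fold must be >= 1")
        for cl in self.clusters:
            if self.cells_in(cl, "normal") <= 0 or self.cells_in(cl, "degenerated") <= 0:
                raise SimSpecError(f"cluster {cl!r} would be empty")
        for kind in self.planted_bad_cells:
            if kind not in BAD_CELL_KINDS:
                raise SimSpecError(f"unknown planted_bad_cells kind {kind!r}")
        for pi in self.planted_interactions:
            if pi.fold < 1:
                raise SimSpecError(f"planted fold must be >= 1, got {pi.fold}")
            if pi.condition_specific not in CONDITION_SPECIFIC:
                raise SimSpecError(f"bad condition_specific {pi.condition_specific!r}")
            for cl in (pi.sender, pi.receiver):
                if cl not in self.clusters:
                    raise SimSpecError(f"planted interaction references unknown cluster {cl!r}")

    def cells_in(self, cluster: str, condition: str) -> int:
        if isinstance(self.n_cells_per_cluster, Mapping):
            base = int(self.n_cells_per_cluster[cluster])
        else:
            base = int(self.n_cells_per_cluster)
        if condition == "degenerated":
            base = int(round(base * float(self.composition_shift.get(cluster, 1.0))))
        return base


@dataclass
class GeneCatalog:
    """Disjoint partition of the gene universe into functional roles."""

    background: list[str]
    markers: dict[str, list[str]]  # cluster -> marker genes
    ligands: list[str]
    receptors: list[str]
    mito: list[str]
    dissoc: list[str]

    @property
    def all_genes(self) -> list[str]:
        out: list[str] = []
        for cl in self.markers:
            out.extend(self.markers[cl])
        out.extend(self.ligands)
        out.extend(self.receptors)
        out.extend(self.mito)
        out.extend(self.dissoc)
        out.extend(self.background)
        return out

    def to_dict(self) -> dict:
        return {
            "background": self.background,
            "markers": self.markers,
            "ligands": self.ligands,
            "receptors": self.receptors,
            "mito": self.mito,
            "dissoc": self.dissoc,
        }


@dataclass
class GroundTruth:
    """What was planted: interactions, bad cells, and true cluster labels."""

    planted_interactions: list[PlantedInteraction]
    bad_cells: dict[str, list[str]]  # kind -> cell ids
    true_cluster_of_cell: dict[str, str]

    @property
    def bad_cell_ids(self) -> list[str]:
        out: list[str] = []
        for kind in BAD_CELL_KINDS:
            out.extend(self.bad_cells.get(kind, []))
        return out

    def to_json(self, path) -> None:
        payload = {
            "planted_interactions": [asdict(pi) for pi in self.planted_interactions],
            "bad_cells": self.bad_cells,
            "true_cluster_of_cell": self.true_cluster_of_cell,
        }
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            planted_interactions=[
                PlantedInteraction(**d) for d in payload["planted_interactions"]
            ],
            bad_cells=payload["bad_cells"],
            true_cluster_of_cell=payload["true_cluster_of_cell"],
        )


# ---------------------------------------------------------------------------
# catalog
# ---------------------------------------------------------------------------


def build_gene_catalog(spec: SimSpec) -> GeneCatalog:
    """Partition ``spec.n_genes`` gene ids into roles.

    Mitochondrial genes are prefixed ``MT-`` so prefix-based QC works on the
    emitted matrix.  Raises a sizing error naming the deficit when the
    requested roles do not fit into ``n_genes``.
    """
    spec.validate()
    n_special = (
        len(spec.clusters) * spec.n_markers_per_cluster
        + spec.n_ligands
        + spec.n_receptors
        + spec.n_mito
        + spec.n_dissoc
    )
    if n_special > spec.n_genes:
        raise SimSpecError(
            f"n_genes={spec.n_genes} cannot host {n_special} role genes "
            f"({len(spec.clusters)}x{spec.n_markers_per_cluster} markers, "
            f"{spec.n_ligands} ligands, {spec.n_receptors} receptors, "
            f"{spec.n_mito} mito, {spec.n_dissoc} dissociation); "
            f"short by {n_special - spec.n_genes}"
        )
    markers = {
        cl: [f"MK-{cl}-{t + 1}" for t in range(spec.n_markers_per_cluster)]
        for cl in spec.clusters
    }
    return GeneCatalog(
        markers=markers,
        ligands=[f"LIG{t + 1:03d}" for t in range(spec.n_ligands)],
        receptors=[f"REC{t + 1:03d}" for t in range(spec.n_receptors)],
        mito=[f"MT-{t + 1}" for t in range(spec.n_mito)],
        dissoc=[f"STRESS{t + 1}" for t in range(spec.n_dissoc)],
        background=[f"BG{t + 1:04d}" for t in range(spec.n_genes - n_special)],
    )


def make_lr_database(
    catalog: GeneCatalog, n_pairs: int | None = None, pairing: str = "one_to_one"
) -> pd.DataFrame:
    """Ligand-receptor database over the catalog's ligand/receptor genes.

    ``one_to_one`` pairs ligand k with receptor k (disjoint genes per pair,
    so a planted pair perturbs no other database pair); ``cross`` walks the
    full ligand x receptor product.  Categories cycle deterministically
    through the supported category labels.
    """
    if pairing == "one_to_one":
        k = min(len(catalog.ligands), len(catalog.receptors))
        pairs = list(zip(catalog.ligands[:k], catalog.receptors[:k]))
    elif pairing == "cross":
        pairs = [(l, r) for l in catalog.ligands for r in catalog.receptors]
    else:
        raise ValueError(f"unknown pairing {pairing!r}")
    if n_pairs is not None:
        if n_pairs > len(pairs):
            raise SimSpecError(f"requested {n_pairs} pairs but only {len(pairs)} available")
        pairs = pairs[:n_pairs]
    return pd.DataFrame(
        {
            "ligand_gene": [p[0] for p in pairs],
            "receptor_gene": [p[1] for p in pairs],
            "category": [LR_CATEGORIES[i % len(LR_CATEGORIES)] for i in range(len(pairs))],
        }
    )


def default_planted_interactions(
    catalog: GeneCatalog,
    clusters: Sequence[str],
    n: int,
    fold: float = 4.0,
    condition_specific: str = "both",
    start: int = 0,
) -> list[PlantedInteraction]:
    """Deterministic planted set: pair t uses ligand/receptor ``start + t`` and
    walks sender->receiver over distinct ordered cluster pairs."""
    k = len(clusters)
    cluster_pairs = [(a, b) for a in clusters for b in clusters if a != b]
    out = []
    for t in range(n):
        i = start + t
        if i >= min(len(catalog.ligands), len(catalog.receptors)):
            raise SimSpecError("not enough ligand/receptor genes for planted interactions")
        sender, receiver = cluster_pairs[t % len(cluster_pairs)]
        out.append(
            PlantedInteraction(
                ligand=catalog.ligands[i],
                receptor=catalog.receptors[i],
                sender=sender,
                receiver=receiver,
                fold=fold,
                condition_specific=condition_specific,
            )
        )
    return out


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def _build_cell_table(spec: SimSpec) -> pd.DataFrame:
    rows = []
    idx = 0
    for cond in spec.conditions:
        samples = [f"{cond[:5]}_s{k + 1}" for k in range(spec.n_samples_per_condition)]
        zone_of = {s: spec.zones[k % len(spec.zones)] for k, s in enumerate(samples)}
        for cl in spec.clusters:
            n = spec.cells_in(cl, cond)
            for t in range(n):
                s = samples[t % len(samples)]
                rows.append((f"cell{idx:06d}", s, cond, zone_of[s], cl))
                idx += 1
    return pd.DataFrame(rows, columns=["cell_id", "sample", "condition", "zone", "cluster"])


def simulate_counts(
    spec: SimSpec, catalog: GeneCatalog | None = None
) -> tuple[CountMatrix, pd.DataFrame, GroundTruth]:
    """Draw a counts matrix, metadata and ground truth from the spec.

    Counts are NB(mean = baseline_mean x role fold x per-cell depth
    multiplier, dispersion = nb_dispersion).  Marker genes are elevated by
    ``marker_fold`` in their cluster; planted ligands/receptors by their
    interaction fold in the sender/receiver cluster (restricted to the
    stated condition when condition-specific).  Planted low-quality cells
    have their mean vector re-partitioned so the mitochondrial (or
    dissociation) share of the cell's expected depth reaches the configured
    fraction, leaving total depth unchanged; planted doublets receive a high
    doublet score directly in the metadata.
    """
    spec.validate()
    if catalog is None:
        catalog = build_gene_catalog(spec)
    genes = catalog.all_genes
    gpos = {g: i for i, g in enumerate(genes)}
    for pi in spec.planted_interactions:
        for g in (pi.ligand, pi.receptor):
            if g not in gpos:
                raise SimSpecError(f"planted interaction references unknown gene {g!r}")

    meta = _build_cell_table(spec)
    n_cells = len(meta)
    n_genes = len(genes)
    rng = np.random.default_rng(spec.seed)

    # per-(cluster, condition) NB mean vectors
    mu: dict[tuple[str, str], np.ndarray] = {}
    for cond in spec.conditions:
        for cl in spec.clusters:
            v = np.full(n_genes, spec.baseline_mean)
            for g in catalog.markers[cl]:
                v[gpos[g]] *= spec.marker_fold
            for pi in spec.planted_interactions:
                if not pi.active_in(cond):
                    continue
                if pi.sender == cl:
                    v[gpos[pi.ligand]] *= pi.fold
                if pi.receiver == cl:
                    v[gpos[pi.receptor]] *= pi.fold
            mu[(cl, cond)] = v

    M = np.empty((n_genes, n_cells))
    for key, grp in meta.groupby(["cluster", "condition"], sort=False):
        M[:, grp.index.to_numpy()] = mu[key][:, None]

    # planted bad cells: re-partition mean mass, preserving total depth
    counts_by_kind = {k: int(spec.planted_bad_cells.get(k, 0)) for k in BAD_CELL_KINDS}
    total_bad = sum(counts_by_kind.values())
    if total_bad > n_cells:
        raise SimSpecError("more planted bad cells than cells")
    bad_idx = rng.choice(n_cells, size=total_bad, replace=False) if total_bad else np.array([], int)
    offsets = np.cumsum([0] + [counts_by_kind[k] for k in BAD_CELL_KINDS])
    kind_idx = {
        k: bad_idx[offsets[t]:offsets[t + 1]] for t, k in enumerate(BAD_CELL_KINDS)
    }
    for kind, rows_genes, frac in (
        ("high_mito", catalog.mito, spec.mito_fraction_bad),
        ("high_dissoc", catalog.dissoc, spec.dissoc_fraction_bad),
    ):
        gi = np.array([gpos[g] for g in rows_genes], dtype=int)
        for c in kind_idx[kind]:
            total = M[:, c].sum()
            rest = np.setdiff1d(np.arange(n_genes), gi)
            M[gi, c] = frac * total / len(gi)
            M[rest, c] *= (1 - frac) * total / M[rest, c].sum()

    depth = (
        rng.lognormal(mean=-spec.libsize_sigma**2 / 2, sigma=spec.libsize_sigma, size=n_cells)
        if spec.libsize_sigma > 0
        else np.ones(n_cells)
    )
    M *= depth[None, :]

    r = spec.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + M)).astype(np.int64)

    scores = rng.uniform(0.0, spec.doublet_score_background_max, size=n_cells)
    scores[kind_idx["high_doublet"]] = spec.doublet_score_bad
    meta["doublet_score"] = scores

    truth = GroundTruth(
        planted_interactions=list(spec.planted_interactions),
        bad_cells={
            k: meta.loc[kind_idx[k], "cell_id"].tolist() for k in BAD_CELL_KINDS
        },
        true_cluster_of_cell=dict(zip(meta["cell_id"], meta["cluster"])),
    )
    if spec.isolate_bad_clusters:
        # emulate the "centrifuge" effect of within-population subclustering:
        # low-quality cells surface as their own tiny labeled groups
        for kind in BAD_CELL_KINDS:
            meta.loc[kind_idx[kind], "cluster"] = f"outlier_{kind.removeprefix('high_')}"

    cm = CountMatrix(genes=genes, cells=meta["cell_id"].tolist(), matrix=sp.csr_matrix(counts))
    meta = validate_metadata(meta, cm)
    return cm, meta, truth


@dataclass
class SimulatedDataset:
    counts: CountMatrix
    metadata: pd.DataFrame
    lr_database: pd.DataFrame
    truth: GroundTruth
    catalog: GeneCatalog


def simulate_dataset(spec: SimSpec, n_pairs: int | None = None) -> SimulatedDataset:
    """Catalog + counts + metadata + LR database + ground truth in one call."""
    catalog = build_gene_catalog(spec)
    counts, meta, truth = simulate_counts(spec, catalog)
    lrdb = make_lr_database(catalog, n_pairs=n_pairs)
    return SimulatedDataset(counts, meta, lrdb, truth, catalog)


def write_dataset(ds: SimulatedDataset, outdir) -> dict[str, str]:
    """Write the CellRanger-style triplet plus side tables; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix(ds.counts, outdir / "matrix")
    write_metadata(ds.metadata, outdir / "metadata.tsv")
    write_lr_database(ds.lr_database, outdir / "lr_database.tsv")
    ds.truth.to_json(outdir / "ground_truth.json")
    write_gene_list(ds.catalog.dissoc, outdir / "dissociation_genes.txt")
    (outdir / "catalog.json").write_text(json.dumps(ds.catalog.to_dict(), sort_keys=True, indent=1))
    return {
        "matrix": str(outdir / "matrix"),
        "metadata": str(outdir / "metadata.tsv"),
        "lr_database": str(outdir / "lr_database.tsv"),
        "ground_truth": str(outdir / "ground_truth.json"),
        "dissociation_genes": str(outdir / "dissociation_genes.txt"),
        "catalog": str(outdir / "catalog.json"),
    }
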