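"""Shared fixtures: session-scoped synthetic datasets reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

from sctalk import (
    NormMatrix,
    SimSpec,
    build_gene_catalog,
    default_planted_interactions,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def planted_ds():
    """Default study conditions with 20 fold-4 planted interactions
    (both conditions) among the 200 database pairs."""
    spec = SimSpec(seed=101)
    catalog = build_gene_catalog(spec)
    spec.planted_interactions = default_planted_interactions(
        catalog, spec.clusters, n=20, fold=4.0
    )
    return simulate_dataset(spec)


@pytest.fixture(scope="session")
def null_ds():
    """Default study conditions with nothing planted (exchangeable LR genes)."""
    return simulate_dataset(SimSpec(seed=202))


@pytest.fixture(scope="session")
def diff_ds():
    """Condition-specific planted interactions: 10 degenerated-only and
    10 normal-only, fold 4, among 200 database pairs."""
    spec = SimSpec(seed=404)
    catalog = build_gene_catalog(spec)
    spec.planted_interactions = default_planted_interactions(
        catalog, spec.clusters, 10, 4.0, "degenerated_only", start=0
    ) + default_planted_interactions(
        catalog, spec.clusters, 10, 4.0, "normal_only", start=10
    )
    return simulate_dataset(spec)


@pytest.fixture(scope="session")
def qc_ds():
    """1000 cells with 5 high-mito, 5 high-dissociation and 5 high-doublet
    planted bad cells surfacing as tiny outlier clusters."""
    spec = SimSpec(
        n_cells_per_cluster=100,
        planted_bad_cells={"high_mito": 5, "high_dissoc": 5, "high_doublet": 5},
        isolate_bad_clusters=True,
        seed=303,
    )
    return simulate_dataset(spec)


def subset_condition(norm: NormMatrix, metadata, condition: str):
    """Restrict a normalized matrix + metadata to one condition stratum."""
    meta = metadata[metadata["condition"] == condition].reset_index(drop=True)
    cells = set(meta["cell_id"])
    mask = np.array([c in cells for c in norm.cells])
    sub = NormMatrix(
        genes=norm.genes,
        cells=[c for c, m in zip(norm.cells, mask) if m],
        matrix=norm.matrix[:, mask],
        provenance=norm.provenance,
    )
    return sub, meta
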