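"""Readers, writers and validation for the on-disk formats shared by all stages.

Count matrices travel either as a CellRanger-style Matrix-Market triplet
directory (``matrix.mtx`` + ``genes.tsv`` + ``barcodes.tsv``, genes as rows,
1-based coordinate indices) or as a dense CSV (genes as rows, cells as
columns).  Cell metadata and the ligand-receptor database are tab-separated
tables with a header row.  Readers validate; downstream modules assume
validated objects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

CONDITIONS = ("normal", "degenerated")
ZONES = ("inner", "outer", "NA")
LR_CATEGORIES = (
    "ECM",
    "TNF",
    "TGFB",
    "chemokine",
    "cytokine",
    "antigen_presentation",
    "other",
)

#: required columns of a metadata table
METADATA_REQUIRED = ("cell_id", "sample", "condition", "cluster")
METADATA_COLUMNS = ("cell_id", "sample", "condition", "zone", "cluster", "doublet_score")


class MatrixFormatError(ValueError):
    """A count-matrix file does not parse under the requested dialect."""


class SchemaError(ValueError):
    """A tabular input is missing required columns or contains invalid values."""


# ---------------------------------------------------------------------------
# count matrix
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Genes x cells matrix of non-negative integer counts.

    ``matrix`` is stored as CSR with genes as rows, matching the on-disk
    CellRanger orientation.  Gene and cell identifiers are unique strings;
    genes are matched downstream by exact symbol (case-sensitive).
    """

    genes: list[str]
    cells: list[str]
    matrix: sp.csr_matrix = field(repr=False)

    def __post_init__(self) -> None:
        self.genes = [str(g) for g in self.genes]
        self.cells = [str(c) for c in self.cells]
        if len(set(self.genes)) != len(self.genes):
            raise SchemaError("gene ids are not unique")
        if len(set(self.cells)) != len(self.cells):
            raise SchemaError("cell ids are not unique")
        if not sp.issparse(self.matrix):
            self.matrix = sp.csr_matrix(np.asarray(self.matrix))
        self.matrix = self.matrix.tocsr()
        if self.matrix.shape != (len(self.genes), len(self.cells)):
            raise MatrixFormatError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        data = self.matrix.data
        if data.size:
            if not np.all(np.isfinite(data)):
                raise SchemaError("matrix contains non-finite entries")
            if np.any(data < 0):
                raise SchemaError("matrix contains negative entries")
            if not np.all(np.equal(np.mod(data, 1), 0)):
                raise SchemaError("matrix contains non-integer entries")
        self.matrix = self.matrix.astype(np.int64)
        self.matrix.eliminate_zeros()

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def gene_index(self, genes) -> np.ndarray:
        """Row indices of ``genes``; raises KeyError on a missing symbol."""
        lookup = {g: i for i, g in enumerate(self.genes)}
        try:
            return np.array([lookup[g] for g in genes], dtype=int)
        except KeyError as exc:
            raise KeyError(f"gene {exc.args[0]!r} not present in matrix") from None

    def to_dense(self) -> np.ndarray:
        return self.matrix.toarray()

    def subset_cells(self, keep) -> "CountMatrix":
        """New matrix restricted to ``keep`` (boolean mask or list of cell ids)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {c: i for i, c in enumerate(self.cells)}
            idx = np.array([pos[c] for c in keep], dtype=int)
        return CountMatrix(
            genes=list(self.genes),
            cells=[self.cells[i] for i in idx],
            matrix=self.matrix[:, idx],
        )


def read_matrix(path, dialect: str = "mtx_triplet") -> CountMatrix:
    """Read a count matrix.

    ``mtx_triplet`` expects a directory containing ``matrix.mtx``,
    ``genes.tsv`` and ``barcodes.tsv``; ``dense_csv`` expects a single CSV
    file with gene ids in the first column and cell ids as the header.
    """
    path = Path(path)
    if dialect == "mtx_triplet":
        return _read_mtx_triplet(path)
    if dialect == "dense_csv":
        return _read_dense_csv(path)
    raise ValueError(f"unknown matrix dialect {dialect!r}")


def _read_mtx_triplet(path: Path) -> CountMatrix:
    for name in ("matrix.mtx", "genes.tsv", "barcodes.tsv"):
        if not (path / name).exists():
            raise MatrixFormatError(f"missing {name} in {path}")
    try:
        mat = mmread(str(path / "matrix.mtx"))
    except Exception as exc:  # scipy raises bare ValueError on bad headers
        raise MatrixFormatError(f"cannot parse {path / 'matrix.mtx'}: {exc}") from exc
    genes_df = pd.read_csv(path / "genes.tsv", sep="\t", header=None, dtype=str)
    genes = genes_df.iloc[:, 0].tolist()
    barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None, dtype=str)
    cells = barcodes.iloc[:, 0].tolist()
    if mat.shape[0] != len(genes):
        raise MatrixFormatError(
            f"matrix.mtx declares {mat.shape[0]} genes but genes.tsv has {len(genes)}"
        )
    if mat.shape[1] != len(cells):
        raise MatrixFormatError(
            f"matrix.mtx declares {mat.shape[1]} cells but barcodes.tsv has {len(cells)}"
        )
    return CountMatrix(genes=genes, cells=cells, matrix=sp.csr_matrix(mat))


def _read_dense_csv(path: Path) -> CountMatrix:
    if not path.exists():
        raise MatrixFormatError(f"no such file: {path}")
    df = pd.read_csv(path, index_col=0)
    return CountMatrix(
        genes=[str(g) for g in df.index],
        cells=[str(c) for c in df.columns],
        matrix=sp.csr_matrix(df.to_numpy()),
    )


def write_matrix(cm: CountMatrix, path, dialect: str = "mtx_triplet") -> None:
    path = Path(path)
    if dialect == "mtx_triplet":
        path.mkdir(parents=True, exist_ok=True)
        mmwrite(str(path / "matrix.mtx"), cm.matrix.tocoo(), field="integer")
        pd.DataFrame({"id": cm.genes, "symbol": cm.genes}).to_csv(
            path / "genes.tsv", sep="\t", header=False, index=False
        )
        pd.Series(cm.cells).to_csv(path / "barcodes.tsv", sep="\t", header=False, index=False)
    elif dialect == "dense_csv":
        path.parent.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(cm.to_dense(), index=cm.genes, columns=cm.cells).to_csv(path)
    else:
        raise ValueError(f"unknown matrix dialect {dialect!r}")


# ---------------------------------------------------------------------------
# cell metadata
# ---------------------------------------------------------------------------


def validate_metadata(meta: pd.DataFrame, counts: CountMatrix | None = None) -> pd.DataFrame:
    """Check the metadata schema; returns the normalized table.

    Ensures required columns, unique cell ids, legal condition/zone values;
    when ``counts`` is given, requires that metadata covers exactly its cells.
    """
    missing = [c for c in METADATA_REQUIRED if c not in meta.columns]
    if missing:
        raise SchemaError(f"metadata is missing required column(s): {missing}")
    meta = meta.copy()
    meta["cell_id"] = meta["cell_id"].astype(str)
    if meta["cell_id"].duplicated().any():
        dup = meta.loc[meta["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise SchemaError(f"duplicate cell_id in metadata: {dup!r}")
    bad_cond = set(meta["condition"].unique()) - set(CONDITIONS)
    if bad_cond:
        raise SchemaError(f"unknown condition value(s) {sorted(bad_cond)}; expected {CONDITIONS}")
    if "zone" not in meta.columns:
        meta["zone"] = "NA"
    meta["zone"] = meta["zone"].fillna("NA")
    bad_zone = set(meta["zone"].unique()) - set(ZONES)
    if bad_zone:
        raise SchemaError(f"unknown zone value(s) {sorted(bad_zone)}; expected {ZONES}")
    if "doublet_score" not in meta.columns:
        meta["doublet_score"] = np.nan
    meta["doublet_score"] = pd.to_numeric(meta["doublet_score"], errors="coerce")
    in_range = meta["doublet_score"].dropna().between(0, 1).all()
    if not in_range:
        raise SchemaError("doublet_score values must lie in [0, 1]")
    if counts is not None:
        meta_cells = set(meta["cell_id"])
        mat_cells = set(counts.cells)
        if meta_cells != mat_cells:
            only_meta = sorted(meta_cells - mat_cells)[:3]
            only_mat = sorted(mat_cells - meta_cells)[:3]
            raise SchemaError(
                "metadata and matrix cells differ "
                f"(e.g. metadata-only {only_meta}, matrix-only {only_mat})"
            )
    return meta[list(METADATA_COLUMNS)]


def read_metadata(path, counts: CountMatrix | None = None) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"cell_id": str}, na_values=["NA"], keep_default_na=True)
    return validate_metadata(meta, counts)


def write_metadata(meta: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    meta.to_csv(path, sep="\t", index=False, na_rep="NA")


def align_metadata(meta: pd.DataFrame, counts: CountMatrix) -> pd.DataFrame:
    """Metadata reordered to the matrix's cell order (validates coverage)."""
    meta = validate_metadata(meta, counts)
    return meta.set_index("cell_id").loc[counts.cells].reset_index()


# ---------------------------------------------------------------------------
# ligand-receptor database
# ---------------------------------------------------------------------------


def read_lr_database(path) -> pd.DataFrame:
    """Read a ligand-receptor pair table.

    Requires ``ligand_gene`` and ``receptor_gene`` columns; ``category``
    defaults to ``"other"`` when absent.  Duplicate (ligand, receptor) pairs
    are dropped, keeping the first occurrence.  An empty file yields an
    empty database with a warning rather than an error.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        warnings.warn(f"ligand-receptor database {path} is empty", stacklevel=2)
        return pd.DataFrame(columns=["ligand_gene", "receptor_gene", "category"])
    return validate_lr_database(df)


def validate_lr_database(df: pd.DataFrame) -> pd.DataFrame:
    for col in ("ligand_gene", "receptor_gene"):
        if col not in df.columns:
            raise SchemaError(f"ligand-receptor database is missing column {col!r}")
    df = df.copy()
    if "category" not in df.columns:
        df["category"] = "other"
    df["category"] = df["category"].fillna("other")
    df = df[["ligand_gene", "receptor_gene", "category"]].astype(str)
    if df.empty:
        warnings.warn("ligand-receptor database has no rows", stacklevel=2)
        return df
    if (df["ligand_gene"].str.len() == 0).any() or (df["receptor_gene"].str.len() == 0).any():
        raise SchemaError("ligand-receptor database contains empty gene ids")
    df = df.drop_duplicates(subset=["ligand_gene", "receptor_gene"], keep="first")
    return df.reset_index(drop=True)


def write_lr_database(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_gene_list(path) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_gene_list(genes, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("\n".join(genes) + "\n")
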