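"""On-disk formats: count matrices (MTX/CSV), GMT gene sets, cell metadata, result tables.

Count matrices are genes x cells throughout, following the 10x Genomics
convention for Matrix Market triplets with sibling ``genes.tsv`` /
``barcodes.tsv`` files. Gene-identifier matching against gene sets is exact
and case-sensitive; any homolog mapping must happen upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    """Input violates a data-contract invariant (actionable user error)."""


class ParseError(ValueError):
    """Input file is malformed at a specific location."""


@dataclass
class CountMatrix:
    """Raw integer counts, genes x cells.

    ``counts`` is kept as a CSR sparse matrix; construction validates
    non-negativity, integrality and identifier uniqueness.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix rows"
            )
        if len(self.cell_ids) != n_cells:
            raise ValidationError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix columns"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        data = self.counts.data
        if data.size:
            if np.any(data < 0):
                i, j = self._locate(lambda d: d < 0)
                raise ValidationError(
                    f"negative count at gene {self.gene_ids[i]!r}, cell {self.cell_ids[j]!r}"
                )
            if not np.allclose(data, np.round(data)):
                i, j = self._locate(lambda d: ~np.isclose(d, np.round(d)))
                raise ValidationError(
                    f"non-integer count at gene {self.gene_ids[i]!r}, cell {self.cell_ids[j]!r}"
                )
        self.counts = self.counts.astype(np.int64)

    def _locate(self, bad) -> tuple[int, int]:
        coo = self.counts.tocoo()
        k = int(np.flatnonzero(bad(coo.data))[0])
        return int(coo.row[k]), int(coo.col[k])

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())

    def select_genes(self, rows: Sequence[int]) -> "CountMatrix":
        rows = list(rows)
        return CountMatrix(
            [self.gene_ids[i] for i in rows], list(self.cell_ids), self.counts[rows, :]
        )

    def select_cells(self, cols: Sequence[int]) -> "CountMatrix":
        cols = list(cols)
        return CountMatrix(
            list(self.gene_ids), [self.cell_ids[j] for j in cols], self.counts[:, cols]
        )


@dataclass
class GeneSet:
    name: str
    description: str
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("gene set name must be non-empty")
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} has no genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"gene set {self.name!r} has duplicate genes")


@dataclass
class GeneSetCollection:
    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_unique([s.name for s in self.sets], "gene set")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)


@dataclass
class CellMetadata:
    cell_ids: list[str]
    columns: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.cell_ids, "cell")


@dataclass
class Outcome:
    """Per-cell variable of interest: categorical condition or continuous pseudotime."""

    cell_ids: list[str]
    kind: str  # "categorical" | "continuous"
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "continuous"):
            raise ValidationError(f"unknown outcome kind {self.kind!r}")
        if len(self.cell_ids) != len(self.values):
            raise ValidationError("outcome values and cell ids differ in length")
        self.values = np.asarray(self.values)
        if self.kind == "categorical":
            levels, counts = np.unique(self.values, return_counts=True)
            if len(levels) < 2 or np.any(counts < 2):
                raise ValidationError(
                    "categorical outcome needs >= 2 levels with >= 2 cells each"
                )
        else:
            self.values = self.values.astype(float)
            if not np.all(np.isfinite(self.values)):
                raise ValidationError("continuous outcome contains non-finite values")
            if len(np.unique(self.values)) < 3:
                raise ValidationError("continuous outcome needs >= 3 distinct values")

    @property
    def levels(self) -> np.ndarray:
        if self.kind != "categorical":
            raise ValidationError("levels undefined for continuous outcome")
        return np.unique(self.values)


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {what} identifier {x!r}")
        seen.add(x)


# ---------------------------------------------------------------------------
# readers


def read_counts(path: str | Path, format: str = "mtx", transpose: bool = False) -> CountMatrix:
    """Read a count matrix.

    format="mtx": ``path`` is a Matrix Market coordinate file with sibling
    ``genes.tsv`` and ``barcodes.tsv`` (first column used). format="csv":
    first column holds gene ids, the header row cell ids.
    ``transpose`` flips a cells-x-genes file into the genes-x-cells contract.
    """
    path = Path(path)
    if format == "mtx":
        try:
            mat = scipy.io.mmread(path)
        except ValueError as e:  # pragma: no cover - message passthrough
            raise ParseError(f"malformed Matrix Market file {path}: {e}") from e
        genes_path = path.parent / "genes.tsv"
        barcodes_path = path.parent / "barcodes.tsv"
        if not genes_path.exists() or not barcodes_path.exists():
            raise ParseError(
                f"expected sibling genes.tsv and barcodes.tsv next to {path}"
            )
        gene_ids = _read_id_column(genes_path)
        cell_ids = _read_id_column(barcodes_path)
        mat = sp.csr_matrix(mat)
        if transpose:
            mat = mat.T.tocsr()
        return CountMatrix(gene_ids, cell_ids, mat)
    if format == "csv":
        try:
            df = pd.read_csv(path, index_col=0)
        except Exception as e:
            raise ParseError(f"malformed CSV header in {path}: {e}") from e
        if transpose:
            df = df.T
        values = df.to_numpy()
        if values.dtype == object or not np.issubdtype(values.dtype, np.number):
            raise ValidationError(f"non-numeric entry in {path}")
        return CountMatrix(
            [str(g) for g in df.index], [str(c) for c in df.columns], sp.csr_matrix(values)
        )
    raise ValueError(f"unknown counts format {format!r}")


def _read_id_column(path: Path) -> list[str]:
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    return ids


def write_counts_csv(counts: CountMatrix, path: str | Path) -> None:
    df = pd.DataFrame(counts.dense(), index=counts.gene_ids, columns=counts.cell_ids)
    df.to_csv(path)


def write_counts_mtx(counts: CountMatrix, out_dir: str | Path, name: str = "matrix.mtx") -> None:
    """Write 10x-style triplet: matrix.mtx + genes.tsv + barcodes.tsv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(out_dir / name, counts.counts.tocoo(), field="integer")
    (out_dir / "genes.tsv").write_text("".join(f"{g}\t{g}\n" for g in counts.gene_ids))
    (out_dir / "barcodes.tsv").write_text("".join(f"{c}\n" for c in counts.cell_ids))


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a Broad-format GMT file: name<TAB>description<TAB>gene1<TAB>...

    Within-line duplicate genes are dropped keeping the first occurrence; the
    total number of dropped duplicates is logged.
    """
    sets: list[GeneSet] = []
    n_dupes = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3"
                )
            name, desc = fields[0], fields[1]
            genes: list[str] = []
            seen: set[str] = set()
            for g in fields[2:]:
                if not g:
                    continue
                if g in seen:
                    n_dupes += 1
                    continue
                seen.add(g)
                genes.append(g)
            sets.append(GeneSet(name, desc, genes))
    if n_dupes:
        logger.warning("dropped %d duplicate gene entries while parsing %s", n_dupes, path)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description or "na", *s.genes]) + "\n")


def read_cell_metadata(
    path: str | Path,
    outcome_col: str,
    outcome_kind: str,
    cell_id_col: str | None = None,
) -> tuple[CellMetadata, Outcome]:
    """Read a per-cell metadata table and extract the outcome of interest.

    Cells with a missing outcome are excluded (never imputed) and their ids
    logged; the outcome covers the remaining cells only.
    """
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, dtype={0: str})
    id_col = cell_id_col if cell_id_col is not None else df.columns[0]
    if outcome_col not in df.columns:
        raise ValidationError(
            f"outcome column {outcome_col!r} not in {path}; available: "
            + ", ".join(c for c in df.columns)
        )
    cell_ids = [str(c) for c in df[id_col]]
    meta = CellMetadata(cell_ids, df.set_index(id_col))
    raw = df[outcome_col]
    keep = raw.notna().to_numpy()
    excluded = [cell_ids[i] for i in np.flatnonzero(~keep)]
    if excluded:
        logger.warning(
            "excluding %d cells with missing %r: %s",
            len(excluded), outcome_col, ", ".join(excluded[:10]),
        )
    kept_ids = [cell_ids[i] for i in np.flatnonzero(keep)]
    vals = raw[keep]
    if outcome_kind == "continuous":
        numeric = pd.to_numeric(vals, errors="coerce")
        bad = numeric.isna().to_numpy()
        if bad.any():
            cell = kept_ids[int(np.flatnonzero(bad)[0])]
            raise ValidationError(
                f"non-numeric value for continuous outcome at cell {cell!r}"
            )
        values = numeric.to_numpy(dtype=float)
    else:
        values = vals.astype(str).to_numpy()
    return meta, Outcome(kept_ids, outcome_kind, values)


RESULT_COLUMNS = [
    "gene_set", "n_genes_in_set", "n_genes_used", "relevance",
    "backend", "model", "outcome_kind", "seed", "skipped", "skip_reason",
]


def write_relevance_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a relevance table as TSV, sorted by relevance descending.

    Scores are written with 6 decimal places and round-trip at that precision.
    """
    if table.empty:
        raise ValidationError("refusing to write an empty relevance table")
    missing = [c for c in RESULT_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"relevance table missing columns: {missing}")
    out = table.loc[:, RESULT_COLUMNS].sort_values(
        "relevance", ascending=False, na_position="last", kind="mergesort"
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_relevance_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
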