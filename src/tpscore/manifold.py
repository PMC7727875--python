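"""Gene-set-specific low-dimensional manifolds from raw counts.

The default backend trains a count autoencoder (ZINB noise model) on the
gene-set submatrix and returns the bottleneck activations as per-cell
coordinates. PCA, tSNE and UMAP run on the same preprocessed input as
alternatives. Library-size factors are always computed transcriptome-wide —
on the full matrix, never the subset — so that a cell's sequencing depth is
estimated from all of its genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .autoencoder import CountAutoencoder
from .io_formats import CountMatrix, GeneSet, ValidationError

logger = logging.getLogger(__name__)

BACKENDS = ("autoencoder", "pca", "tsne", "umap")


class GeneSetSkip(Exception):
    """A gene set cannot be scored (e.g. too little overlap); skip, don't crash."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass
class SizeFactors:
    """Per-cell library-size factors: cell total counts / median total."""

    cell_ids: list[str]
    s: np.ndarray

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        if np.any(self.s <= 0):
            raise ValidationError("size factors must be strictly positive")

    def subset(self, cell_ids: list[str]) -> "SizeFactors":
        pos = {c: i for i, c in enumerate(self.cell_ids)}
        idx = [pos[c] for c in cell_ids]
        sf = object.__new__(SizeFactors)
        sf.cell_ids = list(cell_ids)
        sf.s = self.s[idx]
        return sf


@dataclass
class EmbedConfig:
    """Configuration of the dimension-reduction backend.

    ``hidden_layers`` is symmetric around the bottleneck; the middle entry
    must equal ``bottleneck_dim``. The three benchmark architectures
    (4, 2, 4), (8, 4, 8) and (16, 8, 16) are valid values.
    """

    method: str = "autoencoder"
    bottleneck_dim: int = 2
    hidden_layers: tuple[int, ...] = (64, 2, 64)
    epochs: int = 300
    patience: int = 15
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    noise_model: str = "zinb"
    batchnorm: bool = True

    def __post_init__(self) -> None:
        if self.method not in BACKENDS:
            raise ValidationError(f"unknown embedding method {self.method!r}")
        if self.bottleneck_dim < 2:
            raise ValidationError("bottleneck_dim must be >= 2")
        hl = tuple(self.hidden_layers)
        if len(hl) % 2 == 0 or hl[len(hl) // 2] != self.bottleneck_dim:
            raise ValidationError(
                f"hidden_layers {hl} must be symmetric with middle == bottleneck_dim"
                f" ({self.bottleneck_dim})"
            )
        self.hidden_layers = hl

    def with_seed(self, seed: int) -> "EmbedConfig":
        return replace(self, seed=seed)


@dataclass
class Embedding:
    """Per-cell coordinates of a gene-set-specific manifold."""

    cell_ids: list[str]
    coords: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("embedding contains non-finite coordinates")
        if self.coords.shape[0] != len(self.cell_ids):
            raise ValidationError("embedding rows do not match cell ids")


def compute_size_factors(counts: CountMatrix) -> SizeFactors:
    """s_j = total_j / median(total) over the transcriptome-wide matrix."""
    totals = np.asarray(counts.counts.sum(axis=0)).ravel().astype(float)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValidationError(
            f"cell {counts.cell_ids[int(zero[0])]!r} has zero total counts; "
            "cannot form a size factor"
        )
    return SizeFactors(list(counts.cell_ids), totals / np.median(totals))


def filter_low_genes(counts: CountMatrix, min_total: int = 3) -> CountMatrix:
    """Drop genes with fewer than ``min_total`` counts summed across all cells."""
    if min_total < 0:
        raise ValidationError("min_total must be >= 0")
    row_sums = np.asarray(counts.counts.sum(axis=1)).ravel()
    keep = np.flatnonzero(row_sums >= min_total)
    if keep.size == 0:
        raise ValidationError("gene filter removed every gene")
    if keep.size == counts.n_genes:
        return counts
    return counts.select_genes(keep)


def subset_counts(
    counts: CountMatrix, gene_set: GeneSet, min_overlap: int = 10
) -> CountMatrix:
    """Restrict rows to genes shared with the set, preserving matrix row order.

    Raises :class:`GeneSetSkip` when the overlap is below ``min_overlap``.
    """
    members = set(gene_set.genes)
    rows = [i for i, g in enumerate(counts.gene_ids) if g in members]
    if len(rows) < min_overlap:
        raise GeneSetSkip(
            f"overlap {len(rows)} < min_overlap {min_overlap} "
            f"for gene set {gene_set.name!r}"
        )
    return counts.select_genes(rows)


def preprocess_expression(subset: CountMatrix, size_factors: SizeFactors) -> np.ndarray:
    """Size-factor-normalize, log1p, per-gene z-score. Returns cells x genes.

    Genes with zero variance after log-normalization become all-zero columns.
    """
    s = size_factors.subset(subset.cell_ids).s
    X = subset.dense().T.astype(float)  # cells x genes
    X = np.log1p(X / s[:, None])
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _sorted_by_gene(subset: CountMatrix) -> CountMatrix:
    """Lexicographic gene order, so embeddings don't depend on input row order."""
    order = sorted(range(subset.n_genes), key=lambda i: subset.gene_ids[i])
    if order == list(range(subset.n_genes)):
        return subset
    return subset.select_genes(order)


def embed_autoencoder(
    subset: CountMatrix, size_factors: SizeFactors, config: EmbedConfig
) -> Embedding:
    """Train the count autoencoder on the submatrix; bottleneck = coordinates.

    Deterministic for a fixed seed (single-threaded training). Raw counts are
    the likelihood target; the encoder sees the z-scored log-normal input.
    """
    subset = _sorted_by_gene(subset)
    sf = size_factors.subset(subset.cell_ids)
    X = preprocess_expression(subset, size_factors)
    Y = subset.dense().T.astype(float)
    model = CountAutoencoder(
        n_genes=subset.n_genes,
        hidden_layers=config.hidden_layers,
        noise_model=config.noise_model,
        batchnorm=config.batchnorm,
        learning_rate=config.learning_rate,
        seed=config.seed,
    )
    model.fit(
        X, Y, sf.s,
        epochs=config.epochs,
        patience=config.patience,
        batch_size=config.batch_size,
    )
    coords = model.transform(X)
    return Embedding(
        list(subset.cell_ids),
        coords,
        provenance={
            "method": "autoencoder",
            "config": config,
            "n_genes_used": subset.n_genes,
            "epochs_run": len(model.train_loss_history),
        },
    )


def embed_classic(
    subset: CountMatrix, size_factors: SizeFactors, config: EmbedConfig
) -> Embedding:
    """PCA / tSNE / UMAP on the preprocessed gene-set submatrix."""
    if config.method not in ("pca", "tsne", "umap"):
        raise ValidationError(f"embed_classic cannot run method {config.method!r}")
    subset = _sorted_by_gene(subset)
    X = preprocess_expression(subset, size_factors)
    d = config.bottleneck_dim
    if config.method == "pca":
        if d > min(X.shape):
            raise ValidationError(
                f"bottleneck_dim {d} exceeds min(genes, cells) = {min(X.shape)}"
            )
        from sklearn.decomposition import PCA

        coords = PCA(n_components=d, svd_solver="full").fit_transform(X)
    elif config.method == "tsne":
        from sklearn.manifold import TSNE

        perplexity = min(30.0, max(2.0, (X.shape[0] - 1) / 3.0))
        coords = TSNE(
            n_components=d, random_state=config.seed, perplexity=perplexity,
            init="pca", n_jobs=1,
        ).fit_transform(X)
    else:
        from umap import UMAP

        n_neighbors = min(15, max(2, X.shape[0] - 1))
        coords = UMAP(
            n_components=d, random_state=config.seed, n_neighbors=n_neighbors, n_jobs=1,
        ).fit_transform(X)
    return Embedding(
        list(subset.cell_ids),
        np.asarray(coords, dtype=float),
        provenance={
            "method": config.method,
            "config": config,
            "n_genes_used": subset.n_genes,
        },
    )


def embed(
    subset: CountMatrix, size_factors: SizeFactors, config: EmbedConfig
) -> Embedding:
    """Dispatch to the configured backend."""
    if config.method == "autoencoder":
        return embed_autoencoder(subset, size_factors, config)
    return embed_classic(subset, size_factors, config)
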