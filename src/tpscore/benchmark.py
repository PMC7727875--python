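"""Benchmarking utilities: the relevance-vs-DE-fraction sweep, the
weak-signal significance test, and a signature-score + Geary-C
autocorrelation comparator in the style of global-manifold tools.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CountMatrix, GeneSet, GeneSetCollection, ValidationError
from .manifold import EmbedConfig, Embedding, SizeFactors, preprocess_expression
from .relevance import score_gene_sets
from .simulate import MixedGeneSetTruth, SimulatedDataset

SWEEP_COLUMNS = [
    "gene_set", "de_fraction", "bootstrap_index", "backend", "model",
    "hidden_layers", "relevance",
]


def fraction_sweep(
    sim: SimulatedDataset,
    sets: GeneSetCollection,
    truth: list[MixedGeneSetTruth],
    configs: list[EmbedConfig],
    model: str = "rf",
    n_trees: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Score every gene set under every configuration; one tidy row each.

    Joins relevance scores with the generating DE fraction from the truth
    records, so downstream code never re-derives ground truth from set names.
    """
    truth_by_name = {t.name: t for t in truth}
    missing = [s.name for s in sets if s.name not in truth_by_name]
    if missing:
        raise ValidationError(f"no truth record for gene sets: {missing[:5]}")
    rows = []
    for config in configs:
        table = score_gene_sets(
            sim.counts, sets, sim.group,
            embed_config=config, model=model, n_trees=n_trees, seed=seed,
        )
        for rec in table.itertuples(index=False):
            t = truth_by_name[rec.gene_set]
            rows.append({
                "gene_set": rec.gene_set,
                "de_fraction": t.de_fraction,
                "bootstrap_index": t.bootstrap_index,
                "backend": config.method,
                "model": model,
                "hidden_layers": "x".join(str(h) for h in config.hidden_layers),
                "relevance": rec.relevance,
            })
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


def t_test_vs_random(
    sweep: pd.DataFrame,
    test_fraction: float = 0.2,
    equal_var: bool = False,
) -> dict:
    """One-sided two-sample t-test: relevance at ``test_fraction`` > at fraction 0.

    Welch (unequal-variance) by default; ``equal_var=True`` pools variances.
    """
    x1 = sweep.loc[sweep["de_fraction"] == test_fraction, "relevance"].dropna().to_numpy()
    x0 = sweep.loc[sweep["de_fraction"] == 0.0, "relevance"].dropna().to_numpy()
    if len(x1) < 2 or len(x0) < 2:
        raise ValidationError(
            f"need >= 2 scores per group; got {len(x1)} at fraction "
            f"{test_fraction} and {len(x0)} at fraction 0"
        )
    if np.var(x1) == 0 and np.var(x0) == 0:
        if np.mean(x1) == np.mean(x0):
            raise ValidationError("zero variance in both groups and equal means")
        # degenerate but directionally unambiguous: epsilon-variance convention
        return {
            "t": np.inf if np.mean(x1) > np.mean(x0) else -np.inf,
            "p": 0.0 if np.mean(x1) > np.mean(x0) else 1.0,
            "n1": len(x1), "n0": len(x0),
        }
    res = stats.ttest_ind(x1, x0, equal_var=equal_var, alternative="greater")
    return {"t": float(res.statistic), "p": float(res.pvalue), "n1": len(x1), "n0": len(x0)}


def signature_score(
    counts: CountMatrix,
    size_factors: SizeFactors,
    gene_set: GeneSet,
    signs: dict[str, int] | None = None,
) -> np.ndarray:
    """Per-cell mean of signed, z-scored log-normalized member-gene expression.

    ``signs`` maps gene id to +1 (activated) or -1 (repressed); the default
    is undirected (+1 for every gene).
    """
    members = [g for g in gene_set.genes if g in set(counts.gene_ids)]
    if not members:
        raise ValidationError(f"gene set {gene_set.name!r} has no overlap with counts")
    pos = {g: i for i, g in enumerate(counts.gene_ids)}
    rows = [pos[g] for g in members]
    sub = counts.select_genes(rows)
    Z = preprocess_expression(sub, size_factors)  # cells x members, z-scored
    sign_vec = np.array([(signs or {}).get(g, 1) for g in members], dtype=float)
    return (Z * sign_vec[None, :]).mean(axis=1)


def geary_autocorrelation(
    score: np.ndarray, embedding: Embedding, k_neighbors: int = 30
) -> float:
    """1 - Geary's C of the score over the kNN graph of the embedding.

    The graph uses Euclidean k-nearest neighbors on the embedding
    coordinates, symmetrized by union, with unit weights:

        C = (n - 1) * sum_ij w_ij (y_i - y_j)^2 / (2 W sum_i (y_i - y_bar)^2)

    Returns 1 - C so that larger values mean stronger local autocorrelation
    (a score that varies smoothly over the manifold); ~0 for a randomly
    shuffled score.
    """
    y = np.asarray(score, dtype=float)
    n = len(y)
    if n != len(embedding.cell_ids):
        raise ValidationError("score length does not match embedding")
    if n < k_neighbors + 1:
        raise ValidationError(f"need >= {k_neighbors + 1} cells for k={k_neighbors}")
    if np.var(y) == 0:
        raise ValidationError("score has zero variance; Geary's C undefined")
    from sklearn.neighbors import NearestNeighbors

    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(embedding.coords)
    graph = nn.kneighbors_graph(embedding.coords, mode="connectivity")
    graph.setdiag(0)
    graph.eliminate_zeros()
    W = graph.maximum(graph.T)  # symmetrize by union, unit weights
    return 1.0 - geary_c_from_graph(y, W)


def geary_c_from_graph(y: np.ndarray, W) -> float:
    """Geary's C for an explicit (sparse) symmetric weight matrix."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    coo = W.tocoo()
    num = float(np.sum(coo.data * (y[coo.row] - y[coo.col]) ** 2))
    w_total = float(coo.data.sum())
    denom = 2.0 * w_total * float(np.sum((y - y.mean()) ** 2))
    return (n - 1) * num / denom
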