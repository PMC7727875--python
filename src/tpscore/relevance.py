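"""Relevance scoring: how much outcome information a gene-set manifold carries.

The relevance score of a gene set is the out-of-bag (OOB) performance of a
500-tree random forest that predicts the outcome of interest from the
cells' manifold coordinates: OOB accuracy for categorical outcomes
(condition labels), OOB R^2 for continuous ones (pseudotime). An RBF
support-vector classifier scored by stratified 5-fold cross-validation is
available as a benchmarking comparator (SVMs have no out-of-bag notion).
"""

from __future__ import annotations

import logging
import time
import zlib

import numpy as np
import pandas as pd

from .io_formats import (
    CountMatrix,
    GeneSetCollection,
    Outcome,
    ValidationError,
)
from .manifold import (
    EmbedConfig,
    Embedding,
    GeneSetSkip,
    compute_size_factors,
    embed,
    subset_counts,
)

logger = logging.getLogger(__name__)

MIN_CELLS = 50


def derive_seed(master_seed: int, name: str) -> int:
    """Deterministic per-gene-set seed from the master seed and the set name."""
    ss = np.random.SeedSequence([master_seed, zlib.crc32(name.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def _align(embedding: Embedding, outcome: Outcome) -> tuple[np.ndarray, np.ndarray]:
    pos = {c: i for i, c in enumerate(outcome.cell_ids)}
    emb_idx, out_idx = [], []
    for i, c in enumerate(embedding.cell_ids):
        j = pos.get(c)
        if j is not None:
            emb_idx.append(i)
            out_idx.append(j)
    if len(emb_idx) < MIN_CELLS:
        raise ValidationError(
            f"embedding and outcome share only {len(emb_idx)} cells (< {MIN_CELLS})"
        )
    return embedding.coords[emb_idx], outcome.values[np.asarray(out_idx)]


def relevance_score(
    embedding: Embedding,
    outcome: Outcome,
    model: str = "rf",
    n_trees: int = 500,
    seed: int = 0,
) -> float:
    """Score one embedding against the outcome. Deterministic for a fixed seed."""
    X, y = _align(embedding, outcome)
    if outcome.kind == "categorical" and len(np.unique(y)) < 2:
        raise ValidationError("outcome has a single level on the scored cells")
    if model == "rf":
        if outcome.kind == "categorical":
            from sklearn.ensemble import RandomForestClassifier

            clf = RandomForestClassifier(
                n_estimators=n_trees, oob_score=True, random_state=seed, n_jobs=1
            )
            clf.fit(X, y)
            return float(clf.oob_score_)
        from sklearn.ensemble import RandomForestRegressor

        reg = RandomForestRegressor(
            n_estimators=n_trees, oob_score=True, random_state=seed, n_jobs=1
        )
        reg.fit(X, y)
        return float(reg.oob_score_)
    if model == "svm":
        if outcome.kind != "categorical":
            raise ValidationError("svm relevance supports categorical outcomes only")
        from sklearn.model_selection import StratifiedKFold, cross_val_score
        from sklearn.svm import SVC

        cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
        scores = cross_val_score(SVC(), X, y, cv=cv, scoring="accuracy")
        return float(scores.mean())
    raise ValidationError(f"unknown relevance model {model!r}")


def score_gene_sets(
    counts: CountMatrix,
    sets: GeneSetCollection,
    outcome: Outcome,
    embed_config: EmbedConfig | None = None,
    model: str = "rf",
    n_trees: int = 500,
    min_overlap: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the full scoring loop over a gene-set collection.

    Size factors are computed once, transcriptome-wide, on ``counts``. Cells
    absent from the outcome are dropped before embedding so each manifold is
    learned on exactly the scored cells. Per-set seeds derive from the master
    seed and the set name, so results are independent of collection order.

    Returns one row per gene set (scored or skipped) with the columns of
    :data:`tpscore.io_formats.RESULT_COLUMNS`.
    """
    if embed_config is None:
        embed_config = EmbedConfig()
    keep = set(outcome.cell_ids)
    cols = [j for j, c in enumerate(counts.cell_ids) if c in keep]
    if len(cols) < MIN_CELLS:
        raise ValidationError(
            f"counts and outcome share only {len(cols)} cells (< {MIN_CELLS})"
        )
    if len(cols) < counts.n_cells:
        counts = counts.select_cells(cols)
    size_factors = compute_size_factors(counts)

    records = []
    n_scored = 0
    for gene_set in sets:
        set_seed = derive_seed(seed, gene_set.name)
        rec = {
            "gene_set": gene_set.name,
            "n_genes_in_set": len(gene_set.genes),
            "n_genes_used": 0,
            "relevance": np.nan,
            "backend": embed_config.method,
            "model": model,
            "outcome_kind": outcome.kind,
            "seed": set_seed,
            "skipped": False,
            "skip_reason": "",
        }
        t0 = time.perf_counter()
        try:
            subset = subset_counts(counts, gene_set, min_overlap=min_overlap)
        except GeneSetSkip as skip:
            rec["skipped"] = True
            rec["skip_reason"] = skip.reason
            logger.info("skipping %s: %s", gene_set.name, skip.reason)
            records.append(rec)
            continue
        embedding = embed(subset, size_factors, embed_config.with_seed(set_seed))
        rec["n_genes_used"] = subset.n_genes
        rec["relevance"] = relevance_score(
            embedding, outcome, model=model, n_trees=n_trees, seed=set_seed
        )
        n_scored += 1
        logger.info(
            "%s: relevance=%.4f (%d genes, %.1fs)",
            gene_set.name, rec["relevance"], subset.n_genes, time.perf_counter() - t0,
        )
        records.append(rec)
    if n_scored == 0:
        raise ValidationError(
            "every gene set was skipped — check that gene identifiers in the "
            "collection match the count matrix (exact, case-sensitive)"
        )
    return pd.DataFrame.from_records(records)
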