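"""Splat-style synthetic scRNA-seq counts with ground-truth DE annotation.

The generator follows the splat model family: gamma-distributed gene base
means, log-normal library sizes, multinomial group assignment, log-normal
per-group differential-expression factors (randomly inverted for
down-regulation), negative-binomial counts via Poisson-gamma mixing with a
common biological coefficient of variation, and experiment-wide logistic
dropout as a function of the (log) expected expression. Ground truth —
which genes are truly DE, their per-group factors, and the pre-dropout
expected counts — is recorded alongside the counts.

Two presets reproduce the benchmark scenarios: ``two_group`` (500 genes x
2,000 cells, two equal groups, DE proportion 0.1, DE factor location 0.01,
dropout midpoint 5, dropout shape -1) and ``four_group`` (1,000 genes x
4,000 cells, group proportions 0.1/0.2/0.3/0.4, dropout midpoint 2).

Deliberate simplifications relative to full splat: no expression-outlier
genes, no paths/trajectories, no batch effects, and a constant BCV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

from .io_formats import (
    CountMatrix,
    GeneSet,
    GeneSetCollection,
    Outcome,
    ValidationError,
)


@dataclass
class SimParams:
    """Simulation parameters (splat-style defaults)."""

    n_genes: int = 500
    n_cells: int = 2000
    group_proportions: tuple[float, ...] = (0.5, 0.5)
    de_prob: float = 0.1
    de_factor_loc: float = 0.01
    de_factor_scale: float = 0.4
    mean_shape: float = 0.6
    mean_rate: float = 0.3
    lib_loc: float = 11.0
    lib_scale: float = 0.2
    bcv_common: float = 0.1
    dropout_mid: float = 5.0
    dropout_shape: float = -1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_cells < 1:
            raise ValidationError("n_genes and n_cells must be positive")
        props = np.asarray(self.group_proportions, dtype=float)
        if abs(props.sum() - 1.0) > 1e-9 or np.any(props <= 0):
            raise ValidationError("group_proportions must be positive and sum to 1")
        if not 0.0 <= self.de_prob <= 1.0:
            raise ValidationError("de_prob must lie in [0, 1]")
        for name in ("de_factor_scale", "mean_shape", "mean_rate", "bcv_common"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


PRESETS: dict[str, SimParams] = {
    "two_group": SimParams(),
    "four_group": SimParams(
        n_genes=1000,
        n_cells=4000,
        group_proportions=(0.1, 0.2, 0.3, 0.4),
        dropout_mid=2.0,
    ),
}


@dataclass
class SimulatedDataset:
    counts: CountMatrix
    group: Outcome
    de_flags: np.ndarray          # genes; True iff some group factor != 1
    de_factors: np.ndarray        # genes x groups
    true_means: np.ndarray        # genes x cells, pre-dropout expected counts
    params: SimParams


@dataclass
class MixedGeneSetTruth:
    """Ground truth for one mixed gene set of the benchmark."""

    name: str
    de_fraction: float
    bootstrap_index: int
    genes: list[str]
    de_flags: list[bool] = field(default_factory=list)


def simulate_counts(params: SimParams) -> SimulatedDataset:
    """Draw one seeded dataset from the generative model described above."""
    rng = np.random.default_rng(params.seed)
    n_genes, n_cells = params.n_genes, params.n_cells
    n_groups = len(params.group_proportions)

    base_mean = rng.gamma(params.mean_shape, scale=1.0 / params.mean_rate, size=n_genes)
    lib_size = rng.lognormal(params.lib_loc, params.lib_scale, size=n_cells)
    group = rng.choice(n_groups, size=n_cells, p=params.group_proportions)

    is_de = rng.random(n_genes) < params.de_prob
    factors = np.ones((n_genes, n_groups))
    n_de = int(is_de.sum())
    if n_de:
        raw = np.exp(
            rng.normal(params.de_factor_loc, params.de_factor_scale, size=(n_de, n_groups))
        )
        flip = rng.random((n_de, n_groups)) < 0.5
        raw[flip] = 1.0 / raw[flip]
        factors[is_de] = raw
    de_flags = np.any(factors != 1.0, axis=1)

    # expected expression: per-cell gene proportions scaled by library size
    group_profile = base_mean[:, None] * factors          # genes x groups
    group_profile = group_profile / group_profile.sum(axis=0, keepdims=True)
    lam = group_profile[:, group] * lib_size[None, :]     # genes x cells

    # negative-binomial counts via Poisson-gamma mixture (CV^2 = bcv^2)
    bcv2 = params.bcv_common**2
    noise = rng.gamma(1.0 / bcv2, scale=bcv2, size=lam.shape)
    counts = rng.poisson(lam * noise).astype(np.int64)

    # experiment-wide logistic dropout on ln(lambda + 1)
    p_drop = 1.0 / (1.0 + np.exp(-params.dropout_shape * (np.log(lam + 1.0) - params.dropout_mid)))
    counts[rng.random(lam.shape) < p_drop] = 0

    gene_ids = [f"gene_{i:04d}" for i in range(n_genes)]
    cell_ids = [f"cell_{j:05d}" for j in range(n_cells)]
    cm = CountMatrix(gene_ids, cell_ids, sp.csr_matrix(counts))
    outcome = Outcome(
        cell_ids, "categorical", np.array([f"group{k + 1}" for k in group])
    )
    return SimulatedDataset(cm, outcome, de_flags, factors, lam, params)


def make_mixed_gene_sets(
    sim: SimulatedDataset,
    fractions: list[float] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
    n_bootstrap: int = 10,
    set_size: int = 50,
    seed: int = 0,
) -> tuple[GeneSetCollection, list[MixedGeneSetTruth]]:
    """Build gene sets mixing truly DE genes with non-DE genes.

    For each (fraction, bootstrap) pair, ``set_size * fraction`` genes are
    drawn uniformly without replacement from the truly DE genes and the
    remainder from the non-DE genes; the realized DE fraction equals the
    nominal one exactly, so ``set_size * fraction`` must be integral.
    """
    rng = np.random.default_rng(seed)
    gene_ids = np.asarray(sim.counts.gene_ids)
    de_pool = gene_ids[sim.de_flags]
    bg_pool = gene_ids[~sim.de_flags]

    for f in fractions:
        n_de = set_size * f
        if abs(n_de - round(n_de)) > 1e-9:
            raise ValidationError(
                f"set_size * fraction must be integral; got {set_size} * {f}"
            )
    need_de = int(round(set_size * max(fractions)))
    if need_de > len(de_pool):
        raise ValidationError(
            f"need {need_de} truly DE genes but only {len(de_pool)} are available"
        )
    need_bg = int(round(set_size * (1 - min(fractions))))
    if need_bg > len(bg_pool):
        raise ValidationError(
            f"need {need_bg} non-DE genes but only {len(bg_pool)} are available"
        )

    flag_of = dict(zip(gene_ids.tolist(), sim.de_flags.tolist()))
    sets: list[GeneSet] = []
    truths: list[MixedGeneSetTruth] = []
    for f in fractions:
        k_de = int(round(set_size * f))
        for b in range(n_bootstrap):
            chosen = np.concatenate([
                rng.choice(de_pool, size=k_de, replace=False),
                rng.choice(bg_pool, size=set_size - k_de, replace=False),
            ])
            name = f"mix_f{f:g}_b{b}"
            genes = chosen.tolist()
            sets.append(GeneSet(name, f"de_fraction={f:g} bootstrap={b}", genes))
            truths.append(
                MixedGeneSetTruth(name, float(f), b, genes, [flag_of[g] for g in genes])
            )
    return GeneSetCollection(sets), truths


def benchmark_set_size(sim: SimulatedDataset, target: int = 50) -> int:
    """Largest multiple of 5 <= min(target, number of truly DE genes).

    Keeps ``set_size * fraction`` integral for the canonical fractions
    (0, 0.2, ..., 1) while guaranteeing the fraction-1 sets can be drawn.
    """
    n_de = int(sim.de_flags.sum())
    size = min(target, (n_de // 5) * 5)
    if size < 5:
        raise ValidationError(f"only {n_de} truly DE genes; cannot build benchmark sets")
    return size


def guess_baseline(outcome: Outcome, rule: str = "uniform") -> float:
    """Accuracy of guessing: 1/k levels (uniform) or the majority frequency."""
    if outcome.kind != "categorical":
        raise ValidationError("guess baselines are defined for categorical outcomes")
    levels, counts = np.unique(outcome.values, return_counts=True)
    if rule == "uniform":
        return 1.0 / len(levels)
    if rule == "majority":
        return float(counts.max() / counts.sum())
    raise ValidationError(f"unknown baseline rule {rule!r}")
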