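"""Running-sum (weighted Kolmogorov–Smirnov) enrichment scores.

The enrichment score (ES) of a gene set S against a ranked list L of N genes
is the maximum deviation from zero of the running sum that increases by
|r_j|^α / N_R at each member gene (N_R = Σ_{g∈S} |r_g|^α) and decreases by
1/(N − N_H) at each non-member (N_H = |S|). Used here in two modes:

* per-sample: genes ranked by expression within one sample; the ES of an
  immune-cell signature set is that cell type's relative abundance in the
  sample (single-sample GSEA, default weight α = 0.25);
* two-class: genes ranked by a signal-to-noise statistic between case and
  control groups (classic GSEA phenotype ranking, α = 1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .data_io import ExpressionMatrix

logger = logging.getLogger(__name__)

#: default ssGSEA-style rank weight for per-sample abundance scoring
DEFAULT_ALPHA_PER_SAMPLE = 0.25
#: default weight for two-class phenotype ranking
DEFAULT_ALPHA_TWO_CLASS = 1.0


@dataclass
class RankedList:
    """Gene IDs ordered by a non-increasing ranking statistic."""

    gene_ids: list[str]
    ranking_stats: np.ndarray

    def __post_init__(self) -> None:
        self.ranking_stats = np.asarray(self.ranking_stats, dtype=float)
        if len(self.gene_ids) != self.ranking_stats.shape[0]:
            raise ValueError("gene_ids and ranking_stats lengths differ")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("ranked list contains duplicate gene IDs")
        if np.any(np.diff(self.ranking_stats) > 0):
            raise ValueError("ranking statistics must be non-increasing")

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class EnrichmentResult:
    """Signed ES with the 0-based index of the ranked list where it is attained."""

    es: float
    index: int


@dataclass
class AbundanceTable:
    """Cell types × samples matrix of enrichment scores.

    ``overlap_counts`` records, per cell type, how many signature genes were
    present in the expression matrix.
    """

    cell_types: list[str]
    sample_ids: list[str]
    values: np.ndarray
    overlap_counts: dict[str, int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cell_types), len(self.sample_ids)):
            raise ValueError("abundance matrix shape mismatch")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.cell_types, columns=self.sample_ids)


def _running_sum_increments(
    ranked_stats: np.ndarray, member_positions: np.ndarray, weight_alpha: float
) -> np.ndarray:
    """Per-position increments of the hit-minus-miss running sum."""
    n = ranked_stats.shape[0]
    n_h = member_positions.shape[0]
    weights = np.abs(ranked_stats[member_positions]) ** weight_alpha
    n_r = weights.sum()
    if n_r == 0.0:
        warnings.warn(
            "all member ranking statistics are zero; falling back to unweighted (alpha=0) hits",
            stacklevel=3,
        )
        weights = np.ones(n_h)
        n_r = float(n_h)
    increments = np.full(n, -1.0 / (n - n_h))
    increments[member_positions] = weights / n_r
    return increments


def enrichment_score(
    ranked: RankedList,
    set_members,
    weight_alpha: float = DEFAULT_ALPHA_PER_SAMPLE,
) -> EnrichmentResult:
    """ES of ``set_members`` against ``ranked``: the running-sum deviation of
    largest magnitude (earliest index on ties), signed, in [−1, 1].

    Members absent from the ranked list are ignored; the effective set must be
    a nonempty proper subset of the list.
    """
    if weight_alpha < 0:
        raise ValueError("weight_alpha must be non-negative")
    members = set(set_members)
    positions = np.flatnonzero([g in members for g in ranked.gene_ids])
    n = len(ranked)
    if positions.size == 0:
        raise ValueError("gene set has no members in the ranked list")
    if positions.size == n:
        raise ValueError("gene set covers the whole ranked list; miss penalty undefined")
    running = np.cumsum(
        _running_sum_increments(ranked.ranking_stats, positions, weight_alpha)
    )
    idx = int(np.argmax(np.abs(running)))
    return EnrichmentResult(es=float(running[idx]), index=idx)


def rank_per_sample(expr: ExpressionMatrix, sample: str) -> RankedList:
    """Rank genes by descending expression in one sample; ties break by gene ID."""
    column = expr.column(sample)
    genes = np.asarray(expr.gene_ids)
    order = np.lexsort((genes, -column))
    return RankedList(genes[order].tolist(), column[order])


def signal_to_noise(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Signal-to-noise ratio (μ₁−μ₀)/(σ₁+σ₀) per gene, with each class
    standard deviation floored at 0.2·|μ| (0.2 when μ = 0).

    ``values`` is genes × samples; both classes need at least two samples for
    the sample standard deviations to exist.
    """
    labels = np.asarray(labels, dtype=int)
    case = values[:, labels == 1]
    ctrl = values[:, labels == 0]
    if case.shape[1] < 2 or ctrl.shape[1] < 2:
        raise ValueError("each class needs at least 2 samples for signal-to-noise ranking")

    def _floored_sd(block: np.ndarray) -> np.ndarray:
        mu = block.mean(axis=1)
        sd = block.std(axis=1, ddof=1)
        floor = np.where(mu == 0.0, 0.2, 0.2 * np.abs(mu))
        return np.maximum(sd, floor)

    return (case.mean(axis=1) - ctrl.mean(axis=1)) / (_floored_sd(case) + _floored_sd(ctrl))


def rank_two_class(expr: ExpressionMatrix, labels) -> RankedList:
    """Rank genes by the case-vs-control signal-to-noise statistic, descending."""
    stats = signal_to_noise(expr.values, labels)
    genes = np.asarray(expr.gene_ids)
    order = np.lexsort((genes, -stats))
    return RankedList(genes[order].tolist(), stats[order])


def score_cohort(
    expr: ExpressionMatrix,
    sets: dict[str, list[str]],
    weight_alpha: float = DEFAULT_ALPHA_PER_SAMPLE,
) -> AbundanceTable:
    """Per-sample ES for every signature set: the abundance table.

    Signature genes missing from the expression matrix are dropped (counts
    recorded in ``overlap_counts``); sets with no overlap are skipped with a
    warning. Internally replicates :func:`enrichment_score` on integer
    positions to avoid re-matching gene IDs per sample.
    """
    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}
    effective: dict[str, np.ndarray] = {}
    overlap_counts: dict[str, int] = {}
    for name, genes in sets.items():
        idx = np.array(sorted(gene_index[g] for g in set(genes) if g in gene_index), dtype=int)
        overlap_counts[name] = int(idx.size)
        if idx.size == 0:
            warnings.warn(f"signature {name!r} has no genes in the expression matrix; dropped")
            continue
        if idx.size == expr.n_genes:
            raise ValueError(f"signature {name!r} covers every gene in the matrix")
        effective[name] = idx
    if not effective:
        raise ValueError("no signature set overlaps the expression matrix")

    genes_arr = np.asarray(expr.gene_ids)
    n = expr.n_genes
    values = np.empty((len(effective), expr.n_samples))
    for j, sample in enumerate(expr.sample_ids):
        column = expr.values[:, j]
        order = np.lexsort((genes_arr, -column))
        ranked_stats = column[order]
        inverse = np.empty(n, dtype=int)
        inverse[order] = np.arange(n)
        for i, (name, idx) in enumerate(effective.items()):
            positions = np.sort(inverse[idx])
            running = np.cumsum(
                _running_sum_increments(ranked_stats, positions, weight_alpha)
            )
            values[i, j] = running[np.argmax(np.abs(running))]
    logger.info(
        "scored %d signatures x %d samples (alpha=%g)",
        len(effective), expr.n_samples, weight_alpha,
    )
    return AbundanceTable(
        cell_types=list(effective.keys()),
        sample_ids=list(expr.sample_ids),
        values=values,
        overlap_counts=overlap_counts,
    )


def permutation_pvalues(
    expr: ExpressionMatrix,
    sets: dict[str, list[str]],
    weight_alpha: float = DEFAULT_ALPHA_PER_SAMPLE,
    n_permutations: int = 0,
    seed: int | None = None,
) -> "np.ndarray | None":
    """Optional gene-label permutation null for the abundance table.

    Returns a cell types × samples matrix of two-sided permutation p-values
    (fraction of shuffles whose |ES| meets or exceeds the observed |ES|), or
    None when ``n_permutations`` is 0 (the default: the analysis reports raw
    ES as abundance, without permutation normalization).
    """
    if n_permutations == 0:
        return None
    rng = np.random.default_rng(seed)
    observed = score_cohort(expr, sets, weight_alpha)
    exceed = np.zeros_like(observed.values)
    for _ in range(n_permutations):
        perm = rng.permutation(expr.n_genes)
        shuffled = ExpressionMatrix(
            [expr.gene_ids[i] for i in perm], list(expr.sample_ids), expr.values
        )
        null = score_cohort(shuffled, sets, weight_alpha)
        exceed += np.abs(null.values) >= np.abs(observed.values)
    return (exceed + 1.0) / (n_permutations + 1.0)
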