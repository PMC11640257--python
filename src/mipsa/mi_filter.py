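"""Stage 1: mutual-information gene ranking with redundancy removal.

Each gene's expression is discretized and scored by the plug-in (histogram)
mutual information with the binary class label,

    I(X; Y) = H(Y) - H(Y | X)        [bits]

where H is the plug-in Shannon entropy over observed frequencies. Genes are
ranked by descending MI, the top k kept, and then — scanning in rank
order — any kept gene whose absolute Pearson correlation with an
already-retained gene reaches the redundancy threshold is dropped, so each
cluster of near-duplicate genes contributes only its highest-MI member.

Discretization is equal-frequency (quantile) binning: it is robust to the
heavy-tailed distributions typical of expression data and makes the score
invariant under any strictly monotone transform of the values (quantile
order is preserved), so raw, log and z-scored inputs rank identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .expression_io import ExpressionDataset, GeneSubset

_LOG2 = np.log(2.0)


@dataclass
class FilterConfig:
    """Stage-1 parameters.

    k : genes kept after ranking (default 100).
    n_bins : equal-frequency bins for discretizing expression (default 10).
    redundancy_threshold : absolute Pearson correlation at or above which a
        lower-ranked gene is dropped as redundant (default 0.9).

    All information quantities are in bits (log base 2).
    """

    k: int = 100
    n_bins: int = 10
    redundancy_threshold: float = 0.9

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if not (0.0 < self.redundancy_threshold <= 1.0):
            raise ValueError("redundancy_threshold must be in (0, 1]")


@dataclass
class MIRanking:
    """Result of rank_and_filter.

    scores : gene_id -> MI in bits.
    order : all gene ids, descending MI, ties broken by gene id.
    kept : the surviving filtered pool (subset of the top-k, rank order).
    dropped_redundant : (dropped_gene, retained_partner, correlation)
        for every top-k gene removed by redundancy removal.
    """

    scores: dict[str, float]
    order: list[str]
    kept: GeneSubset
    dropped_redundant: list[tuple[str, str, float]] = field(default_factory=list)


def entropy(labels: np.ndarray) -> float:
    """Plug-in Shannon entropy of a discrete vector, in bits.

    Uses observed frequencies with the 0*log(0) = 0 convention.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("entropy of an empty vector is undefined")
    _, counts = np.unique(labels, return_counts=True)
    p = counts / labels.size
    return float(-(p * np.log(p)).sum() / _LOG2)


def conditional_entropy(gene_bins: np.ndarray, labels: np.ndarray) -> float:
    """Plug-in conditional entropy H(Y | X) in bits.

    X is the discretized gene, Y the label:
    H(Y|X) = sum_x p(x) * [ -sum_y p(y|x) log2 p(y|x) ], over observed
    joint counts.
    """
    gene_bins = np.asarray(gene_bins)
    labels = np.asarray(labels)
    if gene_bins.shape != labels.shape:
        raise ValueError("gene_bins and labels must have equal length")
    if labels.size == 0:
        raise ValueError("conditional entropy of empty vectors is undefined")
    joint = _contingency(gene_bins, labels)
    n = labels.size
    h = 0.0
    for row in joint:  # one x state per row
        nx = row.sum()
        if nx == 0:
            continue
        p_y_given_x = row[row > 0] / nx
        h += (nx / n) * float(-(p_y_given_x * np.log(p_y_given_x)).sum() / _LOG2)
    return h


def _contingency(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((xi.max() + 1, yi.max() + 1), dtype=float)
    np.add.at(joint, (xi, yi), 1.0)
    return joint


def discretize(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency binning of a real vector into at most n_bins levels.

    Bin edges are interior quantiles; tied values collapse bins, so a
    constant vector yields a single level.
    """
    values = np.asarray(values, dtype=float)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    edges = np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, values, side="right")


def mutual_information(
    gene_values: np.ndarray, labels: np.ndarray, n_bins: int = 10
) -> float:
    """Plug-in MI between a (discretized) gene and the label, in bits.

    Computed as H(Y) - H(Y | X_binned) and clamped at zero against
    floating-point underflow. A constant gene scores exactly 0.
    """
    gene_values = np.asarray(gene_values, dtype=float)
    labels = np.asarray(labels)
    if gene_values.shape != labels.shape:
        raise ValueError("gene_values and labels must have equal length")
    bins = discretize(gene_values, n_bins)
    mi = entropy(labels) - conditional_entropy(bins, labels)
    return max(mi, 0.0)


def rank_and_filter(dataset: ExpressionDataset, config: FilterConfig) -> MIRanking:
    """Score, rank, truncate to top-k, and remove redundant genes.

    Ranking is by descending MI with lexicographic gene-id tie-break (fully
    deterministic across platforms). Redundancy removal scans the top-k in
    rank order and drops any gene whose absolute Pearson correlation with a
    previously retained gene is >= the threshold, recording the retained
    partner; it runs after truncation, so the surviving pool may hold fewer
    than k genes.
    """
    k = config.k
    if k > dataset.n_genes:
        warnings.warn(
            f"k={k} exceeds the {dataset.n_genes} genes available; clamping",
            stacklevel=2,
        )
        k = dataset.n_genes

    scores = {
        g: mutual_information(dataset.values[:, j], dataset.labels, config.n_bins)
        for j, g in enumerate(dataset.gene_ids)
    }
    order = sorted(scores, key=lambda g: (-scores[g], g))
    top_k = order[:k]

    col = {g: j for j, g in enumerate(dataset.gene_ids)}
    retained: list[str] = []
    dropped: list[tuple[str, str, float]] = []
    for g in top_k:
        partner = None
        corr_val = 0.0
        for r in retained:
            c = _pearson(dataset.values[:, col[g]], dataset.values[:, col[r]])
            if abs(c) >= config.redundancy_threshold:
                partner, corr_val = r, c
                break
        if partner is None:
            retained.append(g)
        else:
            dropped.append((g, partner, corr_val))

    kept = GeneSubset(retained, source_stage="filter")
    return MIRanking(scores=scores, order=order, kept=kept, dropped_redundant=dropped)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation; 0 when either vector is constant."""
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        return 0.0
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


def ranking_to_rows(ranking: MIRanking) -> list[tuple[str, float, int, bool, str]]:
    """Flatten a ranking for TSV emission.

    Returns (gene_id, mi, rank, kept_flag, redundant_partner) per gene in
    rank order; partner is empty unless the gene was dropped as redundant.
    """
    kept = set(ranking.kept.gene_ids)
    partner = {g: r for g, r, _ in ranking.dropped_redundant}
    return [
        (g, ranking.scores[g], rank, g in kept, partner.get(g, ""))
        for rank, g in enumerate(ranking.order, start=1)
    ]
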