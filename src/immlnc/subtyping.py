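"""Consensus clustering of samples, ssGSEA scoring and group comparisons.

Consensus clustering follows the resampling scheme of Monti et al.: for each
candidate cluster number k, samples are repeatedly subsampled (80% without
replacement) and partitioned by k-means; the consensus matrix records how
often two samples co-cluster among the resamples where both were drawn.
Cluster stability per k is summarized by the proportion of ambiguous
clustering (PAC) — the mass of consensus values falling strictly between
0.1 and 0.9 — and the k with minimal PAC is selected.  Final labels come
from average-linkage hierarchical clustering of 1 - consensus.

ssGSEA scores one sample at a time from within-sample expression ranks, so
they are invariant to any strictly monotone transform of the expression
values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import AgglomerativeClustering, KMeans

from .iodata import GeneSetCollection
from .lncres import fdr_adjust

PAC_LOWER = 0.1
PAC_UPPER = 0.9


@dataclass
class ConsensusResult:
    """Per-k consensus matrices, hard labels, PAC values and the selected k."""

    k_grid: list[int]
    consensus: dict[int, np.ndarray]
    labels: dict[int, np.ndarray]
    stability: dict[int, float]   # PAC per k; lower = more stable
    k_opt: int
    sample_ids: list[str]


def consensus_cluster(
    matrix: pd.DataFrame,
    k_range=range(2, 10),
    n_resamples: int = 1000,
    subsample_frac: float = 0.8,
    seed: int = 0,
) -> ConsensusResult:
    """Consensus-cluster samples (columns of a lncRNA x sample matrix).

    Rows are z-scored before clustering.  Raises if any k < 2, if the input
    has fewer than 2 feature rows, if samples are all identical, or if more
    than 1% of sample pairs were never co-subsampled.
    """
    k_range = list(k_range)
    if any(k < 2 for k in k_range):
        raise ValueError("k_range must contain only k >= 2")
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 features (lncRNAs) to cluster")
    n = matrix.shape[1]
    if n < max(k_range) * 3:
        raise ValueError("need at least 3 samples per candidate cluster")

    x = matrix.to_numpy(dtype=float)
    sd = x.std(axis=1, keepdims=True)
    if np.all(sd == 0):
        raise ValueError("all features are constant; samples are indistinguishable")
    x = (x - x.mean(axis=1, keepdims=True)) / np.where(sd == 0, 1.0, sd)
    points = x.T  # samples as observations

    rng = np.random.default_rng(seed)
    n_sub = max(2, int(round(subsample_frac * n)))
    consensus: dict[int, np.ndarray] = {}
    labels: dict[int, np.ndarray] = {}
    stability: dict[int, float] = {}

    for k in k_range:
        co = np.zeros((n, n))
        both = np.zeros((n, n))
        for _ in range(n_resamples):
            idx = rng.choice(n, size=n_sub, replace=False)
            km = KMeans(n_clusters=k, n_init=10, random_state=int(rng.integers(2**31)))
            assign = km.fit_predict(points[idx])
            ind = np.zeros((n, k))
            ind[idx, assign] = 1.0
            co += ind @ ind.T
            drawn = np.zeros(n)
            drawn[idx] = 1.0
            both += np.outer(drawn, drawn)
        never = (both == 0).sum() - n  # off-diagonal pairs never co-drawn
        if never > 0.01 * n * (n - 1):
            raise ValueError("more than 1% of sample pairs were never co-subsampled")
        with np.errstate(invalid="ignore"):
            cons = np.where(both > 0, co / np.where(both == 0, 1.0, both), 0.0)
        np.fill_diagonal(cons, 1.0)
        cons = (cons + cons.T) / 2.0
        consensus[k] = cons
        off = cons[np.triu_indices(n, k=1)]
        stability[k] = float(np.mean((off > PAC_LOWER) & (off < PAC_UPPER)))
        hier = AgglomerativeClustering(n_clusters=k, metric="precomputed", linkage="average")
        lab = hier.fit_predict(1.0 - cons)
        labels[k] = _canonical_labels(lab)

    k_opt = min(k_range, key=lambda k: (stability[k], k))
    return ConsensusResult(
        k_grid=k_range,
        consensus=consensus,
        labels=labels,
        stability=stability,
        k_opt=k_opt,
        sample_ids=list(matrix.columns),
    )


def _canonical_labels(lab: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..k in order of first appearance (deterministic)."""
    mapping: dict[int, int] = {}
    out = np.empty_like(lab)
    for i, v in enumerate(lab):
        if v not in mapping:
            mapping[v] = len(mapping) + 1
        out[i] = mapping[v]
    return out


# ---------------------------------------------------------------------------
# ssGSEA
# ---------------------------------------------------------------------------

def ssgsea_score(expr_column: pd.Series, gene_set, alpha: float = 0.25) -> float:
    """Single-sample GSEA score of one gene set in one sample.

    Genes are sorted by expression (descending; ties broken by position for
    determinism) and assigned rank values N..1.  The score is the sum over
    positions of the difference between the rank-weighted in-set ECDF
    (weights ``rank^alpha``) and the unweighted out-of-set ECDF.  Only ranks
    enter, so any strictly monotone transform of expression leaves the score
    unchanged.
    """
    values = expr_column.to_numpy(dtype=float)
    n = len(values)
    in_set = np.asarray(expr_column.index.isin(set(gene_set)), dtype=float)
    n_i = int(in_set.sum())
    if n_i == 0:
        raise ValueError("gene set does not intersect the expressed genes")
    if n_i == n:
        raise ValueError("gene set covers all genes; out-of-set ECDF undefined")
    order = np.lexsort((np.arange(n), -values))  # stable descending
    in_sorted = in_set[order]
    rank_values = np.arange(n, 0, -1, dtype=float)
    w = rank_values**alpha
    hit = np.cumsum(w * in_sorted) / float((w * in_sorted).sum())
    miss = np.cumsum(1.0 - in_sorted) / float(n - n_i)
    return float(np.sum(hit - miss))


def score_all(
    expr: pd.DataFrame, sets: GeneSetCollection, alpha: float = 0.25
) -> pd.DataFrame:
    """ssGSEA scores for every sample (rows) x gene set (columns)."""
    out = {}
    for name, members in sets.sets.items():
        out[name] = [
            ssgsea_score(expr[c], members, alpha=alpha) for c in expr.columns
        ]
    return pd.DataFrame(out, index=expr.columns)


# ---------------------------------------------------------------------------
# Group comparisons and the DE screen
# ---------------------------------------------------------------------------

def compare_groups(values_by_group) -> tuple[float, float]:
    """Two-sided rank test across groups.

    Wilcoxon rank-sum for two groups (exact when sample sizes permit),
    Kruskal–Wallis for more.  Each group needs at least 3 observations.
    """
    groups = [np.asarray(g, dtype=float) for g in values_by_group]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(groups):
        if len(g) < 3:
            raise ValueError(f"group {i} has fewer than 3 samples")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    if len(groups) == 2:
        res = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    res = stats.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def de_screen(
    expr: pd.DataFrame,
    group_a_mask: pd.Series,
    p_thresh: float = 0.01,
    lfc_thresh: float = 1.0,
) -> pd.DataFrame:
    """Two-group differential expression on log2-scale values.

    ``group_a_mask`` is a boolean Series over the columns of ``expr``.
    log2FC is the mean difference (A - B) on the log2 scale; p comes from a
    two-sided rank-sum test per gene, adjusted by BH.  ``passed`` requires
    both p < ``p_thresh`` and |log2FC| > ``lfc_thresh``.
    """
    group_a_mask = group_a_mask.reindex(expr.columns)
    if group_a_mask.isna().any():
        raise ValueError("group mask does not cover all samples")
    a = expr.loc[:, group_a_mask.astype(bool)]
    b = expr.loc[:, ~group_a_mask.astype(bool)]
    if a.shape[1] < 3 or b.shape[1] < 3:
        raise ValueError("both groups need at least 3 samples")
    lfc = a.mean(axis=1) - b.mean(axis=1)
    res = stats.mannwhitneyu(
        a.to_numpy(), b.to_numpy(), axis=1, alternative="two-sided"
    )
    pvals = np.asarray(res.pvalue, dtype=float)
    qvals = fdr_adjust(pvals)
    table = pd.DataFrame(
        {"log2fc": lfc, "pval": pvals, "qval": qvals}, index=expr.index
    )
    table["passed"] = (table["pval"] < p_thresh) & (table["log2fc"].abs() > lfc_thresh)
    return table
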