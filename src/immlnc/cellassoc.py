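"""Hypergeometric association of candidate lncRNAs with immune-cell types.

Each candidate lncRNA contributes the set of mRNAs significantly correlated
with it (after purity adjustment).  For each of the 24 immune-cell marker
sets, the overlap ``k`` between those mRNAs and the cell's ``M`` markers is
tested against the upper tail of a hypergeometric distribution over the
marker universe of ``N`` genes (2025 in the reference marker collection):

    P[X >= k],  X ~ Hypergeometric(N, M, n)

where ``n`` is the lncRNA's significant mRNA count inside the universe.
A lncRNA is "immune-disorder related" when at least one cell type reaches
``k >= 3`` overlapping markers at ``p < 0.05``.  Overlaps below three
markers are never called significant regardless of p.
"""

from __future__ import annotations

import logging
import warnings

import pandas as pd
from scipy.stats import hypergeom

from .iodata import GeneSetCollection
from .lncres import CorrelationStats, fdr_adjust

logger = logging.getLogger("immlnc")


def significant_mrnas(
    lnc_id: str,
    corr: CorrelationStats,
    alpha: float = 0.05,
    use_fdr: bool = True,
    restrict_to: set[str] | None = None,
) -> set[str]:
    """mRNAs whose (BH-adjusted, by default) correlation p with ``lnc_id`` < alpha.

    ``restrict_to`` limits both the tested genes and the multiple-testing
    family to a universe (e.g. the marker universe), so that overlap counts
    and the hypergeometric urn refer to the same gene population.
    """
    if lnc_id not in corr.pval.index:
        raise KeyError(f"unknown lncRNA id {lnc_id!r}")
    pvals = corr.pval.loc[lnc_id]
    if restrict_to is not None:
        pvals = pvals.loc[pvals.index.intersection(restrict_to)]
    if use_fdr:
        adjusted = pd.Series(fdr_adjust(pvals.to_numpy()), index=pvals.index)
    else:
        adjusted = pvals
    return set(adjusted.index[adjusted < alpha])


def hypergeom_tail(k: int, n: int, m_markers: int, n_universe: int) -> float:
    """Upper-tail ``P[X >= k]`` for X ~ Hypergeometric(N, M, n)."""
    if not (0 <= k <= min(n, m_markers)):
        raise ValueError(f"inconsistent overlap: k={k}, n={n}, M={m_markers}")
    if not (0 <= m_markers <= n_universe and 0 <= n <= n_universe):
        raise ValueError("marker or draw count exceeds the universe")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, n_universe, m_markers, n))


def associate_cells(
    candidates,
    corr: CorrelationStats,
    markers: GeneSetCollection,
    alpha: float = 0.05,
    use_fdr: bool = True,
    p_thresh: float = 0.05,
    min_overlap: int = 3,
    restrict_to_universe: bool = True,
) -> tuple[pd.DataFrame, set[str]]:
    """Test every candidate lncRNA against every immune-cell marker set.

    Returns the per-(lncRNA, cell) record table (columns ``lnc_id``,
    ``cell_type``, ``k``, ``n``, ``M``, ``N``, ``pval``, ``flagged``) and the
    set of lncRNAs flagged immune-disorder related.
    """
    if len(markers) == 0:
        raise ValueError("marker collection is empty")
    universe = markers.universe()
    n_universe = markers.universe_size
    rows = []
    flagged: set[str] = set()
    for lnc_id in candidates:
        sig = significant_mrnas(
            lnc_id, corr, alpha=alpha, use_fdr=use_fdr,
            restrict_to=universe if restrict_to_universe else None,
        )
        sig_in_universe = sig & universe
        n = len(sig_in_universe)
        for cell, members in markers.sets.items():
            m = len(members)
            k = len(sig_in_universe & set(members))
            p = hypergeom_tail(k, n, m, n_universe)
            hit = (k >= min_overlap) and (p < p_thresh)
            if hit:
                flagged.add(lnc_id)
            rows.append((lnc_id, cell, k, n, m, n_universe, p, hit))
    table = pd.DataFrame(
        rows, columns=["lnc_id", "cell_type", "k", "n", "M", "N", "pval", "flagged"]
    )
    return table, flagged


def intersect_candidates(immune_lncs, disorder_lncs) -> list[str]:
    """Sorted intersection of the enrichment-screen and marker-screen sets."""
    out = sorted(set(immune_lncs) & set(disorder_lncs))
    if not out:
        warnings.warn("intersect_candidates: the two screens share no lncRNAs")
    return out
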