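"""Pathway pre-selection: which pathways does the treatment touch?

Connectivity is only scored inside pathways the treatment plausibly
affects. Two selection modes are provided:

* ``hypergeometric`` — over-representation of the thresholded DE set
  (up + down tags) in each pathway, one-sided upper tail;
* ``ks_permutation`` — the signed KS statistic of the pathway's members
  against the full differential ranking, with a gene-label permutation
  null (random same-size gene subsets), two-sided on |KS|.

A single pre/post pair admits no sample-label permutation, so the
rank-based mode uses gene-label permutation; it is the default because it
uses the whole ranking rather than only the thresholded tags. Pathways
with permutation p < alpha (strict) are selected; no multiple-testing
correction is applied by default, with an optional Benjamini-Hochberg
flag for more conservative gating.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .connectivity import PermutationNullCache, ks_statistic
from .containers import DifferentialRanking, PathwayCollection, TagSignature

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "hypergeometric_enrichment",
    "ks_permutation_enrichment",
    "select_pathways",
]


@dataclass
class EnrichmentResult:
    pathway: str
    method: str
    statistic: float
    p_value: float
    n_pathway_genes_in_universe: int
    n_de_in_pathway: int

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p_value outside [0, 1]")
        if self.n_de_in_pathway > self.n_pathway_genes_in_universe:
            raise ValueError("overlap exceeds pathway size in universe")


def hypergeometric_enrichment(
    sig: TagSignature,
    pathways: PathwayCollection,
    universe,
) -> list[EnrichmentResult]:
    """One-sided over-representation test of the DE tag set per pathway.

    With M universe genes, n DE genes and K pathway genes in the universe,
    the p-value is P(X >= k) for the observed overlap k under the
    hypergeometric null. Pathways disjoint from the universe are skipped.
    An empty DE set yields p = 1 everywhere (with a warning).
    """
    universe = set(universe)
    de = (set(sig.up_genes) | set(sig.down_genes)) & universe
    if not de:
        logger.warning("hypergeometric_enrichment: empty DE set; all p = 1")
    m_total = len(universe)
    results = []
    for name, genes in pathways.items():
        in_universe = genes & universe
        big_k = len(in_universe)
        if big_k == 0:
            logger.info("pathway %r disjoint from universe; skipped", name)
            continue
        k = len(de & in_universe)
        p = float(hypergeom.sf(k - 1, m_total, len(de), big_k)) if de else 1.0
        results.append(
            EnrichmentResult(
                pathway=name,
                method="hypergeometric",
                statistic=float(k),
                p_value=min(p, 1.0),
                n_pathway_genes_in_universe=big_k,
                n_de_in_pathway=k,
            )
        )
    return results


def ks_permutation_enrichment(
    r: DifferentialRanking,
    pathways: PathwayCollection,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Rank-based enrichment with a gene-label permutation null.

    Each pathway's members (restricted to the measured universe) are
    treated as a single tag group against the full differential ranking;
    the null re-draws same-size random gene subsets. p-values carry the
    +1 correction and identical seeds give identical results.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rank = r.rank_of()
    n_total = len(r)
    cache = PermutationNullCache(seed=seed, n_perm=n_perm)
    results = []
    for name, genes in pathways.items():
        positions = sorted(rank[g] for g in genes if g in rank)
        t = len(positions)
        if t == 0:
            logger.info("pathway %r has no measured genes; skipped", name)
            continue
        stat = ks_statistic(positions, n_total)
        null = cache.single_group(n_total, t)
        p = (1 + int(np.sum(null >= abs(stat) - 1e-12))) / (n_perm + 1)
        results.append(
            EnrichmentResult(
                pathway=name,
                method="ks_permutation",
                statistic=stat,
                p_value=p,
                n_pathway_genes_in_universe=t,
                n_de_in_pathway=t,
            )
        )
    return results


def select_pathways(
    results: list[EnrichmentResult],
    pathways: PathwayCollection,
    alpha: float = 0.05,
    fdr: bool = False,
) -> PathwayCollection:
    """Keep pathways with p < alpha (strict), preserving collection order.

    With ``fdr=True`` the Benjamini-Hochberg adjusted p-values are gated
    instead of the raw ones. ``alpha=0`` selects nothing; ``alpha>=1``
    selects every tested pathway.
    """
    if not 0 <= alpha:
        raise ValueError("alpha must be >= 0")
    if not results:
        return PathwayCollection()
    if alpha >= 1:
        return pathways.subset({res.pathway for res in results})
    pvals = np.array([res.p_value for res in results])
    if fdr:
        from statsmodels.stats.multitest import multipletests

        pvals = multipletests(pvals, method="fdr_bh")[1]
    selected = {res.pathway for res, p in zip(results, pvals) if p < alpha}
    return pathways.subset(selected)
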