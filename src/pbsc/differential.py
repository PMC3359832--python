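"""Paired differential expression: fold-change ranking and tag signatures.

One patient contributes a single pre-treatment / post-treatment sample
pair, so the per-gene effect is the plain difference of log2 intensities
(post minus pre). Genes are ranked by that log2 fold change and the tag
signature is the set of genes beyond a fold-change threshold, split into
up- and down-regulated lists.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import DifferentialRanking, ExpressionMatrix, TagSignature

logger = logging.getLogger(__name__)

__all__ = ["paired_log2fc", "tag_signature"]


def paired_log2fc(m: ExpressionMatrix, patient: str) -> DifferentialRanking:
    """Rank genes by post-minus-pre log2 fold change for one patient.

    The matrix must already hold log2 intensities. Ordering is descending
    log2FC with ties broken by gene id, so the ranking is strict and
    reproducible.
    """
    if patient not in m.pair_map:
        raise KeyError(f"unknown patient {patient!r}; known: {sorted(m.pair_map)}")
    pre_id, post_id = m.pair_map[patient]
    fc = (m.data[post_id] - m.data[pre_id]).to_numpy(dtype=float)
    genes = np.asarray(m.gene_ids, dtype=object)
    order = np.lexsort((genes, -fc))
    return DifferentialRanking(genes=genes[order], log2fc=fc[order])


def tag_signature(r: DifferentialRanking, fold_threshold: float = 2.0) -> TagSignature:
    """Threshold a ranking into up/down tag gene lists.

    ``fold_threshold`` is linear-scale; genes with log2FC >= log2(threshold)
    go to ``up_genes`` and log2FC <= -log2(threshold) to ``down_genes``
    (boundaries inclusive), each ordered by decreasing |log2FC|.
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must be > 1")
    cut = np.log2(fold_threshold)
    up_mask = r.log2fc >= cut
    dn_mask = r.log2fc <= -cut
    up = list(r.genes[up_mask])  # ranking is descending -> already |fc| desc
    dn = list(r.genes[dn_mask][::-1])
    if not up and not dn:
        logger.warning(
            "tag_signature: no gene passes the %g-fold threshold; "
            "downstream scoring will be skipped",
            fold_threshold,
        )
    return TagSignature(up_genes=up, down_genes=dn, fold_threshold=fold_threshold)
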