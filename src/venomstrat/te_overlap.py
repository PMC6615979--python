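"""Transposable-element / gene-model interval intersection.

Overlap is computed against the full gene span (exons plus introns); the
region label records whether the TE falls in exonic sequence, intronic
sequence, or straddles the boundary.  Strand is ignored throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Set

from intervaltree import IntervalTree

from .formats_io import GeneModel, TEAnnotation

logger = logging.getLogger(__name__)

REGION_EXON = "exon"
REGION_INTRON = "intron"
REGION_BOTH = "both"


@dataclass(frozen=True)
class TEHit:
    gene_id: str
    te_class: str
    te_family: str
    region: str
    overlap_bp: int


def _intersection(a, b) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def annotate_te(
    genes: Sequence[GeneModel],
    tes: Sequence[TEAnnotation],
    min_overlap_bp: int = 1,
) -> List[TEHit]:
    """One :class:`TEHit` per (gene, TE) pair overlapping by >= *min_overlap_bp*.

    Nested or overlapping TE records are not merged: each input record can
    contribute its own hit.  Hits are sorted by (gene_id, TE position).
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    trees: Dict[str, IntervalTree] = {}
    for gene in genes:
        trees.setdefault(gene.seq_id, IntervalTree())[gene.span[0]:gene.span[1]] = gene

    hits: List[TEHit] = []
    for te in tes:
        tree = trees.get(te.seq_id)
        if tree is None:
            continue
        for iv in tree.overlap(te.interval[0], te.interval[1]):
            gene: GeneModel = iv.data
            overlap = _intersection(te.interval, gene.span)
            if overlap < min_overlap_bp:
                continue
            exon_bp = sum(_intersection(te.interval, e) for e in gene.exons)
            intron_bp = sum(_intersection(te.interval, i) for i in gene.introns)
            if exon_bp and intron_bp:
                region = REGION_BOTH
            elif exon_bp:
                region = REGION_EXON
            else:
                region = REGION_INTRON
            hits.append(
                TEHit(
                    gene_id=gene.gene_id,
                    te_class=te.te_class,
                    te_family=te.te_family,
                    region=region,
                    overlap_bp=overlap,
                )
            )
    hits.sort(key=lambda h: (h.gene_id, h.te_class, h.te_family, -h.overlap_bp))
    return hits


@dataclass
class TESummary:
    n_genes_with_te: int
    genes_per_class: Dict[str, int]  # TE class -> number of distinct genes
    n_hits: int


def summarize_te(hits: Iterable[TEHit], gene_set: Set[str]) -> TESummary:
    """Count distinct genes of *gene_set* with >= 1 TE, overall and per class."""
    hits = [h for h in hits if h.gene_id in gene_set]
    genes = {h.gene_id for h in hits}
    per_class: Dict[str, Set[str]] = {}
    for h in hits:
        per_class.setdefault(h.te_class, set()).add(h.gene_id)
    return TESummary(
        n_genes_with_te=len(genes),
        genes_per_class={cls: len(g) for cls, g in sorted(per_class.items())},
        n_hits=len(hits),
    )
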