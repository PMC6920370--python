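"""De novo CNV detection from pre-called per-sample segment tables.

Segments arrive pre-called (read-depth CNV calling is upstream and out of
scope).  A child segment is inherited when a parental segment of the same
state (loss vs. gain) matches it under reciprocal overlap — both
overlap/len(child) and overlap/len(parent) at or above a threshold (0.5 by
default) — and de novo otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .variants import CNVSegment, GeneInterval


@dataclass
class DenovoCNVCall:
    segment: CNVSegment
    inherited_from: str  # "none", "mother", "father", or "both"
    best_parental_overlap: float
    genes: list[str] = field(default_factory=list)

    @property
    def is_de_novo(self) -> bool:
        return self.inherited_from == "none"


def reciprocal_overlap(a: CNVSegment, b: CNVSegment) -> float:
    """min(overlap/len(a), overlap/len(b)); 0 when disjoint or on different
    chromosomes."""
    ov = a.overlap(b)
    if ov == 0:
        return 0.0
    return min(ov / a.length, ov / b.length)


def _best_match(child: CNVSegment, parent_segs: Sequence[CNVSegment]) -> float:
    best = 0.0
    for seg in parent_segs:
        if seg.state is not child.state:
            continue
        best = max(best, reciprocal_overlap(child, seg))
    return best


def denovo_segments(
    child_segs: Sequence[CNVSegment],
    mother_segs: Sequence[CNVSegment],
    father_segs: Sequence[CNVSegment],
    min_reciprocal_overlap: float = 0.5,
    genes: Iterable[GeneInterval] | None = None,
) -> list[DenovoCNVCall]:
    """Classify each child segment as de novo or inherited.

    A segment is de novo iff no same-state parental segment reaches the
    reciprocal-overlap threshold in either parent.  When ``genes`` is given,
    overlapped gene symbols are attached to each call.
    """
    if not (0.0 < min_reciprocal_overlap <= 1.0):
        raise ValueError("min_reciprocal_overlap must be in (0, 1]")
    gene_list = list(genes) if genes is not None else None
    calls = []
    for seg in child_segs:
        from_mother = _best_match(seg, mother_segs)
        from_father = _best_match(seg, father_segs)
        m_ok = from_mother >= min_reciprocal_overlap
        f_ok = from_father >= min_reciprocal_overlap
        if m_ok and f_ok:
            origin = "both"
        elif m_ok:
            origin = "mother"
        elif f_ok:
            origin = "father"
        else:
            origin = "none"
        calls.append(
            DenovoCNVCall(
                segment=seg,
                inherited_from=origin,
                best_parental_overlap=max(from_mother, from_father),
                genes=segment_genes(seg, gene_list) if gene_list is not None else [],
            )
        )
    return calls


def segment_genes(seg: CNVSegment, genes: Iterable[GeneInterval]) -> list[str]:
    """Symbols of genes overlapping the segment by >= 1 bp, coordinate-sorted
    (half-open coordinates: a gene abutting the segment end is excluded)."""
    trees: dict[str, IntervalTree] = {}
    ordered: list[GeneInterval] = sorted(genes, key=lambda g: (g.chrom, g.start, g.end))
    for g in ordered:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)
    tree = trees.get(seg.chrom)
    if tree is None:
        return []
    hits = sorted((iv.data for iv in tree.overlap(seg.start, seg.end)),
                  key=lambda g: (g.start, g.end, g.symbol))
    return [g.symbol for g in hits]
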