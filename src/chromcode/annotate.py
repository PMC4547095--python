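"""Attach regions to genes and genomic context.

Nearest-gene assignment uses the region midpoint against every TSS on the
region's chromosome; distances are strand-oriented (upstream of the TSS is
negative). The promoter window is [TSS-1000, TSS+100) in oriented
coordinates, a HOMER-like convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trackio import GeneModel, GenomicInterval, PeakSet

PROMOTER_WINDOW = (-1000, 100)  # oriented bp relative to TSS
GENE_BODY_START = 250  # oriented bp downstream of TSS


@dataclass(frozen=True)
class AnnotatedRegion:
    region: GenomicInterval
    gene_id: str | None
    tss_distance: float  # signed, strand-oriented; inf when chromosome has no gene
    context: str  # promoter | exon | intron | intergenic


class _TssIndex:
    """Per-chromosome sorted TSS arrays for vectorized nearest lookups."""

    def __init__(self, genes: list[GeneModel]):
        if not genes:
            raise ValueError("no genes supplied")
        self.genes = genes
        self.by_chrom: dict[str, tuple[np.ndarray, list[GeneModel]]] = {}
        per_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            per_chrom.setdefault(g.chrom, []).append(g)
        for chrom, gs in per_chrom.items():
            # sort by (tss, gene_id) so the documented tie-break (lower
            # gene_id) falls out of taking the first minimizer
            gs = sorted(gs, key=lambda g: (g.tss, g.gene_id))
            self.by_chrom[chrom] = (np.array([g.tss for g in gs]), gs)

    def nearest(self, chrom: str, pos: int) -> GeneModel | None:
        if chrom not in self.by_chrom:
            return None
        tss, gs = self.by_chrom[chrom]
        i = int(np.searchsorted(tss, pos))
        best, best_d = None, None
        for j in (i - 1, i, i + 1):
            if 0 <= j < len(gs):
                d = abs(int(tss[j]) - pos)
                if best is None or d < best_d or (d == best_d and gs[j].gene_id < best.gene_id):
                    best, best_d = gs[j], d
        return best


def oriented_offset(gene: GeneModel, pos: int) -> int:
    """Position of ``pos`` relative to the TSS in the gene's reading direction."""
    return pos - gene.tss if gene.strand == "+" else gene.tss - pos


def oriented_window(gene: GeneModel, lo: int, hi: int) -> GenomicInterval | None:
    """Genomic half-open span covering oriented offsets ``[lo, hi)``.

    Clipped at the chromosome origin; ``None`` if nothing remains.
    """
    if gene.strand == "+":
        start, end = gene.tss + lo, gene.tss + hi
    else:
        start, end = gene.tss - hi + 1, gene.tss - lo + 1
    start = max(start, 0)
    if end <= start:
        return None
    return GenomicInterval(gene.chrom, start, end)


def nearest_tss(
    region: GenomicInterval, genes: list[GeneModel] | _TssIndex
) -> tuple[str | None, float]:
    """Gene whose TSS is closest to the region midpoint, plus signed distance.

    Ties at equal |distance| go to the lexicographically smaller gene id.
    Returns ``(None, inf)`` when the region's chromosome carries no gene;
    raises if the gene list itself is empty.
    """
    index = genes if isinstance(genes, _TssIndex) else _TssIndex(genes)
    gene = index.nearest(region.chrom, region.midpoint)
    if gene is None:
        return None, float("inf")
    return gene.gene_id, float(oriented_offset(gene, region.midpoint))


def classify_context(
    region: GenomicInterval,
    genes: list[GeneModel],
    promoter_window: tuple[int, int] = PROMOTER_WINDOW,
) -> str:
    """promoter > exon > intron > intergenic, decided by the region midpoint."""
    mid = region.midpoint
    in_exon = in_gene = False
    for g in genes:
        if g.chrom != region.chrom:
            continue
        off = oriented_offset(g, mid)
        if promoter_window[0] <= off < promoter_window[1]:
            return "promoter"
        if g.interval.start <= mid < g.interval.end:
            in_gene = True
            if any(e.start <= mid < e.end for e in g.exons):
                in_exon = True
    if in_exon:
        return "exon"
    if in_gene:
        return "intron"
    return "intergenic"


def annotate_regions(
    regions: list[GenomicInterval],
    genes: list[GeneModel],
    promoter_window: tuple[int, int] = PROMOTER_WINDOW,
) -> list[AnnotatedRegion]:
    index = _TssIndex(genes)
    return [
        AnnotatedRegion(
            r, *nearest_tss(r, index), classify_context(r, genes, promoter_window)
        )
        for r in regions
    ]


def peak_gene_map(peaks: PeakSet, genes: list[GeneModel]) -> dict[str, int]:
    """Number of peaks whose nearest gene is each gene (absent = 0)."""
    index = _TssIndex(genes)
    out: dict[str, int] = {}
    for p in peaks.peaks:
        gid, _ = nearest_tss(p.interval, index)
        if gid is not None:
            out[gid] = out.get(gid, 0) + 1
    return out


def link_hairy_bound(
    regions: list[GenomicInterval],
    hairy_peaks: PeakSet,
    genes: list[GeneModel],
) -> list[bool]:
    """Flag each region bound iff its nearest gene carries >= 1 Hairy peak."""
    bound_genes = set(peak_gene_map(hairy_peaks, genes))
    index = _TssIndex(genes)
    return [nearest_tss(r, index)[0] in bound_genes for r in regions]


def classify_polII_change(
    gene: GeneModel,
    polII_decrease_blocks: list[GenomicInterval],
    promoter_window: tuple[int, int] = PROMOTER_WINDOW,
) -> str:
    """Where Pol II occupancy dropped on a gene.

    promoter = oriented [TSS-1000, TSS+100); body = oriented [TSS+250, gene
    end). Category reflects which of the two overlaps >= 1 decrease block:
    ``promoter_only`` / ``body_only`` / ``both`` / ``none``.
    """
    promoter = oriented_window(gene, *promoter_window)
    body_len = gene.interval.width - GENE_BODY_START
    body = oriented_window(gene, GENE_BODY_START, gene.interval.width) if body_len > 0 else None
    hit_prom = promoter is not None and any(
        promoter.overlaps(b) for b in polII_decrease_blocks
    )
    hit_body = body is not None and any(body.overlaps(b) for b in polII_decrease_blocks)
    if hit_prom and hit_body:
        return "both"
    if hit_prom:
        return "promoter_only"
    if hit_body:
        return "body_only"
    return "none"
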