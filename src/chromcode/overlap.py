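"""Co-occurrence statistics for region sets and gene sets.

Two regions co-occur when they share at least 1 bp (half-open coordinates:
[100,200) and [199,300) overlap; [100,200) and [200,300) do not). The
significance of co-occurrence is a natural-log hypergeometric tail with a
sign convention: enrichment (observed >= expected) is reported <= 0,
depletion/divergence > 0.

For region-level tests the hypergeometric universe size N is modelled as
``genome_length / mean width of the pooled region sets`` — a
"places on the genome" slot count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .trackio import GenomicInterval


@dataclass(frozen=True)
class OverlapResult:
    n_a: int
    n_b: int
    n_overlap: int
    universe_n: int
    signed_ln_p: float


def merge_intervals(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals as sorted disjoint spans (touching spans coalesce)."""
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda x: (x.chrom, x.start)):
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = GenomicInterval(iv.chrom, merged[-1].start, iv.end)
        else:
            merged.append(iv)
    return merged


def count_overlaps(
    set_a: list[GenomicInterval], set_b: list[GenomicInterval]
) -> int:
    """Number of A-regions sharing >= 1 bp with any B-region (A counted once)."""
    if not set_a or not set_b:
        return 0
    grouped: dict[str, list[GenomicInterval]] = {}
    for iv in merge_intervals(set_b):
        grouped.setdefault(iv.chrom, []).append(iv)
    by_chrom = {
        chrom: (
            np.array([iv.start for iv in ivs]),
            np.array([iv.end for iv in ivs]),
        )
        for chrom, ivs in grouped.items()
    }
    n = 0
    for a in set_a:
        if a.chrom not in by_chrom:
            continue
        starts, ends = by_chrom[a.chrom]
        # candidate: last merged B with start < a.end
        i = int(np.searchsorted(starts, a.end, side="left")) - 1
        if i >= 0 and ends[i] > a.start:
            n += 1
    return n


def hypergeom_signed_ln_p(k: int, K: int, n: int, N: int) -> float:
    """Signed natural-log hypergeometric tail for k overlaps of K among n in N.

    Returns ``ln P(X >= k)`` (<= 0) when k is at or above the expectation
    K*n/N, else ``-ln P(X <= k)`` (>= 0, divergence). Computed in log space;
    stable for N up to ~1e6.
    """
    if not (0 <= k <= min(K, n) <= N) or min(K, n) < 0 or k < n + K - N:
        raise ValueError(f"invalid counts k={k}, K={K}, n={n}, N={N}")
    if N == 0:
        return 0.0
    expected = K * n / N
    if k >= expected:
        return float(stats.hypergeom.logsf(k - 1, N, K, n))
    return float(-stats.hypergeom.logcdf(k, N, K, n))


def region_universe_n(
    set_a: list[GenomicInterval],
    set_b: list[GenomicInterval],
    genome_length: int,
) -> int:
    pooled = list(set_a) + list(set_b)
    if not pooled:
        return 0
    mean_w = float(np.mean([iv.width for iv in pooled]))
    return max(int(round(genome_length / mean_w)), len(set_a) + len(set_b))


def region_set_overlap(
    set_a: list[GenomicInterval],
    set_b: list[GenomicInterval],
    genome_length: int,
) -> OverlapResult:
    """Hypergeometric co-occurrence of two region sets on a genome of slots."""
    k = count_overlaps(set_a, set_b)
    N = region_universe_n(set_a, set_b, genome_length)
    K, n = len(set_a), len(set_b)
    if N == 0 or K == 0 or n == 0:
        return OverlapResult(K, n, k, N, 0.0)
    k = min(k, K, n)
    return OverlapResult(K, n, k, N, hypergeom_signed_ln_p(k, K, n, N))


def gene_set_overlap(
    genes_a: set[str], genes_b: set[str], universe_genes: set[str]
) -> OverlapResult:
    """Standard gene-universe hypergeometric test, same sign convention."""
    genes_a, genes_b, universe = set(genes_a), set(genes_b), set(universe_genes)
    if not genes_a <= universe or not genes_b <= universe:
        raise ValueError("gene sets must be subsets of the universe")
    k = len(genes_a & genes_b)
    value = (
        0.0
        if not universe
        else hypergeom_signed_ln_p(k, len(genes_a), len(genes_b), len(universe))
    )
    return OverlapResult(len(genes_a), len(genes_b), k, len(universe), value)


def cooccurrence_matrix(
    blocks_by_category: dict[str, list[GenomicInterval]],
    genome_length: int,
) -> pd.DataFrame:
    """Pairwise signed ln p over {mark x direction} categories.

    ``count_overlaps`` is directed, so each cell is the mean of the two
    directed signed values — the matrix is symmetric by construction. The
    diagonal is self-enrichment; empty categories give zero rows.
    """
    cats = list(blocks_by_category)
    if len(cats) < 2:
        raise ValueError("need at least 2 categories")
    mat = pd.DataFrame(0.0, index=cats, columns=cats)
    for i, a in enumerate(cats):
        for b in cats[i:]:
            ab = region_set_overlap(
                blocks_by_category[a], blocks_by_category[b], genome_length
            ).signed_ln_p
            ba = region_set_overlap(
                blocks_by_category[b], blocks_by_category[a], genome_length
            ).signed_ln_p
            mat.loc[a, b] = mat.loc[b, a] = 0.5 * (ab + ba)
    return mat
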