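"""Variant-density enrichment scan for localizing hidden loci.

A pathogenic repeat expansion is invisible to SNV calling, but the ancestral
haplotype it rides on is not: rare variants in linkage disequilibrium with
the expansion co-segregate with the disease and pile up around the locus.
After segregation and frequency filtering, an unusual concentration of the
surviving variants on one chromosome — and within it, a density peak — points
at the hidden locus.

The scan formalizes this in two steps: a one-sided binomial test per
chromosome (observed count vs. the count expected if variants fell uniformly
in proportion to chromosome length) with Benjamini–Hochberg correction, then
a sliding-window count profile on each flagged chromosome.  The candidate
interval is the peak center +/- a half-width (1 Mb by default, the
"peak +/- 1 Mb" search convention), and genes overlapping it are ranked by
distance from the peak center.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .variants import GeneInterval

DEFAULT_WINDOW = 1_000_000
DEFAULT_STEP = 500_000
DEFAULT_HALF_WIDTH = 1_000_000


@dataclass
class ChromEnrichment:
    chrom: str
    n_variants: int
    expected: float
    p_value: float
    q_value: float
    flagged: bool


@dataclass
class DensityProfile:
    """Per-window counts on one chromosome."""

    chrom: str
    window_size: int
    step: int
    window_starts: np.ndarray
    window_counts: np.ndarray
    total: int


@dataclass
class EnrichedRegion:
    chrom: str
    peak_window: tuple[int, int]
    enriched_run: tuple[int, int]
    peak_center: int
    candidate_interval: tuple[int, int]
    n_variants_in_region: int
    p_value: float | None = None
    q_value: float | None = None


def chrom_enrichment(
    positions: Sequence[tuple[str, int]],
    chrom_lengths: Mapping[str, int],
    alpha: float = 0.05,
) -> list[ChromEnrichment]:
    """One-sided binomial enrichment test per chromosome, BH-corrected.

    Under the null, each variant lands on chromosome c with probability
    length(c) / genome length; a chromosome is flagged when its BH-adjusted
    q-value is below ``alpha``.  Returns one row per chromosome in
    ``chrom_lengths``, in that order.  Zero variants yields an empty list.
    """
    n_total = len(positions)
    if n_total == 0:
        import warnings

        warnings.warn("chrom_enrichment called with zero variants", stacklevel=2)
        return []
    genome = float(sum(chrom_lengths.values()))
    counts: dict[str, int] = {c: 0 for c in chrom_lengths}
    for chrom, _pos in positions:
        if chrom in counts:
            counts[chrom] += 1
    chroms = list(chrom_lengths)
    pvals = []
    for c in chroms:
        p_null = chrom_lengths[c] / genome
        pvals.append(
            stats.binomtest(counts[c], n_total, p_null, alternative="greater").pvalue
        )
    qvals = stats.false_discovery_control(pvals, method="bh")
    return [
        ChromEnrichment(
            chrom=c,
            n_variants=counts[c],
            expected=n_total * chrom_lengths[c] / genome,
            p_value=float(p),
            q_value=float(q),
            flagged=bool(q < alpha),
        )
        for c, p, q in zip(chroms, pvals, qvals)
    ]


def window_scan(
    positions: Sequence[int],
    chrom: str,
    chrom_length: int,
    window_size: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    half_width: int = DEFAULT_HALF_WIDTH,
) -> tuple[DensityProfile, EnrichedRegion]:
    """Sliding-window density profile and peak localization on one chromosome.

    The peak window is the maximal-count window (ties break to the smallest
    start); the enriched run is the maximal contiguous stretch of windows
    containing the peak whose counts reach half the peak count; the peak
    center is the median position of the variants inside the peak window,
    rounded to 1 kb; and the candidate interval is the center +/- half-width,
    clipped to the chromosome.
    """
    if window_size <= 0 or step <= 0:
        raise ValueError("window_size and step must be positive")
    if len(positions) == 0:
        raise ValueError("window_scan requires at least one variant")
    pos = np.sort(np.asarray(positions, dtype=np.int64))
    starts = np.arange(0, max(chrom_length - window_size, 0) + 1, step, dtype=np.int64)
    if len(starts) == 0:
        starts = np.array([0], dtype=np.int64)
    # count of positions with start <= p < start + window
    counts = np.searchsorted(pos, starts + window_size, side="left") - np.searchsorted(
        pos, starts, side="left"
    )
    profile = DensityProfile(
        chrom=chrom,
        window_size=window_size,
        step=step,
        window_starts=starts,
        window_counts=counts,
        total=len(pos),
    )
    peak_idx = int(np.argmax(counts))  # argmax takes the first (smallest start) tie
    peak_start = int(starts[peak_idx])
    peak_window = (peak_start, min(peak_start + window_size, chrom_length))
    # contiguous run of windows with count >= half the peak, around the peak
    threshold = counts[peak_idx] / 2
    lo = peak_idx
    while lo > 0 and counts[lo - 1] >= threshold:
        lo -= 1
    hi = peak_idx
    while hi < len(counts) - 1 and counts[hi + 1] >= threshold:
        hi += 1
    run = (int(starts[lo]), int(min(starts[hi] + window_size, chrom_length)))
    in_peak = pos[(pos >= peak_window[0]) & (pos < peak_window[1])]
    peak_center = int(round(float(np.median(in_peak)) / 1000.0) * 1000)
    interval = (
        max(0, peak_center - half_width),
        min(chrom_length, peak_center + half_width),
    )
    n_in_region = int(((pos >= interval[0]) & (pos < interval[1])).sum())
    region = EnrichedRegion(
        chrom=chrom,
        peak_window=peak_window,
        enriched_run=run,
        peak_center=peak_center,
        candidate_interval=interval,
        n_variants_in_region=n_in_region,
    )
    return profile, region


def candidate_genes(
    region: EnrichedRegion, genes: Iterable[GeneInterval]
) -> list[GeneInterval]:
    """Genes overlapping the candidate interval, sorted by distance of their
    midpoint from the peak center (then coordinate for stability)."""
    lo, hi = region.candidate_interval
    hits = [g for g in genes if g.overlaps(region.chrom, lo, hi)]
    hits.sort(key=lambda g: (abs(g.midpoint - region.peak_center), g.start, g.symbol))
    return hits


def scan_flagged_chromosomes(
    positions: Sequence[tuple[str, int]],
    chrom_lengths: Mapping[str, int],
    alpha: float = 0.05,
    window_size: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    half_width: int = DEFAULT_HALF_WIDTH,
) -> tuple[list[ChromEnrichment], list[tuple[DensityProfile, EnrichedRegion]]]:
    """Convenience wrapper: enrichment test, then a window scan per flagged
    chromosome, with the enrichment p/q copied onto each region."""
    enrich = chrom_enrichment(positions, chrom_lengths, alpha)
    scans = []
    for row in enrich:
        if not row.flagged:
            continue
        pos_c = [p for c, p in positions if c == row.chrom]
        profile, region = window_scan(
            pos_c, row.chrom, chrom_lengths[row.chrom], window_size, step, half_width
        )
        region.p_value = row.p_value
        region.q_value = row.q_value
        scans.append((profile, region))
    return enrich, scans
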