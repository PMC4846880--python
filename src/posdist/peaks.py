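"""DHS / ChIP peak processing: merging, TSS annotation, distributions.

Overlapping peaks are merged (strict overlap — intervals that merely
touch are kept separate).  Each peak is then annotated with the signed
distance from its midpoint to the TSS of the nearest gene on either
strand: negative means the midpoint lies upstream of the TSS in that
gene's direction of transcription.  Distances are histogrammed with the
same binning and normalization as the motif-site distributions, so the
peak and TFBS profiles are directly comparable.
"""

from __future__ import annotations

import warnings
from bisect import bisect_left, bisect_right
from dataclasses import dataclass

import numpy as np

from .io_formats import GeneModel, PeakInterval
from .positional_stats import WINDOW, PositionalDistribution, build_distribution

__all__ = [
    "AnnotatedPeak",
    "PeakLengthStats",
    "merge_overlapping",
    "nearest_tss_distance",
    "annotate_peaks",
    "peak_length_stats",
    "peak_distribution",
    "per_family_peak_distributions",
]


@dataclass(frozen=True)
class AnnotatedPeak:
    peak: PeakInterval
    midpoint: int
    nearest_gene: str
    signed_distance: int


@dataclass(frozen=True)
class PeakLengthStats:
    count: int
    mean_length: float | None
    total_length: int
    genome_fraction: float | None


def merge_overlapping(peaks: list[PeakInterval]) -> list[PeakInterval]:
    """Union-merge strictly overlapping peaks per chromosome.

    Output is sorted and pairwise non-overlapping; each interval is the
    union of a maximal chain of overlapping inputs.  Bookended intervals
    (end == start) are NOT merged.  Idempotent.  The merged interval
    keeps the source of its first member; tf_name survives only when
    unanimous in the chain.
    """
    by_chrom: dict[str, list[PeakInterval]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chromosome, []).append(p)
    merged: list[PeakInterval] = []
    for chrom in sorted(by_chrom):
        chain: list[PeakInterval] = []
        end = None
        for p in sorted(by_chrom[chrom], key=lambda q: (q.start, q.end)):
            if chain and p.start < end:
                chain.append(p)
                end = max(end, p.end)
            else:
                if chain:
                    merged.append(_union(chain, end))
                chain = [p]
                end = p.end
        if chain:
            merged.append(_union(chain, end))
    return merged


def _union(chain: list[PeakInterval], end: int) -> PeakInterval:
    tf_names = {p.tf_name for p in chain}
    tf = chain[0].tf_name if len(tf_names) == 1 else None
    return PeakInterval(
        chromosome=chain[0].chromosome,
        start=chain[0].start,
        end=end,
        source=chain[0].source,
        tf_name=tf,
    )


class _GeneIndex:
    """Per-chromosome sorted TSS arrays for nearest-gene queries."""

    def __init__(self, genes: list[GeneModel]):
        self.by_chrom: dict[str, tuple[list[int], list[GeneModel]]] = {}
        tmp: dict[str, list[GeneModel]] = {}
        for g in genes:
            tmp.setdefault(g.chromosome, []).append(g)
        for chrom, gs in tmp.items():
            gs.sort(key=lambda g: (g.tss, g.gene_id))
            self.by_chrom[chrom] = ([g.tss for g in gs], gs)

    def nearest(self, chrom: str, pos: int) -> GeneModel | None:
        entry = self.by_chrom.get(chrom)
        if entry is None:
            return None
        tss_list, gs = entry
        i = bisect_left(tss_list, pos)
        dmin = None
        for j in (i - 1, i):
            if 0 <= j < len(tss_list):
                d = abs(tss_list[j] - pos)
                dmin = d if dmin is None else min(dmin, d)
        # all genes at distance exactly dmin (either side), tie -> smallest id
        candidates: list[GeneModel] = []
        for target in {pos - dmin, pos + dmin}:
            lo = bisect_left(tss_list, target)
            hi = bisect_right(tss_list, target)
            candidates.extend(gs[lo:hi])
        return min(candidates, key=lambda g: g.gene_id)


def nearest_tss_distance(
    peak: PeakInterval, genes: list[GeneModel] | _GeneIndex
) -> AnnotatedPeak | None:
    """Signed midpoint-to-nearest-TSS distance for one peak.

    Midpoint rounds down for even-length peaks.  Nearest gene is by
    absolute distance over both strands on the peak's chromosome (ties:
    lexicographically smaller gene id); the sign is negative when the
    midpoint is 5' of the TSS in the gene's transcription direction.
    Returns None with a warning when the chromosome has no genes.
    """
    index = genes if isinstance(genes, _GeneIndex) else _GeneIndex(genes)
    mid = peak.midpoint
    gene = index.nearest(peak.chromosome, mid)
    if gene is None:
        warnings.warn(f"no genes on chromosome {peak.chromosome!r}; peak skipped")
        return None
    if gene.strand == "+":
        signed = mid - gene.tss
    else:
        signed = gene.tss - mid
    return AnnotatedPeak(peak, mid, gene.gene_id, signed)


def annotate_peaks(
    peaks: list[PeakInterval], genes: list[GeneModel]
) -> list[AnnotatedPeak]:
    index = _GeneIndex(genes)
    out = []
    for p in peaks:
        ap = nearest_tss_distance(p, index)
        if ap is not None:
            out.append(ap)
    return out


def peak_length_stats(
    peaks: list[PeakInterval], genome_length: int | None = None
) -> PeakLengthStats:
    """Count, mean and total peak length, and fraction of the genome covered."""
    n = len(peaks)
    total = sum(p.length for p in peaks)
    mean = total / n if n else None
    frac = (total / genome_length) if (genome_length and n) else (0.0 if n == 0 else None)
    return PeakLengthStats(n, mean, total, frac)


def peak_distribution(
    annotated: list[AnnotatedPeak],
    window: tuple[int, int] = WINDOW,
    bin_width: int = 50,
    label: str = "peaks",
) -> tuple[PositionalDistribution, int]:
    """Positional density of in-window peak distances.

    Peaks whose signed distance falls outside the reporting window are
    excluded from the density; their count is returned alongside.
    """
    lo, hi = window
    inside = [a.signed_distance for a in annotated if lo <= a.signed_distance <= hi]
    n_outside = len(annotated) - len(inside)
    dist = build_distribution(inside, bin_width=bin_width, window=window, label=label)
    return dist, n_outside


def per_family_peak_distributions(
    annotated: list[AnnotatedPeak],
    family_map: dict[str, str],
    min_sites: int = 1000,
    window: tuple[int, int] = WINDOW,
    bin_width: int = 50,
) -> dict[str, PositionalDistribution]:
    """One pooled distribution per TF family with more than ``min_sites`` peaks.

    ChIP peaks are grouped by the family of their TF; families with
    ``min_sites`` or fewer annotated peaks are excluded (strictly-greater
    rule).
    """
    by_family: dict[str, list[AnnotatedPeak]] = {}
    for a in annotated:
        tf = a.peak.tf_name
        if tf is None:
            continue
        fam = family_map.get(tf)
        if fam is None:
            continue
        by_family.setdefault(fam, []).append(a)
    out: dict[str, PositionalDistribution] = {}
    for fam, aps in sorted(by_family.items()):
        if len(aps) > min_sites:
            dist, _ = peak_distribution(
                aps, window=window, bin_width=bin_width, label=f"peaks:{fam}"
            )
            out[fam] = dist
    return out
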