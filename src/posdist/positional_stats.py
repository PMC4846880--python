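"""TSS-relative positional distributions and their summary statistics.

Site positions (by default the occurrence midpoint) are histogrammed over
the promoter window [-2000, +200] in 50-bp bins and normalized so the
density integrates to exactly 1 over the window.  Peakedness is measured
by excess kurtosis of the raw positions (0 for a normal distribution,
positive for sharper, negative for flatter), and TF families are
classified by the location of their density peak together with the sign
of the kurtosis.

Occurrence de-duplication: when one promoter sequence stretch matches two
motifs of the same TF family on the same strand (overlapping intervals),
it is counted as a single binding site; overlapping matches of motifs
from different families remain distinct sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .motif_scan import MotifHit

__all__ = [
    "PositionalDistribution",
    "FamilyClass",
    "SummaryStats",
    "WINDOW",
    "hit_position",
    "dedup_family_sites",
    "build_distribution",
    "cumulative",
    "cumulative_at",
    "excess_kurtosis",
    "classify_family",
    "summary_statistics",
    "fraction_in_range",
]

WINDOW = (-2000, 200)


@dataclass
class PositionalDistribution:
    """Binned, normalized positional density over the promoter window.

    ``density`` is probability per bp per bin, so
    sum(density * bin_width) == 1.  ``peak_position`` is the midpoint of
    the maximal bin (ties broken toward the most upstream bin);
    ``kurtosis`` is the excess kurtosis of the raw positions (None when
    degenerate: n < 4 or zero variance).
    """

    bin_edges: np.ndarray
    density: np.ndarray
    counts: np.ndarray
    n_sites: int
    peak_position: float
    kurtosis: float | None
    label: str = ""

    def integral(self) -> float:
        widths = np.diff(self.bin_edges)
        return float(np.sum(self.density * widths))


@dataclass(frozen=True)
class FamilyClass:
    family: str
    peak_position: float
    kurtosis: float
    category: str  # upstream_sharp | TSS_proximal_sharp | downstream_sharp | flat
    n_sites: int


@dataclass(frozen=True)
class SummaryStats:
    mean_sites_per_gene: float
    mean_families_per_gene: float
    mean_genes_per_motif: float
    fraction_genes_with_site: float
    n_genes_with_site: int


def hit_position(hit: MotifHit, anchor: str = "midpoint") -> int:
    """TSS-relative position of a hit: midpoint (default) or start."""
    if anchor == "midpoint":
        return hit.tss_relative_start + hit.width // 2
    if anchor == "start":
        return hit.tss_relative_start
    raise ValueError(f"unknown anchor {anchor!r}")


def dedup_family_sites(
    hits: list[MotifHit],
    family_map: dict[str, str],
) -> list[MotifHit]:
    """Collapse same-family overlapping hits within one gene to single sites.

    Hits of motifs from the same family, on the same strand, whose
    intervals overlap (strictly share bases, chained transitively) are
    one binding site; the representative kept is the hit with the
    smallest p-value (ties: leftmost start, then motif id).  Hits of
    different families are never collapsed.  Idempotent.
    """
    groups: dict[tuple[str, str], list[MotifHit]] = {}
    for h in hits:
        fam = family_map.get(h.motif_id, "unknown")
        groups.setdefault((fam, h.strand), []).append(h)
    sites: list[MotifHit] = []
    for _, grp in sorted(groups.items()):
        grp.sort(key=lambda h: (h.tss_relative_start, h.tss_relative_end))
        cluster: list[MotifHit] = []
        cluster_end = None
        for h in grp:
            if cluster and h.tss_relative_start < cluster_end:
                cluster.append(h)
                cluster_end = max(cluster_end, h.tss_relative_end)
            else:
                if cluster:
                    sites.append(_best_of(cluster))
                cluster = [h]
                cluster_end = h.tss_relative_end
        if cluster:
            sites.append(_best_of(cluster))
    sites.sort(key=lambda h: (h.tss_relative_start, h.motif_id))
    return sites


def _best_of(cluster: list[MotifHit]) -> MotifHit:
    return min(cluster, key=lambda h: (h.p_value, h.tss_relative_start, h.motif_id))


def build_distribution(
    positions,
    bin_width: int = 50,
    window: tuple[int, int] = WINDOW,
    label: str = "",
) -> PositionalDistribution:
    """Histogram positions into a density integrating to 1 over the window.

    Bins are half-open with the last bin closed (numpy convention);
    positions outside the window are rejected.
    """
    positions = np.asarray(list(positions), dtype=float)
    if positions.size == 0:
        raise ValueError("cannot build a distribution from zero positions")
    lo, hi = window
    if positions.min() < lo or positions.max() > hi:
        raise ValueError(f"positions outside window [{lo}, {hi}]")
    edges = np.arange(lo, hi + bin_width, bin_width, dtype=float)
    counts, _ = np.histogram(positions, bins=edges)
    n = int(positions.size)
    density = counts / (n * bin_width)
    peak_bin = int(np.argmax(counts))  # ties -> most upstream
    peak_position = float(edges[peak_bin] + bin_width / 2.0)
    if positions.size >= 4 and positions.std() > 0:
        kurt = excess_kurtosis(positions)
    else:
        kurt = None
    return PositionalDistribution(
        bin_edges=edges,
        density=density,
        counts=counts,
        n_sites=n,
        peak_position=peak_position,
        kurtosis=kurt,
        label=label,
    )


def cumulative(dist: PositionalDistribution) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative probability at every bin edge, from the upstream end.

    Returns (edges, cum) with cum[0] = 0 and cum[-1] = 1.
    """
    cum = np.concatenate([[0.0], np.cumsum(dist.counts) / dist.n_sites])
    return dist.bin_edges, cum


def cumulative_at(dist: PositionalDistribution, position: float) -> float:
    """P(site position <= ``position``), linear within bins."""
    edges, cum = cumulative(dist)
    return float(np.interp(position, edges, cum))


def excess_kurtosis(positions) -> float:
    """Population-moment excess kurtosis g2 = m4/m2^2 - 3 (no bias correction)."""
    positions = np.asarray(list(positions), dtype=float)
    if positions.size < 4:
        raise ValueError("need at least 4 positions for kurtosis")
    if positions.std() == 0:
        raise ValueError("zero variance: kurtosis undefined")
    return float(sps.kurtosis(positions, fisher=True, bias=True))


def classify_family(
    family: str, dist: PositionalDistribution
) -> FamilyClass:
    """Classify a family distribution by peak location and kurtosis sign.

    kurtosis < 0 -> flat; otherwise the peak bin midpoint decides:
    < -100 bp -> upstream_sharp, in [-100, 0] -> TSS_proximal_sharp,
    > 0 -> downstream_sharp.  Kurtosis exactly 0 falls in the sharp
    branches.
    """
    if dist.kurtosis is None:
        raise ValueError(f"family {family!r}: kurtosis undefined")
    k = dist.kurtosis
    p = dist.peak_position
    if k < 0:
        category = "flat"
    elif p < -100:
        category = "upstream_sharp"
    elif p <= 0:
        category = "TSS_proximal_sharp"
    else:
        category = "downstream_sharp"
    return FamilyClass(family, p, k, category, dist.n_sites)


def summary_statistics(
    sites: list[MotifHit],
    family_map: dict[str, str],
    n_genes_total: int,
) -> SummaryStats:
    """Per-gene and per-motif occupancy averages over de-duplicated sites.

    Per-gene means are taken over genes with at least one site; the
    per-motif mean over motifs with at least one target gene.
    """
    by_gene: dict[str, list[MotifHit]] = {}
    by_motif: dict[str, set[str]] = {}
    for s in sites:
        by_gene.setdefault(s.gene_id, []).append(s)
        by_motif.setdefault(s.motif_id, set()).add(s.gene_id)
    n_with = len(by_gene)
    if n_with == 0:
        return SummaryStats(0.0, 0.0, 0.0, 0.0, 0)
    sites_per_gene = [len(v) for v in by_gene.values()]
    fams_per_gene = [
        len({family_map.get(h.motif_id, "unknown") for h in v})
        for v in by_gene.values()
    ]
    genes_per_motif = [len(v) for v in by_motif.values()]
    return SummaryStats(
        mean_sites_per_gene=float(np.mean(sites_per_gene)),
        mean_families_per_gene=float(np.mean(fams_per_gene)),
        mean_genes_per_motif=float(np.mean(genes_per_motif)),
        fraction_genes_with_site=n_with / n_genes_total if n_genes_total else 0.0,
        n_genes_with_site=n_with,
    )


def fraction_in_range(positions, lo: float, hi: float) -> float:
    """Fraction of positions with lo <= x <= hi (inclusive both ends)."""
    positions = np.asarray(list(positions), dtype=float)
    if positions.size == 0:
        raise ValueError("no positions")
    return float(np.mean((positions >= lo) & (positions <= hi)))
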