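"""Cross-species conservation test for motif occurrences.

The test mirrors classic phylogenetic footprinting: a motif occurrence in
the query species' promoter counts as conserved when an occurrence of the
same motif is found in the orthologous promoter of each reference species
within 100 columns of the query occurrence in the pairwise promoter
alignment, on the same strand relative to transcription.

One-to-one orthologs are selected per reference species by requiring
percent identity > 50 and taking the candidate with the highest identity
(ties broken toward the lexicographically smaller id); genes lacking an
ortholog in any reference species are dropped from the analysis.

Promoters are the window [-2000, +200) around the TSS, extracted in
transcription orientation (minus-strand genes reverse-complemented).
Pairwise global alignments use match +5, mismatch -4, gap open -10,
gap extend -0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align

from .io_formats import GeneModel, GenomeSet
from .motif_scan import MotifHit, reverse_complement

__all__ = [
    "PromoterRecord",
    "OrthologAssignment",
    "PairAlignment",
    "PromoterAlignment",
    "ConservedHit",
    "PROMOTER_UPSTREAM",
    "PROMOTER_DOWNSTREAM",
    "extract_promoter",
    "select_ortholog",
    "assign_orthologs",
    "drop_genes_without_full_orthology",
    "make_aligner",
    "align_promoters",
    "test_conservation",
    "motif_passes_conservation",
    "position_shift_distribution",
]

PROMOTER_UPSTREAM = 2000
PROMOTER_DOWNSTREAM = 200


@dataclass
class PromoterRecord:
    """A promoter window in transcription orientation.

    ``window_start``/``window_end`` give the covered interval in
    TSS-relative bp (normally [-2000, +200)); shorter records at
    chromosome edges are flagged ``truncated``.
    """

    gene_id: str
    species: str
    sequence: str
    window_start: int = -PROMOTER_UPSTREAM
    window_end: int = PROMOTER_DOWNSTREAM
    truncated: bool = False

    def __post_init__(self) -> None:
        if len(self.sequence) != self.window_end - self.window_start:
            raise ValueError(
                f"promoter {self.gene_id}/{self.species}: sequence length "
                f"{len(self.sequence)} != window span"
            )


@dataclass(frozen=True)
class OrthologAssignment:
    query_gene: str
    species: str
    ortholog: str | None
    identity: float | None


def extract_promoter(
    gene: GeneModel,
    genome: GenomeSet,
    species: str | None = None,
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
) -> PromoterRecord:
    """Extract the [-upstream, +downstream) window around a gene's TSS.

    Minus-strand genes are reverse-complemented so that position
    ``-upstream`` is always the 5'-most base of the window in
    transcription orientation.  Windows clipped at a chromosome edge are
    flagged truncated.
    """
    chrom = genome.sequences.get(gene.chromosome)
    if chrom is None:
        raise KeyError(
            f"gene {gene.gene_id}: chromosome {gene.chromosome!r} not in genome"
        )
    n = len(chrom)
    if not (0 <= gene.tss < n):
        raise ValueError(f"gene {gene.gene_id}: TSS outside chromosome")
    if gene.strand == "+":
        g0 = max(0, gene.tss - upstream)
        g1 = min(n, gene.tss + downstream)
        seq = chrom[g0:g1]
        ws, we = g0 - gene.tss, g1 - gene.tss
    else:
        # transcript coordinate t maps to genomic g = tss - t
        a = max(0, gene.tss - downstream + 1)
        b = min(n, gene.tss + upstream + 1)
        seq = reverse_complement(chrom[a:b])
        ws, we = gene.tss - b + 1, gene.tss - a + 1
    truncated = ws != -upstream or we != downstream
    return PromoterRecord(
        gene_id=gene.gene_id,
        species=species if species is not None else genome.species_id,
        sequence=seq,
        window_start=ws,
        window_end=we,
        truncated=truncated,
    )


# ---------------------------------------------------------------------------
# Ortholog selection


def select_ortholog(
    query_gene: str,
    species: str,
    candidates: list[tuple[str, float]],
    min_identity: float = 50.0,
) -> OrthologAssignment:
    """One-to-one ortholog choice: identity strictly > 50, then max identity.

    Ties in identity are broken toward the lexicographically smaller
    ortholog id so the choice is deterministic.
    """
    survivors = [(g, ident) for g, ident in candidates if ident > min_identity]
    if not survivors:
        return OrthologAssignment(query_gene, species, None, None)
    best = min(survivors, key=lambda c: (-c[1], c[0]))
    return OrthologAssignment(query_gene, species, best[0], best[1])


def assign_orthologs(
    table: pd.DataFrame,
    reference_species: list[str],
    min_identity: float = 50.0,
) -> dict[tuple[str, str], OrthologAssignment]:
    """Run :func:`select_ortholog` for every (query gene, species) pair."""
    assignments: dict[tuple[str, str], OrthologAssignment] = {}
    grouped = table.groupby(["query_gene", "species"])
    for (gene, species), grp in grouped:
        if species not in reference_species:
            continue
        cands = list(zip(grp["ortholog_gene"], grp["percent_identity"]))
        assignments[(gene, species)] = select_ortholog(
            gene, species, cands, min_identity
        )
    return assignments


def drop_genes_without_full_orthology(
    assignments: dict[tuple[str, str], OrthologAssignment],
    reference_species: list[str],
) -> set[str]:
    """Retain only genes with a chosen ortholog in every reference species."""
    genes = {g for g, _ in assignments}
    retained = set()
    for g in genes:
        if all(
            (g, sp) in assignments and assignments[(g, sp)].ortholog is not None
            for sp in reference_species
        ):
            retained.add(g)
    return retained


# ---------------------------------------------------------------------------
# Promoter alignment


def make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 5
    aligner.mismatch_score = -4
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -0.5
    return aligner


@dataclass
class PairAlignment:
    """One reference promoter globally aligned to the query promoter."""

    species: str
    score: float
    col_of_query: np.ndarray  # query promoter position -> alignment column
    col_of_ortho: np.ndarray  # ortholog promoter position -> alignment column
    aligned_query: str
    aligned_ortho: str


@dataclass
class PromoterAlignment:
    gene_id: str
    query: PromoterRecord
    orthologs: dict[str, PromoterRecord]
    pairs: dict[str, PairAlignment]


def _pair_alignment(
    aligner: Align.PairwiseAligner,
    species: str,
    query_seq: str,
    ortho_seq: str,
) -> PairAlignment:
    aln = aligner.align(query_seq, ortho_seq)[0]
    indices = aln.indices  # 2 x ncols; -1 at gaps
    ncols = indices.shape[1]
    cols = np.arange(ncols)
    col_of_query = np.full(len(query_seq), -1, dtype=np.int64)
    col_of_ortho = np.full(len(ortho_seq), -1, dtype=np.int64)
    mq = indices[0] >= 0
    mo = indices[1] >= 0
    col_of_query[indices[0][mq]] = cols[mq]
    col_of_ortho[indices[1][mo]] = cols[mo]
    a_query, a_ortho = str(aln[0]), str(aln[1])
    return PairAlignment(species, float(aln.score), col_of_query, col_of_ortho,
                         a_query, a_ortho)


def align_promoters(
    query: PromoterRecord,
    orthologs: dict[str, PromoterRecord],
    aligner: Align.PairwiseAligner | None = None,
) -> PromoterAlignment:
    """Align each reference-species promoter to the query promoter.

    Three pairwise global alignments (affine gaps); column maps are
    rebuilt from each alignment so promoter positions can be compared in
    alignment space.
    """
    if aligner is None:
        aligner = make_aligner()
    if not query.sequence:
        raise ValueError(f"gene {query.gene_id}: empty query promoter")
    pairs = {}
    for species, rec in orthologs.items():
        if not rec.sequence:
            raise ValueError(f"gene {query.gene_id}/{species}: empty promoter")
        pairs[species] = _pair_alignment(aligner, species, query.sequence,
                                         rec.sequence)
    return PromoterAlignment(query.gene_id, query, orthologs, pairs)


# ---------------------------------------------------------------------------
# Conservation test


@dataclass
class ConservedHit:
    """A query-species motif hit annotated with its conservation outcome."""

    hit: MotifHit
    conserved_in: set[str]
    shifts: dict[str, int | None]
    passed: bool


def test_conservation(
    hit: MotifHit,
    alignment: PromoterAlignment,
    ortholog_hits: dict[str, list[MotifHit]],
    tolerance: int = 100,
) -> ConservedHit | None:
    """Apply the 100-column / same-strand conservation rule to one hit.

    For each reference species the hit is conserved iff some occurrence of
    the same motif on the same strand starts within ``tolerance`` columns
    of the query occurrence's start column in the pairwise alignment.
    The signed column offset of the nearest qualifying occurrence is
    recorded.  Returns None (with a warning) when the hit's start does not
    map into the alignment, e.g. inside a truncated window.
    """
    qpos = hit.tss_relative_start - alignment.query.window_start
    conserved: set[str] = set()
    shifts: dict[str, int | None] = {}
    for species, pair in alignment.pairs.items():
        if not (0 <= qpos < len(pair.col_of_query)):
            warnings.warn(
                f"hit {hit.motif_id}@{hit.tss_relative_start} of gene "
                f"{hit.gene_id}: start not mapped in alignment; excluded"
            )
            return None
        c0 = int(pair.col_of_query[qpos])
        best: int | None = None
        orec = alignment.orthologs[species]
        for oh in ortholog_hits.get(species, []):
            if oh.motif_id != hit.motif_id or oh.strand != hit.strand:
                continue
            opos = oh.tss_relative_start - orec.window_start
            if not (0 <= opos < len(pair.col_of_ortho)):
                continue
            shift = int(pair.col_of_ortho[opos]) - c0
            if abs(shift) <= tolerance:
                if best is None or (abs(shift), shift) < (abs(best), best):
                    best = shift
        shifts[species] = best
        if best is not None:
            conserved.add(species)
    passed = conserved == set(alignment.pairs)
    return ConservedHit(hit=hit, conserved_in=conserved, shifts=shifts,
                        passed=passed)


def motif_passes_conservation(
    motif_id: str, conserved_hits: list[ConservedHit]
) -> bool:
    """A motif passes when at least one of its occurrences passed the test."""
    return any(c.passed for c in conserved_hits if c.hit.motif_id == motif_id)


def position_shift_distribution(
    conserved_hits: list[ConservedHit],
) -> dict[str, float]:
    """Fractions of per-species |position shift| in bins {0, 1-10, >10}.

    Pools the alignment-column shifts of all passed hits across reference
    species; fractions sum to 1.
    """
    shifts = [
        abs(s)
        for c in conserved_hits
        if c.passed
        for s in c.shifts.values()
        if s is not None
    ]
    n = len(shifts)
    if n == 0:
        return {"0": 0.0, "1-10": 0.0, ">10": 0.0}
    zero = sum(1 for s in shifts if s == 0)
    small = sum(1 for s in shifts if 1 <= s <= 10)
    large = n - zero - small
    return {"0": zero / n, "1-10": small / n, ">10": large / n}
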