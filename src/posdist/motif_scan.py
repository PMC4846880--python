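"""PWM scanning of promoters with exact p-value calibration.

A motif's position probability matrix is turned into an integer-scaled
log-odds matrix; the null distribution of the total score of a random
background word is then computed exactly by convolving the per-position
score distributions over the integer score support.  A promoter window is
reported as a hit when the probability that a background word scores at
least as high is strictly below ``alpha`` (default 1e-4), on either strand.

The background model is 0-order, uniform by default.  Ambiguous bases (N)
score 0 by construction, i.e. they are treated as background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_formats import MotifModel

__all__ = [
    "ScoringMatrix",
    "PValueTable",
    "MotifHit",
    "build_scoring_matrix",
    "exact_pvalues",
    "scan_promoter",
    "reverse_complement",
    "UNIFORM_BACKGROUND",
]

UNIFORM_BACKGROUND = np.array([0.25, 0.25, 0.25, 0.25])

_BASE_TO_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMPLEMENT_INDEX = np.array([3, 2, 1, 0, 4])  # A<->T, C<->G, N->N

_ENCODE_TABLE = np.full(256, 4, dtype=np.int8)
for _b, _i in _BASE_TO_INDEX.items():
    _ENCODE_TABLE[ord(_b)] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Map a nucleotide string to integer codes (A=0 C=1 G=2 T=3, N/other=4)."""
    return _ENCODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


@dataclass
class ScoringMatrix:
    """Integer-scaled log-odds scores for one motif.

    ``log_odds`` has shape width x 5; column 4 (N) is all zeros so that
    ambiguous bases contribute the background score.  ``scale`` is the
    number of integer score units per log2 (granularity of the exact
    p-value support).
    """

    motif_id: str
    log_odds: np.ndarray
    scale: int
    background: np.ndarray

    def __post_init__(self) -> None:
        self.log_odds = np.asarray(self.log_odds, dtype=np.int64)
        self.background = np.asarray(self.background, dtype=float)
        if self.scale < 100:
            raise ValueError("scale must be >= 100 integer units per log2")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.log_odds.shape[0]

    def reverse_complement(self) -> "ScoringMatrix":
        rc = self.log_odds[::-1, _COMPLEMENT_INDEX]
        return ScoringMatrix(self.motif_id, rc, self.scale, self.background)


@dataclass
class PValueTable:
    """Exact survival function of the background score distribution.

    ``sf[s - min_score]`` = P(total score of a random background word >= s)
    for every integer s in [min_score, max_score].
    """

    motif_id: str
    min_score: int
    sf: np.ndarray

    @property
    def max_score(self) -> int:
        return self.min_score + len(self.sf) - 1

    def pvalue(self, score: int) -> float:
        if score <= self.min_score:
            return 1.0
        if score > self.max_score:
            return 0.0
        return float(self.sf[score - self.min_score])

    def pvalues(self, scores: np.ndarray) -> np.ndarray:
        idx = np.clip(scores - self.min_score, 0, len(self.sf) - 1)
        p = self.sf[idx]
        return np.where(scores > self.max_score, 0.0, p)


@dataclass(frozen=True)
class MotifHit:
    """One scored motif occurrence in a promoter.

    ``tss_relative_start`` is in bp along the direction of transcription,
    0 at the TSS and negative upstream.  ``strand`` is ``"same"`` or
    ``"opposite"`` relative to the gene's coding strand.  ``score`` is in
    log2-odds units.
    """

    motif_id: str
    gene_id: str
    tss_relative_start: int
    strand: str
    score: float
    p_value: float
    width: int

    @property
    def tss_relative_end(self) -> int:
        return self.tss_relative_start + self.width

    def midpoint(self) -> int:
        return self.tss_relative_start + self.width // 2


def build_scoring_matrix(
    motif: MotifModel,
    background: np.ndarray | None = None,
    pseudocount: float = 0.1,
    scale: int = 1000,
) -> ScoringMatrix:
    """Integer-scaled log-odds matrix from a position probability matrix.

    score(i, b) = round(scale * log2((p[i,b] + pseudocount*bg[b]) /
    ((1 + pseudocount) * bg[b]))).  A fractional pseudocount distributed
    by the background keeps zero-probability cells finite.
    """
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
    if (bg <= 0).any():
        raise ValueError("background probabilities must be > 0")
    if abs(bg.sum() - 1.0) > 1e-9:
        raise ValueError("background must sum to 1")
    p = motif.matrix
    if (p.sum(axis=1) == 0).any():
        raise ValueError(f"motif {motif.motif_id}: all-zero row")
    adjusted = (p + pseudocount * bg[None, :]) / (1.0 + pseudocount)
    if (adjusted <= 0).any():
        raise ValueError(
            f"motif {motif.motif_id}: zero adjusted probability; "
            "use a positive pseudocount"
        )
    lo = np.rint(scale * np.log2(adjusted / bg[None, :])).astype(np.int64)
    lo5 = np.zeros((motif.width, 5), dtype=np.int64)
    lo5[:, :4] = lo
    return ScoringMatrix(motif.motif_id, lo5, scale, bg)


def exact_pvalues(sm: ScoringMatrix) -> PValueTable:
    """Exact p-value table by dynamic programming over the score support.

    The distribution of the total score of a width-w i.i.d. background
    word is the convolution of the w per-position score distributions,
    computed over the integer score lattice; the table is its survival
    function.
    """
    lo = sm.log_odds[:, :4]
    bg = sm.background
    min_s = int(lo.min(axis=1).sum())
    max_s = int(lo.max(axis=1).sum())
    span = max_s - min_s + 1
    # dist[k] = P(partial score == min_partial + k)
    dist = np.zeros(1)
    dist[0] = 1.0
    offset = 0  # minimum achievable partial score so far
    for i in range(sm.width):
        row = lo[i]
        row_min = int(row.min())
        row_max = int(row.max())
        new = np.zeros(len(dist) + (row_max - row_min))
        for b in range(4):
            shift = int(row[b]) - row_min
            new[shift : shift + len(dist)] += bg[b] * dist
        dist = new
        offset += row_min
    assert offset == min_s and len(dist) == span
    sf = np.cumsum(dist[::-1])[::-1]
    np.clip(sf, 0.0, 1.0, out=sf)
    return PValueTable(sm.motif_id, min_s, sf)


def _window_scores(codes: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Total integer score at every offset of a width-w window."""
    w = lo.shape[0]
    n = len(codes) - w + 1
    scores = np.zeros(n, dtype=np.int64)
    for i in range(w):
        scores += lo[i, codes[i : i + n]]
    return scores


def scan_promoter(
    promoter_seq: str,
    sm: ScoringMatrix,
    pvalue_table: PValueTable,
    alpha: float = 1e-4,
    gene_id: str = "",
    window_start: int = -2000,
) -> list[MotifHit]:
    """Report motif occurrences with exact p-value strictly below ``alpha``.

    The promoter is given in transcription orientation; a hit at string
    offset k is reported at ``tss_relative_start = window_start + k``.
    Both strands are scanned; the opposite strand is scored by scanning
    the forward string with the reverse-complemented matrix, so same and
    opposite hits share the start-coordinate convention.
    """
    w = sm.width
    if len(promoter_seq) < w:
        warnings.warn(
            f"promoter of gene {gene_id!r} shorter than motif width {w}; no scan"
        )
        return []
    codes = encode_sequence(promoter_seq)
    hits: list[MotifHit] = []
    for strand, matrix in (("same", sm), ("opposite", sm.reverse_complement())):
        scores = _window_scores(codes, matrix.log_odds)
        pvals = pvalue_table.pvalues(scores)
        for k in np.flatnonzero(pvals < alpha):
            hits.append(
                MotifHit(
                    motif_id=sm.motif_id,
                    gene_id=gene_id,
                    tss_relative_start=window_start + int(k),
                    strand=strand,
                    score=float(scores[k]) / sm.scale,
                    p_value=float(pvals[k]),
                    width=w,
                )
            )
    hits.sort(key=lambda h: (h.tss_relative_start, h.strand))
    return hits


HITS_TSV_COLUMNS = [
    "motif_id",
    "gene_id",
    "tss_relative_start",
    "strand",
    "score",
    "p_value",
    "width",
]


def write_hits_tsv(hits: list[MotifHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(HITS_TSV_COLUMNS) + "\n")
        for h in hits:
            fh.write(
                f"{h.motif_id}\t{h.gene_id}\t{h.tss_relative_start}\t{h.strand}\t"
                f"{h.score:.6g}\t{h.p_value:.6g}\t{h.width}\n"
            )


def read_hits_tsv(path) -> list[MotifHit]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return [
        MotifHit(
            motif_id=str(r.motif_id),
            gene_id=str(r.gene_id),
            tss_relative_start=int(r.tss_relative_start),
            strand=str(r.strand),
            score=float(r.score),
            p_value=float(r.p_value),
            width=int(r.width),
        )
        for r in df.itertuples()
    ]
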