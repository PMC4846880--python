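"""Readers and writers for the external formats the pipeline touches.

Coordinate conventions
----------------------
All internal genomic coordinates are 0-based half-open.  BED is native;
GFF3 (1-based inclusive) is converted on read: the TSS of a ``+`` gene is
``start - 1`` and of a ``-`` gene ``end - 1`` — in both cases the first
transcribed base.  Sequences are uppercased on load; the ambiguity code N
is permitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "GenomeSet",
    "GeneModel",
    "MotifModel",
    "PeakInterval",
    "read_fasta",
    "write_fasta",
    "read_gff3_genes",
    "write_gff3_genes",
    "read_meme_motifs",
    "write_meme_motifs",
    "read_bed_peaks",
    "write_bed_peaks",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_ortholog_table",
    "write_ortholog_table",
]

_VALID_BASES = frozenset("ACGTN")

ORTHOLOG_COLUMNS = ["query_gene", "species", "ortholog_gene", "percent_identity"]


@dataclass
class GenomeSet:
    """A set of chromosome sequences for one species."""

    species_id: str
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"empty sequence for chromosome {name!r}")
            bad = set(seq) - _VALID_BASES
            if bad:
                raise ValueError(
                    f"chromosome {name!r} contains invalid characters {sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.sequences)

    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())


@dataclass(frozen=True)
class GeneModel:
    """A gene anchored by its transcription start site.

    ``tss`` is the 0-based genomic coordinate of the first transcribed
    base; all promoter-relative positions are measured from it along the
    direction of transcription.
    """

    gene_id: str
    chromosome: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.tss < 0:
            raise ValueError(f"gene {self.gene_id}: negative TSS")


@dataclass
class MotifModel:
    """A position probability matrix with TF and family labels.

    ``matrix`` is width x 4 over the alphabet ACGT; every row is a
    probability distribution (sum 1 within 1e-6).
    """

    motif_id: str
    tf_name: str
    family: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError(f"motif {self.motif_id}: matrix must be width x 4")
        if self.width < 4:
            raise ValueError(f"motif {self.motif_id}: width {self.width} < 4")
        if (self.matrix < 0).any():
            raise ValueError(f"motif {self.motif_id}: negative probability")
        sums = self.matrix.sum(axis=1)
        if np.abs(sums - 1.0).max() > 1e-6:
            raise ValueError(f"motif {self.motif_id}: rows do not sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=1))


@dataclass(frozen=True)
class PeakInterval:
    """A DHS or ChIP interval in 0-based half-open coordinates."""

    chromosome: str
    start: int
    end: int
    source: str = "DHS"
    tf_name: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"peak {self.chromosome}:{self.start}-{self.end}: start >= end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        # even-length intervals round down
        return (self.start + self.end) // 2


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path, species_id: str | None = None) -> GenomeSet:
    """Read a FASTA file into a :class:`GenomeSet` (sequences uppercased)."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate FASTA header {record.id!r}")
        seq = str(record.seq).upper()
        if not seq:
            raise ValueError(f"empty FASTA record {record.id!r}")
        sequences[record.id] = seq
    if not sequences:
        raise ValueError(f"no FASTA records in {path}")
    sid = species_id if species_id is not None else str(path)
    return GenomeSet(species_id=sid, sequences=sequences)


def write_fasta(genome: GenomeSet, path, line_width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 gene models


def read_gff3_genes(path) -> list[GeneModel]:
    """Extract gene features from a GFF3 file as :class:`GeneModel` records.

    GFF3 start/end are 1-based inclusive; the returned TSS is 0-based.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    seen: set[str] = set()
    for feat in db.features_of_type("gene"):
        if feat.strand not in ("+", "-"):
            raise ValueError(f"gene feature without strand: {feat}")
        if "ID" not in feat.attributes:
            raise ValueError(f"gene feature without ID attribute: {feat}")
        gene_id = feat.attributes["ID"][0]
        if gene_id in seen:
            raise ValueError(f"duplicate gene ID {gene_id!r}")
        seen.add(gene_id)
        tss = feat.start - 1 if feat.strand == "+" else feat.end - 1
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chromosome=feat.seqid,
                strand=feat.strand,
                tss=tss,
            )
        )
    return genes


def write_gff3_genes(genes: list[GeneModel], path, gene_span: int = 1000) -> None:
    """Write gene models as GFF3 gene features.

    Only the TSS and strand are meaningful downstream; the far end of each
    feature is drawn ``gene_span`` bp into the gene body.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            if g.strand == "+":
                start, end = g.tss + 1, g.tss + gene_span
            else:
                start, end = max(1, g.tss + 2 - gene_span), g.tss + 1
            fh.write(
                f"{g.chromosome}\tposdist\tgene\t{start}\t{end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# MEME minimal motif format
#
# TF name and family ride in the motif name field as "motif_id|tf|family";
# the format itself has no slot for either.  Absent fields default to the
# motif_id and "unknown".


def _parse_motif_name(name: str) -> tuple[str, str, str]:
    parts = name.split("|")
    motif_id = parts[0]
    tf_name = parts[1] if len(parts) > 1 and parts[1] else motif_id
    family = parts[2] if len(parts) > 2 and parts[2] else "unknown"
    return motif_id, tf_name, family


def read_meme_motifs(path) -> list[MotifModel]:
    """Read MEME minimal-format motifs (letter-probability matrices over ACGT).

    Rows whose sum is within 1e-3 of 1 are renormalized; larger deviations
    and negative entries are errors.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    motifs: list[MotifModel] = []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            name = line.split(None, 2)[1]
            i += 1
            while i < len(lines) and not lines[i].strip().startswith(
                "letter-probability matrix"
            ):
                i += 1
            if i >= len(lines):
                raise ValueError(f"motif {name!r}: no letter-probability matrix")
            header = lines[i].strip()
            width = None
            toks = header.replace("=", " = ").split()
            for j, t in enumerate(toks):
                if t == "w" and j + 2 < len(toks) and toks[j + 1] == "=":
                    width = int(toks[j + 2])
            if width is None:
                raise ValueError(f"motif {name!r}: matrix header lacks w=")
            if width < 4:
                raise ValueError(f"motif {name!r}: width {width} < 4")
            rows = []
            i += 1
            while len(rows) < width:
                if i >= len(lines):
                    raise ValueError(f"motif {name!r}: truncated matrix")
                row_line = lines[i].strip()
                i += 1
                if not row_line:
                    continue
                vals = [float(x) for x in row_line.split()]
                if len(vals) != 4:
                    raise ValueError(f"motif {name!r}: expected 4 columns per row")
                rows.append(vals)
            matrix = np.array(rows, dtype=float)
            if (matrix < 0).any():
                raise ValueError(f"motif {name!r}: negative probability")
            sums = matrix.sum(axis=1)
            if np.abs(sums - 1.0).max() > 1e-3:
                bad = int(np.abs(sums - 1.0).argmax())
                raise ValueError(
                    f"motif {name!r}: row {bad} sums to {sums[bad]:.6g}, "
                    "outside the 1e-3 tolerance"
                )
            matrix = matrix / sums[:, None]
            motif_id, tf_name, family = _parse_motif_name(name)
            motifs.append(MotifModel(motif_id, tf_name, family, matrix))
        else:
            i += 1
    if not motifs:
        raise ValueError(f"no motifs found in {path}")
    return motifs


def write_meme_motifs(motifs: list[MotifModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for m in motifs:
            fh.write(f"MOTIF {m.motif_id}|{m.tf_name}|{m.family}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.width} "
                f"nsites= 20 E= 0\n"
            )
            for row in m.matrix:
                fh.write(" " + " ".join(f"{p:.10g}" for p in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# BED peaks


def read_bed_peaks(path, source: str = "DHS") -> list[PeakInterval]:
    """Read BED3+ intervals; an optional 4th column is the ChIP TF name."""
    peaks: list[PeakInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            tf_name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            peaks.append(PeakInterval(chrom, start, end, source, tf_name))
    return peaks


def write_bed_peaks(peaks: list[PeakInterval], path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            if p.tf_name is not None:
                fh.write(f"{p.chromosome}\t{p.start}\t{p.end}\t{p.tf_name}\n")
            else:
                fh.write(f"{p.chromosome}\t{p.start}\t{p.end}\n")


# ---------------------------------------------------------------------------
# Expression matrix (genes x samples, raw RPKM)


def read_expression_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate gene_id {dup!r} in expression matrix")
    if df.isna().any().any():
        raise ValueError("missing values in expression matrix")
    if (df.to_numpy() < 0).any():
        raise ValueError("negative RPKM values in expression matrix")
    df.index.name = "gene_id"
    return df


def write_expression_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# Ortholog candidate table


def read_ortholog_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(ORTHOLOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"ortholog table missing columns {sorted(missing)}")
    ident = df["percent_identity"]
    if ((ident < 0) | (ident > 100)).any():
        raise ValueError("percent_identity outside [0, 100]")
    return df[ORTHOLOG_COLUMNS]


def write_ortholog_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=ORTHOLOG_COLUMNS)
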