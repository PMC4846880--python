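"""Self-contained four-species toy dataset with planted ground truth.

Every pipeline stage needs data with a known answer: this module builds a
query genome whose promoters carry motif occurrences planted from a
controllable positional law (by default Gaussian centred 50 bp upstream
of the TSS), three "reference species" genomes whose orthologous
promoters are mutated copies in which each planted site is either
preserved verbatim or destroyed at a controlled rate, an expression
matrix in which a controlled fraction of TF-target pairs is strongly
correlated, and DHS/ChIP peak files centred on the planted sites with
positional jitter.

Background sequence is i.i.d. uniform over ACGT, which makes the
scanner's exact p-value calibration exact for this data.  Genes occupy
non-overlapping 3,000-bp slots with alternating strands, so per-gene
ground truth never bleeds across genes.

Planted site instances are sampled from the motif's probability rows
(so scanner score variability is exercised) but rejection-sampled to
score below the scan threshold's p-value: a planted site is by contract
an occurrence the scanner can see.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    GeneModel,
    GenomeSet,
    MotifModel,
    PeakInterval,
    write_bed_peaks,
    write_expression_tsv,
    write_fasta,
    write_gff3_genes,
    write_meme_motifs,
    write_ortholog_table,
)
from .motif_scan import (
    build_scoring_matrix,
    encode_sequence,
    exact_pvalues,
    reverse_complement,
)

__all__ = [
    "GaussianLaw",
    "UniformLaw",
    "PointLaw",
    "SyntheticSpec",
    "PlantedSite",
    "GroundTruth",
    "SyntheticDataset",
    "generate_dataset",
    "generate_expression",
    "write_dataset",
    "QUERY_SPECIES",
    "REFERENCE_SPECIES",
]

QUERY_SPECIES = "query"
REFERENCE_SPECIES = ["ref1", "ref2", "ref3"]

_SLOT = 3000
_UPSTREAM = 2000
_DOWNSTREAM = 200
_WINDOW_LEN = _UPSTREAM + _DOWNSTREAM

_FAMILY_POOL = ["bZIP", "bHLH", "MYB", "AP2", "WRKY", "GATA", "NAC", "HB"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# Positional laws (TSS-relative bp)


@dataclass(frozen=True)
class GaussianLaw:
    mu: float = -50.0
    sigma: float = 200.0

    def sample(self, rng: np.random.Generator, lo: int, hi: int) -> int:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        while True:
            x = rng.normal(self.mu, self.sigma)
            if lo <= x <= hi:
                return int(round(x))


@dataclass(frozen=True)
class UniformLaw:
    def sample(self, rng: np.random.Generator, lo: int, hi: int) -> int:
        return int(rng.integers(lo, hi + 1))


@dataclass(frozen=True)
class PointLaw:
    x: int = -50

    def sample(self, rng: np.random.Generator, lo: int, hi: int) -> int:
        if not lo <= self.x <= hi:
            raise ValueError(f"point law at {self.x} outside [{lo}, {hi}]")
        return self.x


# ---------------------------------------------------------------------------
# Spec and ground truth


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study.

    Rates are probabilities in [0, 1]; positions are TSS-relative bp.
    Defaults give the standard demo conditions: 200 genes, 10 motifs,
    sites from a Gaussian centred at -50 bp with sd 200 bp, 21
    expression samples.
    """

    n_genes: int = 200
    chrom_length: int | None = None  # default: n_genes * 3000 + 1000
    n_motifs: int = 10
    motif_width: int = 8
    site_position_law: GaussianLaw | UniformLaw | PointLaw = field(
        default_factory=GaussianLaw
    )
    plant_rate: float = 0.3
    conservation_rate: float = 0.9
    ortholog_identity_range: tuple[float, float] = (60.0, 95.0)
    orphan_rate: float = 0.1  # fraction of (gene, species) without an ortholog
    background_mutation_rate: float = 0.1
    indel_rate: float = 0.0  # per-bp probability of a small (<=3 bp) indel
    # sd (bp) of the displacement of a conserved site relative to its
    # homologous position in the ortholog promoter; 0 = verbatim in place
    conserved_site_shift_sd: float = 0.0
    coexpression_rate: float = 0.8
    n_samples: int = 21
    n_unexpressed_decoys: int = 5
    peak_jitter_sd: float = 50.0
    peak_length_mean: float = 300.0
    peak_length_sd: float = 30.0
    n_decoy_peaks: int = 20
    scan_alpha: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chrom_length is None:
            self.chrom_length = self.n_genes * _SLOT + 1000
        for name in (
            "plant_rate",
            "conservation_rate",
            "orphan_rate",
            "background_mutation_rate",
            "indel_rate",
            "coexpression_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if isinstance(self.site_position_law, GaussianLaw):
            if self.site_position_law.sigma <= 0:
                raise ValueError("site_position_law sigma must be > 0")
        if self.chrom_length < self.n_genes * _SLOT:
            raise ValueError(
                f"chrom_length {self.chrom_length} < n_genes * {_SLOT}"
            )
        if self.n_samples < 3:
            raise ValueError("n_samples must be >= 3")
        if self.motif_width < 4:
            raise ValueError("motif_width must be >= 4")


@dataclass(frozen=True)
class PlantedSite:
    gene_id: str
    motif_id: str
    position: int  # TSS-relative start, transcription orientation
    strand: str  # same | opposite
    instance: str  # the planted word, motif orientation
    conserved_in: frozenset[str]


@dataclass
class GroundTruth:
    planted_sites: list[PlantedSite]
    coexpressed_pairs: list[tuple[str, str]]


@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    genomes: dict[str, GenomeSet]
    genes: dict[str, list[GeneModel]]
    ortholog_table: pd.DataFrame
    motifs: list[MotifModel]
    expression: pd.DataFrame
    dhs_peaks: list[PeakInterval]
    chip_peaks: list[PeakInterval]
    ground_truth: GroundTruth

    @property
    def family_map(self) -> dict[str, str]:
        return {m.motif_id: m.family for m in self.motifs}

    @property
    def tf_family_map(self) -> dict[str, str]:
        return {m.tf_name: m.family for m in self.motifs}

    @property
    def tf_gene_map(self) -> dict[str, str]:
        """motif_id -> the gene id carrying its TF's expression profile."""
        return {m.motif_id: m.tf_name for m in self.motifs}


# ---------------------------------------------------------------------------
# Helpers


def _random_chromosome(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _gene_layout(n_genes: int) -> list[GeneModel]:
    """Alternating-strand genes, one per 3,000-bp slot, promoters disjoint."""
    genes = []
    for i in range(n_genes):
        gene_id = f"g{i:04d}"
        if i % 2 == 0:
            genes.append(GeneModel(gene_id, "chr1", "+", i * _SLOT + 2400))
        else:
            genes.append(GeneModel(gene_id, "chr1", "-", i * _SLOT + 599))
    return genes


def _transcript_to_genomic_start(gene: GeneModel, pos: int, width: int) -> int:
    """Genomic start of the width-bp transcript interval beginning at pos."""
    if gene.strand == "+":
        return gene.tss + pos
    return gene.tss - pos - width + 1


def _write_segment(
    chrom: np.ndarray, gene: GeneModel, pos: int, segment: str
) -> None:
    """Write a transcript-orientation segment at TSS-relative pos."""
    w = len(segment)
    if gene.strand == "-":
        segment = reverse_complement(segment)
    g0 = _transcript_to_genomic_start(gene, pos, w)
    chrom[g0 : g0 + w] = np.frombuffer(segment.encode(), dtype=np.uint8)


def _read_promoter(chrom: np.ndarray, gene: GeneModel) -> str:
    if gene.strand == "+":
        seq = chrom[gene.tss - _UPSTREAM : gene.tss + _DOWNSTREAM]
        return seq.tobytes().decode()
    seq = chrom[gene.tss - _DOWNSTREAM + 1 : gene.tss + _UPSTREAM + 1]
    return reverse_complement(seq.tobytes().decode())


def _random_motif(
    rng: np.random.Generator, motif_id: str, tf_name: str, family: str, width: int
) -> MotifModel:
    """A high-information PPM: one dominant base per column (prob 0.85-0.97)."""
    matrix = np.empty((width, 4))
    for i in range(width):
        dom = int(rng.integers(0, 4))
        p = float(rng.uniform(0.85, 0.97))
        rest = (1.0 - p) / 3.0
        matrix[i] = rest
        matrix[i, dom] = p
    return MotifModel(motif_id, tf_name, family, matrix)


def _sample_detectable_instance(
    rng: np.random.Generator, motif: MotifModel, pvt, sm, alpha: float
) -> str:
    """Sample a word from the PPM, rejecting until its scan p-value < alpha."""
    for _ in range(100):
        idx = [
            int(rng.choice(4, p=motif.matrix[i])) for i in range(motif.width)
        ]
        word = "".join("ACGT"[b] for b in idx)
        score = int(sm.log_odds[np.arange(motif.width), idx].sum())
        if pvt.pvalue(score) < alpha:
            return word
    return motif.consensus()


def _mutate(
    rng: np.random.Generator, seq: str, rate: float, protected: list[tuple[int, int]]
) -> list[str]:
    """Per-base substitution outside protected intervals; token list output."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    mask = rng.random(len(arr)) < rate
    for a, b in protected:
        mask[max(0, a) : b] = False
    for i in np.flatnonzero(mask):
        arr[i] = _BASES[rng.integers(0, 4)]
    return [chr(c) for c in arr]


def _apply_indels(
    rng: np.random.Generator,
    tokens: list[str],
    rate: float,
    protected: list[tuple[int, int]],
) -> list[str]:
    """Small (<=3 bp) insertions/deletions outside protected intervals.

    The TSS base (index ``_UPSTREAM``) is also protected so the anchor
    survives.
    """
    n = len(tokens)
    blocked = np.zeros(n, dtype=bool)
    for a, b in protected:
        blocked[max(0, a) : b] = True
    blocked[_UPSTREAM] = True
    hits = np.flatnonzero((rng.random(n) < rate) & ~blocked)
    for i in hits:
        size = int(rng.integers(1, 4))
        if rng.random() < 0.5:  # deletion of up to `size` unprotected bases
            for j in range(i, min(i + size, n)):
                if not blocked[j]:
                    tokens[j] = ""
        else:  # insertion after base i
            ins = "".join("ACGT"[b] for b in rng.integers(0, 4, size=size))
            tokens[i] = tokens[i] + ins
    return tokens


def _place_promoter(
    chrom: np.ndarray, gene: GeneModel, tokens: list[str]
) -> None:
    """Write a (possibly indel-bearing) promoter so its TSS base stays put."""
    upstream_len = sum(len(t) for t in tokens[:_UPSTREAM])
    prom = "".join(tokens)
    total = len(prom)
    if gene.strand == "+":
        g0 = gene.tss - upstream_len
        chrom[g0 : g0 + total] = np.frombuffer(prom.encode(), dtype=np.uint8)
    else:
        rc = reverse_complement(prom)
        g0 = gene.tss - (total - upstream_len) + 1
        chrom[g0 : g0 + total] = np.frombuffer(rc.encode(), dtype=np.uint8)


# ---------------------------------------------------------------------------
# Expression


def generate_expression(
    gene_ids: list[str],
    coexpressed_pairs: list[tuple[str, str]],
    n_samples: int = 21,
    rng: np.random.Generator | int = 0,
    unexpressed: set[str] | None = None,
) -> pd.DataFrame:
    """Raw-RPKM expression matrix with controlled co-expression.

    Each co-expressed pair's target profile is the TF profile rescaled
    plus small noise, shrunk until the realized Pearson correlation
    exceeds 0.9.  All other genes are drawn independently (log-normal),
    and every gene except the ``unexpressed`` decoys has RPKM > 1 in at
    least two samples.
    """
    if n_samples < 3:
        raise ValueError("n_samples must be >= 3")
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    unexpressed = unexpressed or set()
    gene_set = set(gene_ids)
    for tf, tgt in coexpressed_pairs:
        if tf not in gene_set or tgt not in gene_set:
            raise ValueError(f"co-expressed pair ({tf}, {tgt}) not in gene_ids")
    targets = {tgt: tf for tf, tgt in coexpressed_pairs}
    profiles: dict[str, np.ndarray] = {}

    def independent_profile() -> np.ndarray:
        while True:
            p = rng.lognormal(mean=1.0, sigma=1.0, size=n_samples)
            if (p > 1).sum() >= 2:
                return p

    for g in gene_ids:
        if g in targets:
            continue
        if g in unexpressed:
            profiles[g] = rng.uniform(0.0, 0.9, size=n_samples)
        else:
            profiles[g] = independent_profile()
    for tgt, tf in targets.items():
        base = profiles[tf] * float(rng.uniform(0.5, 2.0))
        noise_sd = 0.1 * base.std()
        for _ in range(20):
            prof = np.clip(base + rng.normal(0.0, noise_sd, size=n_samples), 0, None)
            pcc = np.corrcoef(profiles[tf], prof)[0, 1]
            if pcc > 0.9 and (prof > 1).sum() >= 2:
                break
            noise_sd /= 2.0
        profiles[tgt] = prof
    df = pd.DataFrame(
        {f"sample{j:02d}": [profiles[g][j] for g in gene_ids] for j in range(n_samples)},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return df


# ---------------------------------------------------------------------------
# Main generator


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate the full four-species dataset with ground truth.

    Deterministic given ``spec.seed``: two calls with equal specs produce
    identical objects and (via :func:`write_dataset`) identical files.
    """
    rng = np.random.default_rng(spec.seed)
    w = spec.motif_width
    query_genes = _gene_layout(spec.n_genes)

    # motif library
    n_fam = max(1, min(len(_FAMILY_POOL), spec.n_motifs // 2 + 1))
    motifs = [
        _random_motif(rng, f"m{i:02d}", f"TF{i:02d}", _FAMILY_POOL[i % n_fam], w)
        for i in range(spec.n_motifs)
    ]
    motif_by_id = {m.motif_id: m for m in motifs}
    scoring = {}
    for m in motifs:
        sm = build_scoring_matrix(m)
        scoring[m.motif_id] = (sm, exact_pvalues(sm))

    # query genome with planted sites
    chrom = _random_chromosome(rng, spec.chrom_length)
    pos_lo, pos_hi = -_UPSTREAM, _DOWNSTREAM - w
    occupied: dict[str, list[tuple[int, int]]] = {g.gene_id: [] for g in query_genes}
    planted: list[tuple[str, str, int, str, str]] = []
    for gene in query_genes:
        for m in motifs:
            if rng.random() >= spec.plant_rate:
                continue
            placed = None
            for _ in range(20):
                pos = spec.site_position_law.sample(rng, pos_lo, pos_hi)
                if all(
                    pos + w <= a or pos >= b for a, b in occupied[gene.gene_id]
                ):
                    placed = pos
                    break
            if placed is None:
                continue
            strand = "same" if rng.random() < 0.5 else "opposite"
            sm, pvt = scoring[m.motif_id]
            word = _sample_detectable_instance(rng, m, pvt, sm, spec.scan_alpha)
            segment = word if strand == "same" else reverse_complement(word)
            _write_segment(chrom, gene, placed, segment)
            occupied[gene.gene_id].append((placed, placed + w))
            planted.append((gene.gene_id, m.motif_id, placed, strand, word))

    genomes = {QUERY_SPECIES: GenomeSet(QUERY_SPECIES, {"chr1": chrom.tobytes().decode()})}
    genes = {QUERY_SPECIES: query_genes}

    # ortholog genomes: mutated promoter copies with controlled conservation
    has_ortholog: dict[tuple[str, str], bool] = {}
    for sp in REFERENCE_SPECIES:
        for gene in query_genes:
            has_ortholog[(gene.gene_id, sp)] = rng.random() >= spec.orphan_rate

    site_by_gene: dict[str, list[int]] = {}
    for idx, (gid, *_rest) in enumerate(planted):
        site_by_gene.setdefault(gid, []).append(idx)
    conserved_in: list[set[str]] = [set() for _ in planted]

    ortholog_rows = []
    for sp in REFERENCE_SPECIES:
        ref_chrom = _random_chromosome(rng, spec.chrom_length)
        ref_genes = []
        for gene in query_genes:
            ortho_id = f"{sp}_{gene.gene_id}"
            ref_genes.append(
                GeneModel(ortho_id, "chr1", gene.strand, gene.tss)
            )
            if not has_ortholog[(gene.gene_id, sp)]:
                continue
            identity = float(rng.uniform(*spec.ortholog_identity_range))
            ortholog_rows.append((gene.gene_id, sp, ortho_id, round(identity, 1)))
            if rng.random() < 0.5:  # low-identity decoy candidate
                ortholog_rows.append(
                    (
                        gene.gene_id,
                        sp,
                        f"{ortho_id}_decoy",
                        round(float(rng.uniform(20.0, 50.0)), 1),
                    )
                )
            prom = _read_promoter(chrom, gene)
            gene_sites = site_by_gene.get(gene.gene_id, [])
            taken = [
                (planted[s][2] + _UPSTREAM, planted[s][2] + _UPSTREAM + w)
                for s in gene_sites
            ]
            kept: list[tuple[int, int]] = []  # final site intervals, protected
            moved: list[tuple[int, int, str]] = []  # (old_start, new_start, seg)
            destroyed: list[int] = []
            for k, sidx in enumerate(gene_sites):
                _, motif_id, pos, strand, word = planted[sidx]
                start = pos + _UPSTREAM
                if rng.random() >= spec.conservation_rate:
                    destroyed.append(pos)
                    continue
                conserved_in[sidx].add(sp)
                delta = 0
                if spec.conserved_site_shift_sd > 0:
                    delta = int(round(rng.normal(0.0, spec.conserved_site_shift_sd)))
                    new_start = min(max(start + delta, 0), _WINDOW_LEN - w)
                    others = taken[:k] + taken[k + 1 :] + [
                        (a, b) for a, b in kept if (a, b) != (start, start + w)
                    ]
                    if any(new_start < b and new_start + w > a for a, b in others):
                        new_start = start  # collision with another site
                    delta = new_start - start
                if delta == 0:
                    kept.append((start, start + w))
                else:
                    # a shifted conserved site is an independent occurrence:
                    # resample its instance so the displacement is absorbed
                    # as mismatches, not as an alignment gap
                    sm, pvt = scoring[motif_id]
                    motif = motif_by_id[motif_id]
                    new_word = _sample_detectable_instance(
                        rng, motif, pvt, sm, spec.scan_alpha
                    )
                    seg = new_word if strand == "same" else reverse_complement(new_word)
                    moved.append((start, start + delta, seg))
                    kept.append((start + delta, start + delta + w))
                    taken[k] = (start + delta, start + delta + w)
            tokens = _mutate(rng, prom, spec.background_mutation_rate, kept)
            for old_start, new_start, seg in moved:
                # vacate the homologous location, re-plant the site shifted
                for j in range(w):
                    tokens[old_start + j] = "ACGT"[int(rng.integers(0, 4))]
                for j, c in enumerate(seg):
                    tokens[new_start + j] = c
            for pos in destroyed:
                fresh = "".join(
                    "ACGT"[b] for b in rng.integers(0, 4, size=w)
                )
                start = pos + _UPSTREAM
                for j, c in enumerate(fresh):
                    tokens[start + j] = c
            if spec.indel_rate > 0:
                tokens = _apply_indels(rng, tokens, spec.indel_rate, kept)
            _place_promoter(ref_chrom, ref_genes[-1], tokens)
        genomes[sp] = GenomeSet(sp, {"chr1": ref_chrom.tobytes().decode()})
        genes[sp] = ref_genes

    ortholog_table = pd.DataFrame(
        ortholog_rows,
        columns=["query_gene", "species", "ortholog_gene", "percent_identity"],
    )

    planted_sites = [
        PlantedSite(gid, mid, pos, strand, word, frozenset(conserved_in[i]))
        for i, (gid, mid, pos, strand, word) in enumerate(planted)
    ]

    # expression: TF genes + query genes + unexpressed decoys
    tf_genes = [m.tf_name for m in motifs]
    decoys = [f"unexpr{i:02d}" for i in range(spec.n_unexpressed_decoys)]
    expr_genes = tf_genes + [g.gene_id for g in query_genes] + decoys
    pairs: list[tuple[str, str]] = []
    paired_targets: set[str] = set()
    tf_of = {m.motif_id: m.tf_name for m in motifs}
    for site in planted_sites:
        if site.gene_id in paired_targets:
            continue  # one co-expression driver per target gene
        if rng.random() < spec.coexpression_rate:
            pairs.append((tf_of[site.motif_id], site.gene_id))
            paired_targets.add(site.gene_id)
    expression = generate_expression(
        expr_genes, pairs, n_samples=spec.n_samples, rng=rng, unexpressed=set(decoys)
    )

    # peaks: one per fully conserved site, plus random decoys
    all_refs = set(REFERENCE_SPECIES)
    dhs_peaks: list[PeakInterval] = []
    chip_peaks: list[PeakInterval] = []
    gene_by_id = {g.gene_id: g for g in query_genes}
    for site in planted_sites:
        if site.conserved_in != all_refs:
            continue
        gene = gene_by_id[site.gene_id]
        center_t = site.position + w // 2
        center = (
            gene.tss + center_t if gene.strand == "+" else gene.tss - center_t
        )
        for sink, source, tf in (
            (dhs_peaks, "DHS", None),
            (chip_peaks, "ChIP", tf_of[site.motif_id]),
        ):
            c = center + int(round(rng.normal(0.0, spec.peak_jitter_sd)))
            length = max(50, int(round(rng.normal(spec.peak_length_mean,
                                                  spec.peak_length_sd))))
            start = max(0, c - length // 2)
            end = min(spec.chrom_length, start + length)
            sink.append(PeakInterval("chr1", start, end, source, tf))
    for _ in range(spec.n_decoy_peaks):
        length = max(50, int(round(rng.normal(spec.peak_length_mean,
                                              spec.peak_length_sd))))
        start = int(rng.integers(0, max(1, spec.chrom_length - length)))
        dhs_peaks.append(PeakInterval("chr1", start, start + length, "DHS", None))

    return SyntheticDataset(
        spec=spec,
        genomes=genomes,
        genes=genes,
        ortholog_table=ortholog_table,
        motifs=motifs,
        expression=expression,
        dhs_peaks=dhs_peaks,
        chip_peaks=chip_peaks,
        ground_truth=GroundTruth(planted_sites, pairs),
    )


# ---------------------------------------------------------------------------
# Serialization


def write_dataset(ds: SyntheticDataset, outdir) -> dict[str, Path]:
    """Write the dataset in the pipeline's input formats; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for sp, genome in ds.genomes.items():
        p = outdir / f"{sp}.fasta"
        write_fasta(genome, p)
        paths[f"fasta:{sp}"] = p
        p = outdir / f"{sp}.gff3"
        write_gff3_genes(ds.genes[sp], p)
        paths[f"gff3:{sp}"] = p
    paths["motifs"] = outdir / "motifs.meme"
    write_meme_motifs(ds.motifs, paths["motifs"])
    paths["orthologs"] = outdir / "orthologs.tsv"
    write_ortholog_table(ds.ortholog_table, paths["orthologs"])
    paths["expression"] = outdir / "expression.tsv"
    write_expression_tsv(ds.expression, paths["expression"])
    paths["dhs"] = outdir / "dhs_peaks.bed"
    write_bed_peaks(ds.dhs_peaks, paths["dhs"])
    paths["chip"] = outdir / "chip_peaks.bed"
    write_bed_peaks(ds.chip_peaks, paths["chip"])
    paths["ground_truth"] = outdir / "ground_truth.tsv"
    with open(paths["ground_truth"], "w") as fh:
        fh.write("gene_id\tmotif_id\tposition\tstrand\tinstance\tconserved_in\n")
        for s in ds.ground_truth.planted_sites:
            fh.write(
                f"{s.gene_id}\t{s.motif_id}\t{s.position}\t{s.strand}\t"
                f"{s.instance}\t{','.join(sorted(s.conserved_in))}\n"
            )
    paths["coexpressed"] = outdir / "coexpressed_pairs.tsv"
    with open(paths["coexpressed"], "w") as fh:
        fh.write("tf_gene\ttarget_gene\n")
        for tf, tgt in ds.ground_truth.coexpressed_pairs:
            fh.write(f"{tf}\t{tgt}\n")
    return paths
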