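import numpy as np
import pytest

from posdist.conservation import (
    align_promoters,
    drop_genes_without_full_orthology,
    extract_promoter,
    make_aligner,
    motif_passes_conservation,
    position_shift_distribution,
    select_ortholog,
    ConservedHit,
    PromoterRecord,
)
from posdist.conservation import test_conservation as conservation_test
from posdist.io_formats import GeneModel, GenomeSet
from posdist.motif_scan import MotifHit, reverse_complement
from posdist.pipeline import PipelineConfig, scan_and_conserve
from posdist.synthetic_data import SyntheticSpec, generate_dataset


# ---------------------------------------------------------------------------
# Ortholog selection


class TestSelectOrtholog:
    def test_identity_at_or_below_50_rejected(self):
        a = select_ortholog("g", "ref1", [("x", 40.0)])
        assert a.ortholog is None
        assert select_ortholog("g", "ref1", [("x", 50.0)]).ortholog is None

    def test_highest_identity_wins(self):
        a = select_ortholog("g", "ref1", [("g1", 60.0), ("g2", 75.0)])
        assert a.ortholog == "g2" and a.identity == 75.0

    def test_tie_breaks_lexicographically(self):
        a = select_ortholog("g", "ref1", [("g2", 70.0), ("g1", 70.0)])
        assert a.ortholog == "g1"


class TestDropGenes:
    REFS = ["ref1", "ref2", "ref3"]

    def _assign(self, gene, species_with):
        from posdist.conservation import OrthologAssignment

        return {
            (gene, sp): OrthologAssignment(
                gene, sp, f"{sp}_{gene}" if sp in species_with else None,
                70.0 if sp in species_with else None,
            )
            for sp in self.REFS
        }

    def test_partial_orthology_dropped(self):
        a = self._assign("g", ["ref1", "ref2"])
        assert drop_genes_without_full_orthology(a, self.REFS) == set()

    def test_full_orthology_retained(self):
        a = self._assign("g", self.REFS)
        assert drop_genes_without_full_orthology(a, self.REFS) == {"g"}

    def test_no_orthology_dropped(self):
        a = self._assign("g", [])
        assert drop_genes_without_full_orthology(a, self.REFS) == set()


# ---------------------------------------------------------------------------
# Promoter extraction


class TestExtractPromoter:
    @pytest.fixture
    def genome(self):
        rng = np.random.default_rng(0)
        return GenomeSet("sp", {"chr1": "".join(rng.choice(list("ACGT"), 8000))})

    def test_plus_strand_window(self, genome):
        gene = GeneModel("g", "chr1", "+", 5000)
        rec = extract_promoter(gene, genome)
        assert rec.sequence == genome.sequences["chr1"][3000:5200]
        assert (rec.window_start, rec.window_end) == (-2000, 200)
        assert not rec.truncated

    def test_minus_strand_window(self, genome):
        gene = GeneModel("g", "chr1", "-", 5000)
        rec = extract_promoter(gene, genome)
        assert rec.sequence == reverse_complement(
            genome.sequences["chr1"][4801:7001]
        )
        assert not rec.truncated

    def test_tss_base_is_at_window_offset_2000(self, genome):
        chrom = genome.sequences["chr1"]
        plus = extract_promoter(GeneModel("g", "chr1", "+", 5000), genome)
        assert plus.sequence[2000] == chrom[5000]
        minus = extract_promoter(GeneModel("g", "chr1", "-", 5000), genome)
        assert minus.sequence[2000] == reverse_complement(chrom[5000])

    def test_truncation_at_chromosome_start(self, genome):
        rec = extract_promoter(GeneModel("g", "chr1", "+", 100), genome)
        assert rec.truncated and len(rec.sequence) == 300
        assert rec.window_start == -100

    def test_missing_chromosome_errors(self, genome):
        with pytest.raises(KeyError):
            extract_promoter(GeneModel("g", "chrX", "+", 10), genome)


# ---------------------------------------------------------------------------
# Alignment


def _gotoh_score(a, b, match=5, mismatch=-4, gap_open=-10, gap_extend=-0.5):
    """Affine-gap global alignment score, plain O(n*m) oracle."""
    inf = float("inf")
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), -inf)
    X = np.full((n + 1, m + 1), -inf)  # gap in b (deletion)
    Y = np.full((n + 1, m + 1), -inf)  # gap in a (insertion)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend)
    return max(M[n, m], X[n, m], Y[n, m])


def _record(gene_id, species, seq, ws=0):
    return PromoterRecord(gene_id, species, seq, ws, ws + len(seq))


class TestAlignPromoters:
    def test_identical_sequences_identity_map(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), 300))
        pa = align_promoters(
            _record("g", "query", seq), {"ref1": _record("g", "ref1", seq)}
        )
        pair = pa.pairs["ref1"]
        assert (pair.col_of_query == np.arange(300)).all()
        assert (pair.col_of_ortho == np.arange(300)).all()

    def test_insertion_shifts_downstream_columns(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), 2000))
        ins = seq[:1000] + "ACGTA" + seq[1000:]
        pa = align_promoters(
            _record("g", "query", seq), {"ref1": _record("g", "ref1", ins)}
        )
        pair = pa.pairs["ref1"]
        # upstream of the insertion the maps agree; downstream the query
        # columns are shifted by exactly 5
        assert (pair.col_of_query[:995] == np.arange(995)).all()
        assert (pair.col_of_query[1005:] == np.arange(1005, 2000) + 5).all()

    def test_substitutions_only_gives_gap_free_alignment(self):
        rng = np.random.default_rng(3)
        seq = list("".join(rng.choice(list("ACGT"), 500)))
        mut = seq.copy()
        for i in rng.choice(500, size=50, replace=False):
            mut[i] = rng.choice(list("ACGT"))
        pa = align_promoters(
            _record("g", "query", "".join(seq)),
            {"ref1": _record("g", "ref1", "".join(mut))},
        )
        pair = pa.pairs["ref1"]
        assert (pair.col_of_query == np.arange(500)).all()

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_alignment_score_is_optimal(self, seed):
        """Aligner score equals the exhaustive affine-gap DP on 50-mers."""
        rng = np.random.default_rng(seed)
        a = "".join(rng.choice(list("ACGT"), 50))
        b = list(a)
        for i in rng.choice(50, size=10, replace=False):
            b[i] = rng.choice(list("ACGT"))
        if seed % 2:
            b = b[:20] + ["A", "C"] + b[20:]  # small insertion
        b = "".join(b)
        aligner = make_aligner()
        assert aligner.align(a, b).score == pytest.approx(_gotoh_score(a, b))

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            align_promoters(
                _record("g", "query", "ACGT"),
                {"ref1": PromoterRecord("g", "ref1", "", 0, 0)},
            )


# ---------------------------------------------------------------------------
# Conservation test


def _hit(motif="m0", gene="g", start=-50, strand="same", width=8):
    return MotifHit(motif, gene, start, strand, 12.0, 1e-5, width)


def _aligned_records(seq, ortho_seqs):
    q = _record("g", "query", seq, ws=-2000)
    orecs = {sp: _record("g", sp, s, ws=-2000) for sp, s in ortho_seqs.items()}
    return align_promoters(q, orecs)


class TestConservationRule:
    @pytest.fixture
    def identical_alignment(self):
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGT"), 2200))
        return _aligned_records(seq, {sp: seq for sp in ("ref1", "ref2", "ref3")})

    def test_identical_promoters_pass_with_zero_shift(self, identical_alignment):
        hit = _hit()
        ortho_hits = {sp: [_hit(gene="o")] for sp in ("ref1", "ref2", "ref3")}
        ch = conservation_test(hit, identical_alignment, ortho_hits)
        assert ch.passed
        assert all(s == 0 for s in ch.shifts.values())

    def test_hit_beyond_tolerance_fails_that_species(self, identical_alignment):
        hit = _hit()
        ortho_hits = {
            "ref1": [_hit(start=-50 + 150)],  # 150 columns away
            "ref2": [_hit()],
            "ref3": [_hit()],
        }
        ch = conservation_test(hit, identical_alignment, ortho_hits)
        assert not ch.passed and ch.conserved_in == {"ref2", "ref3"}

    def test_hit_at_exact_tolerance_passes(self, identical_alignment):
        hit = _hit()
        ortho_hits = {
            "ref1": [_hit(start=-50 + 100)],
            "ref2": [_hit()],
            "ref3": [_hit()],
        }
        ch = conservation_test(hit, identical_alignment, ortho_hits)
        assert ch.passed and ch.shifts["ref1"] == 100

    def test_opposite_strand_fails(self, identical_alignment):
        hit = _hit()
        ortho_hits = {
            "ref1": [_hit(strand="opposite")],
            "ref2": [_hit()],
            "ref3": [_hit()],
        }
        assert not conservation_test(hit, identical_alignment, ortho_hits).passed

    def test_different_motif_does_not_count(self, identical_alignment):
        hit = _hit()
        ortho_hits = {
            "ref1": [_hit(motif="other")],
            "ref2": [_hit()],
            "ref3": [_hit()],
        }
        assert not conservation_test(hit, identical_alignment, ortho_hits).passed

    def test_tolerance_monotonicity(self, identical_alignment):
        """The passed set at tolerance 100 contains the passed set at any
        smaller tolerance."""
        hit = _hit()
        rng = np.random.default_rng(5)
        for _ in range(20):
            off = int(rng.integers(-130, 131))
            ortho_hits = {
                sp: [_hit(start=-50 + off)] for sp in ("ref1", "ref2", "ref3")
            }
            small = conservation_test(hit, identical_alignment, ortho_hits, 30)
            large = conservation_test(hit, identical_alignment, ortho_hits, 100)
            if small.passed:
                assert large.passed


class TestMotifPassAndShifts:
    def _conserved(self, motif, passed, shifts=(0, 0, 0)):
        return ConservedHit(
            _hit(motif=motif),
            {"ref1", "ref2", "ref3"} if passed else set(),
            dict(zip(("ref1", "ref2", "ref3"), shifts)),
            passed,
        )

    def test_motif_with_passed_hit_passes(self):
        chs = [self._conserved("m0", True), self._conserved("m0", False)]
        assert motif_passes_conservation("m0", chs)

    def test_motif_without_passed_hits_fails(self):
        assert not motif_passes_conservation("m0", [self._conserved("m0", False)])

    def test_shift_fractions(self):
        chs = [
            self._conserved("m0", True, (0, 0, 5)),
            self._conserved("m0", True, (12, 0, 0)),
        ]
        d = position_shift_distribution(chs)
        # shifts pooled: {0,0,5,12,0,0} -> 4/6, 1/6, 1/6
        assert d["0"] == pytest.approx(4 / 6)
        assert d["1-10"] == pytest.approx(1 / 6)
        assert d[">10"] == pytest.approx(1 / 6)
        assert sum(d.values()) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# End-to-end recall on synthetic data


def _planted_recall(ds, stage):
    """Fraction of planted sites (in retained genes) recovered as passed."""
    retained = {g.gene_id for g in stage.retained_genes}
    passed = {
        (c.hit.gene_id, c.hit.motif_id, c.hit.tss_relative_start, c.hit.strand)
        for c in stage.conserved_hits
        if c.passed
    }
    truth = [
        (s.gene_id, s.motif_id, s.position, s.strand)
        for s in ds.ground_truth.planted_sites
        if s.gene_id in retained
    ]
    assert truth
    return sum(1 for t in truth if t in passed) / len(truth)


class TestPlantedSiteRecall:
    def test_full_conservation_gives_full_recall(self):
        spec = SyntheticSpec(
            seed=11, n_genes=20, n_motifs=3, conservation_rate=1.0,
            orphan_rate=0.0, background_mutation_rate=0.0,
        )
        ds = generate_dataset(spec)
        stage = scan_and_conserve(
            PipelineConfig(), ds.genomes, ds.genes, ds.motifs, ds.ortholog_table
        )
        assert _planted_recall(ds, stage) == 1.0

    def test_zero_conservation_gives_zero_pass(self):
        spec = SyntheticSpec(
            seed=12, n_genes=20, n_motifs=3, conservation_rate=0.0,
            orphan_rate=0.0,
        )
        ds = generate_dataset(spec)
        stage = scan_and_conserve(
            PipelineConfig(), ds.genomes, ds.genes, ds.motifs, ds.ortholog_table
        )
        assert _planted_recall(ds, stage) == 0.0

    def test_strand_flip_leaves_passed_set_invariant(self):
        """Reverse-complementing every genome and flipping every gene's
        strand must not change which hits pass or their positions."""
        spec = SyntheticSpec(
            seed=13, n_genes=10, n_motifs=2, orphan_rate=0.0,
        )
        ds = generate_dataset(spec)
        config = PipelineConfig()

        def passed_set(genomes, genes):
            stage = scan_and_conserve(
                config, genomes, genes, ds.motifs, ds.ortholog_table
            )
            return {
                (c.hit.gene_id, c.hit.motif_id, c.hit.tss_relative_start,
                 c.hit.strand)
                for c in stage.conserved_hits
                if c.passed
            }

        flipped_genomes = {
            sp: GenomeSet(
                sp, {c: reverse_complement(s) for c, s in g.sequences.items()}
            )
            for sp, g in ds.genomes.items()
        }
        flipped_genes = {
            sp: [
                GeneModel(
                    g.gene_id,
                    g.chromosome,
                    "-" if g.strand == "+" else "+",
                    len(ds.genomes[sp].sequences[g.chromosome]) - 1 - g.tss,
                )
                for g in gl
            ]
            for sp, gl in ds.genes.items()
        }
        assert passed_set(ds.genomes, ds.genes) == passed_set(
            flipped_genomes, flipped_genes
        )

    def test_site_shift_mode_produces_nonzero_shifts(self):
        spec = SyntheticSpec(
            seed=14, n_genes=15, n_motifs=2, orphan_rate=0.0,
            conservation_rate=1.0, indel_rate=0.002,
            conserved_site_shift_sd=4.0,
        )
        ds = generate_dataset(spec)
        stage = scan_and_conserve(
            PipelineConfig(), ds.genomes, ds.genes, ds.motifs, ds.ortholog_table
        )
        d = position_shift_distribution(stage.conserved_hits)
        assert d["0"] < 1.0
        assert sum(d.values()) == pytest.approx(1.0)
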