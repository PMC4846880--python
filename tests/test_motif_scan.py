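import itertools

import numpy as np
import pytest

from posdist.io_formats import MotifModel
from posdist.motif_scan import (
    PValueTable,
    ScoringMatrix,
    build_scoring_matrix,
    encode_sequence,
    exact_pvalues,
    reverse_complement,
    scan_promoter,
)


def brute_force_sf(sm: ScoringMatrix) -> dict[int, float]:
    """Exhaustive survival function over all 4^w background words."""
    lo = sm.log_odds[:, :4]
    w = sm.width
    probs: dict[int, float] = {}
    for word in itertools.product(range(4), repeat=w):
        s = int(sum(lo[i, b] for i, b in enumerate(word)))
        p = float(np.prod([sm.background[b] for b in word]))
        probs[s] = probs.get(s, 0.0) + p
    sf = {}
    for s in probs:
        sf[s] = sum(p for s2, p in probs.items() if s2 >= s)
    return sf


def random_motif(rng, width):
    return MotifModel(
        f"w{width}", "TF", "fam", rng.dirichlet(np.ones(4) * 0.5, size=width)
    )


class TestScoringMatrix:
    def test_uniform_row_scores_zero(self, uniform_motif):
        sm = build_scoring_matrix(uniform_motif, pseudocount=0.0)
        assert (sm.log_odds[:, :4] == 0).all()

    def test_sign_of_preferred_base(self):
        m = MotifModel(
            "m", "t", "f", np.array([[1.0, 0, 0, 0]] + [[0.25] * 4] * 3)
        )
        sm = build_scoring_matrix(m, pseudocount=0.1)
        assert sm.log_odds[0, 0] > 0 > sm.log_odds[0, 1]

    def test_n_column_scores_zero(self, sharp_motif):
        sm = build_scoring_matrix(sharp_motif)
        assert (sm.log_odds[:, 4] == 0).all()

    def test_zero_pseudocount_with_zero_prob_errors(self):
        m = MotifModel("m", "t", "f", np.array([[1.0, 0, 0, 0]] * 4))
        with pytest.raises(ValueError):
            build_scoring_matrix(m, pseudocount=0.0)

    @pytest.mark.parametrize("width", [4, 5, 6])
    def test_consensus_achieves_maximum_score(self, width):
        rng = np.random.default_rng(width)
        m = random_motif(rng, width)
        sm = build_scoring_matrix(m)
        lo = sm.log_odds[:, :4]
        consensus_score = sum(
            lo[i, "ACGT".index(c)] for i, c in enumerate(m.consensus())
        )
        best = max(
            sum(lo[i, b] for i, b in enumerate(word))
            for word in itertools.product(range(4), repeat=width)
        )
        assert consensus_score == best


class TestExactPValues:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("width", [4, 5, 6])
    def test_matches_exhaustive_enumeration(self, width, seed):
        rng = np.random.default_rng(100 * width + seed)
        sm = build_scoring_matrix(random_motif(rng, width))
        pvt = exact_pvalues(sm)
        for s, p in brute_force_sf(sm).items():
            assert pvt.pvalue(s) == pytest.approx(p, abs=1e-12)

    def test_single_position_top_score(self):
        # one informative position with four distinct scores: the top
        # score is reached by exactly one of four equiprobable bases
        lo = np.zeros((1, 5), dtype=np.int64)
        lo[0, :4] = [300, 200, 100, -600]
        sm = ScoringMatrix("w1", lo, 1000, np.full(4, 0.25))
        pvt = exact_pvalues(sm)
        assert pvt.pvalue(300) == pytest.approx(0.25)
        assert pvt.pvalue(200) == pytest.approx(0.5)

    def test_minimum_score_has_pvalue_one(self, sharp_motif):
        sm = build_scoring_matrix(sharp_motif)
        pvt = exact_pvalues(sm)
        assert pvt.pvalue(pvt.min_score) == 1.0

    def test_sf_monotone_non_increasing(self, sharp_motif):
        pvt = exact_pvalues(build_scoring_matrix(sharp_motif))
        assert (np.diff(pvt.sf) <= 1e-15).all()

    def test_non_uniform_background(self):
        rng = np.random.default_rng(5)
        m = random_motif(rng, 5)
        bg = np.array([0.4, 0.1, 0.1, 0.4])
        sm = build_scoring_matrix(m, background=bg)
        pvt = exact_pvalues(sm)
        for s, p in brute_force_sf(sm).items():
            assert pvt.pvalue(s) == pytest.approx(p, abs=1e-12)


def _random_promoter(rng, n=2200):
    return "".join(rng.choice(list("ACGT"), n))


class TestScanPromoter:
    def test_planted_consensus_reported_at_minus_50(self, sharp_motif):
        rng = np.random.default_rng(0)
        sm = build_scoring_matrix(sharp_motif)
        pvt = exact_pvalues(sm)
        prom = _random_promoter(rng)
        cons = sharp_motif.consensus()
        prom = prom[:1950] + cons + prom[1950 + len(cons):]
        hits = scan_promoter(prom, sm, pvt, gene_id="g")
        assert any(h.tss_relative_start == -50 and h.strand == "same" for h in hits)

    def test_all_n_promoter_has_no_hits(self, sharp_motif):
        sm = build_scoring_matrix(sharp_motif)
        pvt = exact_pvalues(sm)
        assert scan_promoter("N" * 2200, sm, pvt) == []

    def test_reverse_complemented_site_is_opposite_strand(self, sharp_motif):
        rng = np.random.default_rng(1)
        sm = build_scoring_matrix(sharp_motif)
        pvt = exact_pvalues(sm)
        prom = _random_promoter(rng)
        site = reverse_complement(sharp_motif.consensus())
        prom = prom[:1950] + site + prom[1950 + len(site):]
        hits = scan_promoter(prom, sm, pvt)
        assert any(
            h.tss_relative_start == -50 and h.strand == "opposite" for h in hits
        )

    def test_short_promoter_warns_and_returns_empty(self, sharp_motif):
        sm = build_scoring_matrix(sharp_motif)
        pvt = exact_pvalues(sm)
        with pytest.warns(UserWarning):
            assert scan_promoter("ACG", sm, pvt, window_start=0) == []

    def test_reverse_complement_mirror_symmetry(self, sharp_motif):
        """Scanning a sequence and its reverse complement yields mirrored
        hit sets: position p <-> L - w - p with strands swapped."""
        rng = np.random.default_rng(2)
        sm = build_scoring_matrix(sharp_motif)
        pvt = exact_pvalues(sm)
        L = 500
        seq = "".join(rng.choice(list("ACGT"), L))
        cons = sharp_motif.consensus()
        seq = seq[:100] + cons + seq[100 + len(cons):]
        fwd = scan_promoter(seq, sm, pvt, alpha=1e-3, window_start=0)
        rev = scan_promoter(
            reverse_complement(seq), sm, pvt, alpha=1e-3, window_start=0
        )
        flip = {"same": "opposite", "opposite": "same"}
        mirrored = {
            (L - sm.width - h.tss_relative_start, flip[h.strand], h.score)
            for h in fwd
        }
        assert {(h.tss_relative_start, h.strand, h.score) for h in rev} == mirrored

    def test_pvalue_non_increasing_in_score(self, small_dataset):
        m = small_dataset.motifs[0]
        sm = build_scoring_matrix(m)
        pvt = exact_pvalues(sm)
        rng = np.random.default_rng(3)
        hits = scan_promoter(_random_promoter(rng), sm, pvt, alpha=0.5)
        hits.sort(key=lambda h: h.score)
        for a, b in zip(hits, hits[1:]):
            assert a.p_value >= b.p_value

    def test_background_hit_rate_matches_exact_null(self, sharp_motif):
        """On i.i.d. uniform sequence the per-window hit probability equals
        the exact null mass below alpha; the observed count over 10,000
        promoters must fall within 3 binomial SEs (and below the alpha
        upper bound)."""
        rng = np.random.default_rng(42)
        sm = build_scoring_matrix(sharp_motif)
        pvt = exact_pvalues(sm)
        alpha = 1e-4
        # exact per-window null probability: largest sf value < alpha
        p_star = float(pvt.sf[pvt.sf < alpha][0])
        assert p_star < alpha
        n_prom, L = 10_000, 2200
        w = sm.width
        codes = rng.integers(0, 4, size=(n_prom, L))
        total = 0
        for matrix in (sm, sm.reverse_complement()):
            scores = np.zeros((n_prom, L - w + 1), dtype=np.int64)
            for i in range(w):
                scores += matrix.log_odds[i, codes[:, i : i + L - w + 1]]
            total += int((pvt.pvalues(scores) < alpha).sum())
        n_windows = 2 * n_prom * (L - w + 1)
        expected = n_windows * p_star
        se = np.sqrt(n_windows * p_star * (1 - p_star))
        assert abs(total - expected) <= 3 * se
        assert total <= n_windows * alpha + 3 * np.sqrt(n_windows * alpha)


def test_encode_sequence_maps_unknown_to_n():
    assert encode_sequence("ACGTNX").tolist() == [0, 1, 2, 3, 4, 4]
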