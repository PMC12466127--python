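"""PWM construction, relative-score scanning, and affinity-shift calls."""

import math

import numpy as np
import pytest

from enhancerscan import (
    PFM,
    affinity_shift,
    build_pwm,
    rank_top_k,
    read_jaspar,
    relative_score,
    revcomp,
    scan_variant,
    write_jaspar,
)
from enhancerscan.simulate import (
    generate_annotations,
    generate_cohorts,
    generate_genome,
    generate_pwms,
    generate_snvs,
)

BASES = "ACGT"


# ---------------------------------------------------------------------------
# independent brute-force oracle (simple loops, own min/max computation)
# ---------------------------------------------------------------------------

def naive_relative_score(weights, window, must_cover):
    """Exhaustive (offset x strand) scan with explicit loops; N scores 0."""
    L = weights.shape[1]

    def raw(seq, offset):
        total = 0.0
        for j in range(L):
            base = seq[offset + j]
            total += 0.0 if base == "N" else weights[BASES.index(base), j]
        return total

    s_min = sum(min(weights[b, j] for b in range(4)) for j in range(L))
    s_max = sum(max(weights[b, j] for b in range(4)) for j in range(L))
    best = -math.inf
    for offset in range(len(window) - L + 1):
        if offset <= must_cover <= offset + L - 1:
            best = max(best, raw(window, offset))
    rc = revcomp(window)
    rc_cover = len(window) - 1 - must_cover
    for offset in range(len(rc) - L + 1):
        if offset <= rc_cover <= offset + L - 1:
            best = max(best, raw(rc, offset))
    return min(1.0, max(0.0, (best - s_min) / (s_max - s_min)))


def random_pfm(rng, length):
    counts = np.zeros((4, length))
    for j in range(length):
        counts[:, j] = rng.integers(1, 40, size=4)
    return PFM(f"RND{length}", f"RND{length}.1", counts)


def random_window(rng, n=15):
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


class TestBuildPwm:
    def test_uninformative_motif_rejected(self):
        pfm = PFM("FLAT", "FLAT.1", np.full((4, 4), 5.0))
        with pytest.raises(ValueError, match="degenerate"):
            build_pwm(pfm)

    def test_weights_match_hand_computation(self):
        # column counts A/C/G/T = [8, 2, 0, 0]; pseudocount 0.25 per cell
        counts = np.array(
            [[8, 0, 0, 8], [2, 0, 2, 2], [0, 2, 8, 0], [0, 8, 0, 0]],
            dtype=float,
        )
        pwm = build_pwm(PFM("HAND", "HAND.1", counts))
        # hand-computed first column: colsum 10, denominator 10 + 1
        assert pwm.weights[0, 0] == pytest.approx(math.log2((8.25 / 11) / 0.25))
        assert pwm.weights[1, 0] == pytest.approx(math.log2((2.25 / 11) / 0.25))
        assert pwm.weights[2, 0] == pytest.approx(math.log2((0.25 / 11) / 0.25))
        # score range equals the column-wise extremes
        assert pwm.s_max == pytest.approx(pwm.weights.max(axis=0).sum())
        assert pwm.s_min == pytest.approx(pwm.weights.min(axis=0).sum())
        assert pwm.consensus == "ATGA"

    def test_column_scaling_invariance_at_vanishing_pseudocount(self):
        counts = np.array(
            [[8, 1, 1, 1], [2, 1, 1, 1], [1, 8, 1, 1], [1, 1, 8, 8]],
            dtype=float,
        )
        pwm1 = build_pwm(PFM("S", "S.1", counts), pseudocount=1e-9)
        scaled = counts.copy()
        scaled[:, 0] *= 10
        pwm2 = build_pwm(PFM("S", "S.1", scaled), pseudocount=1e-9)
        assert np.allclose(pwm1.weights[:, 0], pwm2.weights[:, 0], atol=1e-6)

    def test_matches_biopython_log_odds(self):
        # independent route: Bio.motifs normalize + log_odds
        from Bio import motifs as bio_motifs

        rng = np.random.default_rng(7)
        counts = rng.integers(0, 30, size=(4, 6)).astype(float)
        counts[0, :] += 1  # keep every column sum positive
        motif = bio_motifs.Motif(
            counts={b: list(counts[i]) for i, b in enumerate(BASES)},
            alphabet="ACGT",
        )
        pssm = motif.counts.normalize(pseudocounts=0.25).log_odds(
            {b: 0.25 for b in BASES}
        )
        pwm = build_pwm(PFM("BIO", "BIO.1", counts))
        for i, b in enumerate(BASES):
            for j in range(6):
                assert pwm.weights[i, j] == pytest.approx(pssm[b][j], rel=1e-9)

    def test_invalid_inputs(self):
        counts = np.ones((4, 5))
        with pytest.raises(ValueError):
            build_pwm(PFM("X", "X.1", counts), pseudocount=0)
        with pytest.raises(ValueError):
            build_pwm(PFM("X", "X.1", counts), background=(0.5, 0.5, 0.1, 0.1))
        with pytest.raises(ValueError, match="column sum"):
            PFM("Z", "Z.1", np.zeros((4, 4)))


class TestRelativeScore:
    def _informative_pwm(self, consensus="ACGT"):
        counts = np.full((4, len(consensus)), 1.0)
        for j, b in enumerate(consensus):
            counts[BASES.index(b), j] = 50
        return build_pwm(PFM("TOY", "TOY.1", counts))

    def test_consensus_scores_one(self):
        pwm = self._informative_pwm("ACGT")
        rel, _, strand = relative_score(pwm, "AAAAAACGTAAAAAA", must_cover=7)
        assert rel == pytest.approx(1.0)
        assert strand == "+"

    def test_anti_consensus_scores_zero(self):
        # C and G share the minimal weight in every column, so an all-C
        # window is per-column-worst on the forward strand and its reverse
        # complement (all G) is per-column-worst too: both strands at S_min
        counts = np.tile(np.array([[50.0], [1.0], [1.0], [10.0]]), (1, 4))
        pwm = build_pwm(PFM("ANTI", "ANTI.1", counts))
        rel, _, _ = relative_score(pwm, "C" * 15, must_cover=7)
        assert rel == pytest.approx(0.0)

    def test_motif_longer_than_window_rejected(self):
        pwm = self._informative_pwm("ACGTACGT")
        with pytest.raises(ValueError, match="TOY"):
            relative_score(pwm, "ACGTA", must_cover=2)

    @pytest.mark.parametrize("length", [4, 5, 6])
    def test_matches_exhaustive_scan_oracle(self, length):
        rng = np.random.default_rng(length)
        pwm = build_pwm(random_pfm(rng, length))
        for _ in range(200):
            window = random_window(rng)
            rel, _, _ = relative_score(pwm, window, must_cover=7)
            assert rel == pytest.approx(
                naive_relative_score(pwm.weights, window, 7), abs=1e-12
            )

    def test_invariant_under_reverse_complement(self):
        rng = np.random.default_rng(3)
        pwm = build_pwm(random_pfm(rng, 5))
        for _ in range(100):
            window = random_window(rng)
            rel_fwd, _, _ = relative_score(pwm, window, must_cover=7)
            rel_rev, _, _ = relative_score(pwm, revcomp(window), must_cover=7)
            assert rel_fwd == pytest.approx(rel_rev, abs=1e-12)

    def test_n_bases_score_background_weight(self):
        pwm = self._informative_pwm("ACGT")
        # all-N window: every scored position contributes weight 0
        rel, _, _ = relative_score(pwm, "N" * 15, must_cover=7)
        expected = (0.0 - pwm.s_min) / (pwm.s_max - pwm.s_min)
        assert rel == pytest.approx(min(1.0, max(0.0, expected)))
        # oracle agrees on windows with occasional Ns
        rng = np.random.default_rng(9)
        for _ in range(50):
            chars = list(random_window(rng))
            chars[int(rng.integers(0, 15))] = "N"
            window = "".join(chars)
            rel, _, _ = relative_score(pwm, window, must_cover=7)
            assert rel == pytest.approx(
                naive_relative_score(pwm.weights, window, 7), abs=1e-12
            )


class TestAffinityShift:
    def _pwm_for(self, consensus):
        counts = np.full((4, len(consensus)), 1.0)
        for j, b in enumerate(consensus):
            counts[BASES.index(b), j] = 50
        return build_pwm(PFM(f"TF_{consensus}", "T.1", counts))

    def test_identical_windows_rejected(self):
        pwms = [self._pwm_for("ACGT")]
        with pytest.raises(ValueError):
            affinity_shift(pwms, "A" * 15, "A" * 15)

    def test_off_centre_difference_rejected(self):
        pwms = [self._pwm_for("ACGT")]
        mut = "C" + "A" * 14
        with pytest.raises(ValueError):
            affinity_shift(pwms, "A" * 15, mut)

    def test_unrelated_motif_is_neutral(self):
        # A>T touches neither G nor C, so a G-run motif scores both
        # alleles identically on both strands
        pwm = self._pwm_for("GGGG")
        wt = "ATATATAAATATATA"
        mut = wt[:7] + "T" + wt[8:]
        [shift] = affinity_shift([pwm], wt, mut)
        assert shift.category == "neutral"
        assert abs(shift.delta) < 0.05

    def test_allele_swap_negates_every_delta(self):
        rng = np.random.default_rng(4)
        pwms = [build_pwm(random_pfm(rng, L)) for L in (4, 5, 6)]
        for _ in range(50):
            wt = random_window(rng)
            alt = BASES[(BASES.index(wt[7]) + 1) % 4]
            mut = wt[:7] + alt + wt[8:]
            fwd = affinity_shift(pwms, wt, mut)
            rev = affinity_shift(pwms, mut, wt)
            for f, r in zip(fwd, rev):
                assert f.delta == pytest.approx(-r.delta, abs=1e-12)

    def test_scores_bounded_categories_exclusive(self):
        rng = np.random.default_rng(5)
        pwms = [build_pwm(random_pfm(rng, L)) for L in (4, 6)]
        for _ in range(100):
            wt = random_window(rng)
            alt = BASES[(BASES.index(wt[7]) + 1) % 4]
            shifts = affinity_shift(pwms, wt, wt[:7] + alt + wt[8:])
            for s in shifts:
                assert 0 <= s.wt_rel <= 1 and 0 <= s.mut_rel <= 1
                assert -1 <= s.delta <= 1
                assert s.category in (
                    "gain", "loss", "novel", "lost_site", "neutral"
                )


class TestRankTopK:
    def _shift(self, tf, wt, mut):
        from enhancerscan import AffinityShift

        return AffinityShift(tf, wt, mut, mut - wt, 0, "+", 0, "+", "neutral")

    def test_fewer_than_k_returned_in_order(self):
        shifts = [self._shift("B", 0.1, 0.5), self._shift("A", 0.2, 0.3)]
        out = rank_top_k(shifts, k=5)
        assert [s.tf_name for s in out] == ["B", "A"]

    def test_zero_delta_ties_break_by_rel_then_name(self):
        shifts = [
            self._shift("C", 0.3, 0.3),
            self._shift("A", 0.6, 0.6),
            self._shift("B", 0.6, 0.6),
        ]
        out = rank_top_k(shifts, k=3)
        assert [s.tf_name for s in out] == ["A", "B", "C"]

    def test_random_shifts_match_brute_force_sort(self):
        rng = np.random.default_rng(4)
        shifts = [
            self._shift(f"TF{i:02d}", float(rng.random()), float(rng.random()))
            for i in range(20)
        ]
        out = rank_top_k(shifts, k=20)
        expected = sorted(
            shifts,
            key=lambda s: (-abs(s.delta), -max(s.wt_rel, s.mut_rel), s.tf_name),
        )
        assert [s.tf_name for s in out] == [s.tf_name for s in expected]


@pytest.fixture(scope="module")
def planted_fixture():
    genome = generate_genome(seed=3)
    _, _, cohort_gt = generate_cohorts(genome, seed=3)
    _, _, _, annot_gt = generate_annotations(cohort_gt, seed=3, genome=genome)
    _, _, snv_gt = generate_snvs(genome, annot_gt, seed=3)
    pfms, pwm_gt = generate_pwms(snv_gt, genome, seed=3)
    pwms = [build_pwm(p) for p in pfms]
    return genome, pwms, pwm_gt


class TestScanVariant:
    def test_windows_are_15bp_at_default_flank(self, planted_fixture):
        genome, pwms, pwm_gt = planted_fixture
        from enhancerscan import extract_window

        m = pwm_gt["planted_motifs"][0]
        assert len(extract_window(genome, m["chrom"], m["pos"], 7)) == 15

    def test_planted_gain_ranks_first_as_novel(self, planted_fixture):
        genome, pwms, pwm_gt = planted_fixture
        from enhancerscan import SNVRecord

        gain = next(m for m in pwm_gt["planted_motifs"]
                    if m["effect"] == "gain")
        snv = SNVRecord(gain["chrom"], gain["pos"], gain["ref"], gain["alt"],
                        patient="P01")
        _, top = scan_variant(genome, pwms, snv)
        assert top[0].tf_name == gain["tf_name"]
        assert top[0].category == "novel"
        assert top[0].delta > 0

    def test_planted_loss_is_lost_site(self, planted_fixture):
        genome, pwms, pwm_gt = planted_fixture
        from enhancerscan import SNVRecord

        loss = next(m for m in pwm_gt["planted_motifs"]
                    if m["effect"] == "loss")
        snv = SNVRecord(loss["chrom"], loss["pos"], loss["ref"], loss["alt"],
                        patient="P01")
        _, top = scan_variant(genome, pwms, snv)
        assert top[0].tf_name == loss["tf_name"]
        assert top[0].category == "lost_site"
        assert top[0].delta < 0

    def test_ref_mismatch_rejected(self, planted_fixture):
        genome, pwms, pwm_gt = planted_fixture
        from enhancerscan import SNVRecord

        m = pwm_gt["planted_motifs"][0]
        wrong_ref = next(b for b in BASES if b not in (m["ref"], m["alt"]))
        snv = SNVRecord(m["chrom"], m["pos"], wrong_ref, m["alt"],
                        patient="P01")
        with pytest.raises(ValueError, match="ref mismatch"):
            scan_variant(genome, pwms, snv)


class TestJasparRoundTrip:
    def test_write_then_read_preserves_counts(self, tmp_path):
        rng = np.random.default_rng(6)
        pfms = [random_pfm(rng, L) for L in (4, 6, 8)]
        path = tmp_path / "motifs.jaspar"
        write_jaspar(pfms, path)
        back = read_jaspar(path)
        assert len(back) == 3
        for orig, rt in zip(pfms, back):
            assert np.allclose(orig.counts, rt.counts)
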