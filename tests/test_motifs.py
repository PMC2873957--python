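"""Edit distance, neighborhood harvest, PWM build/scan, fixed motifs, filters."""

import numpy as np
import pytest
import edlib
from hypothesis import given, settings
from hypothesis import strategies as st

from chipmod import motifs as mo
from chipmod.simulate import MOTIF_WORDS, reverse_complement

words = st.text(alphabet="ACGT", min_size=1, max_size=12)


class TestLevenshtein:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ATGCAAAT", "ATGCAAAT", 0),
            ("ATGCAAAT", "ATGCAAT", 1),
            ("ATGCAAAT", "TTGCAAGT", 2),
            ("A", "T", 1),
        ],
    )
    def test_known_distances(self, a, b, expected):
        assert mo.levenshtein(a, b) == expected

    @settings(max_examples=200, deadline=None)
    @given(words, words)
    def test_agrees_with_edlib(self, a, b):
        assert mo.levenshtein(a, b) == edlib.align(a, b)["editDistance"]

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            mo.levenshtein("ATGN", "ATG")


class TestNeighborhoodHarvest:
    def test_neighborhood_distances_are_true_edit_distances(self):
        nb = mo.levenshtein_neighborhood("ATGC", max_dist=2)
        for word, d in list(nb.items())[::7]:
            assert mo.levenshtein(word, "ATGC") == d

    def test_exact_consensus_found_at_distance_zero(self):
        seq = "C" * 30 + "ATGCAAAT" + "C" * 30
        hits = mo.harvest_neighborhood({"r": seq})
        exact = [h for h in hits if h.offset == 30 and h.strand == "+" and h.length == 8]
        assert exact and exact[0].distance == 0

    def test_all_c_region_has_no_hits(self):
        assert mo.harvest_neighborhood({"r": "C" * 200}) == []

    def test_matches_exhaustive_window_oracle(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=600))
        got = {
            (h.offset, h.length, h.strand, h.distance)
            for h in mo.harvest_neighborhood({"r": seq})
        }
        expected = set()
        for L in range(6, 11):
            for off in range(len(seq) - L + 1):
                w = seq[off : off + L]
                d = mo.levenshtein(w, "ATGCAAAT")
                if d <= 2:
                    expected.add((off, L, "+", d))
                d = mo.levenshtein(reverse_complement(w), "ATGCAAAT")
                if d <= 2:
                    expected.add((off, L, "-", d))
        assert got == expected


class TestMergeAdjacent:
    SEQ = {"r": "ACGT" * 30}

    def hit(self, off, length, strand="+"):
        return mo.MotifHit("r", off, strand, "ATGCAAAT", word=self.SEQ["r"][off : off + length], length=length)

    def test_abutting_hits_fuse(self):
        out = mo.merge_adjacent([self.hit(10, 8), self.hit(18, 8)], self.SEQ)
        assert len(out) == 1
        assert (out[0].offset, out[0].end) == (10, 26)
        assert out[0].word == self.SEQ["r"][10:26]

    def test_gap_of_two_not_fused(self):
        out = mo.merge_adjacent([self.hit(10, 8), self.hit(20, 8)], self.SEQ)
        assert len(out) == 2

    def test_chain_fuses_transitively(self):
        out = mo.merge_adjacent(
            [self.hit(0, 8), self.hit(9, 8), self.hit(18, 8)], self.SEQ
        )
        assert len(out) == 1
        assert (out[0].offset, out[0].end) == (0, 26)

    def test_opposite_strands_not_fused(self):
        out = mo.merge_adjacent([self.hit(10, 8, "+"), self.hit(18, 8, "-")], self.SEQ)
        assert len(out) == 2


class TestBuildPwm:
    def test_planted_consensus_recovered(self):
        pwm = mo.build_pwm(["ATGCAAAT"] * 10)
        assert pwm.consensus == "ATGCAAAT"

    def test_zero_pseudocount_pure_columns_reach_two_bits(self):
        pwm = mo.build_pwm(["ATGCAAAT"] * 10, pseudocount=0.0)
        np.testing.assert_allclose(pwm.bits.sum(axis=0), 2.0)

    def test_even_mixture_column_probabilities_and_bits(self):
        pwm = mo.build_pwm(["ATGCAAAT"] * 5 + ["TTGCAAAT"] * 5, pseudocount=0.0)
        np.testing.assert_allclose(pwm.probs[[0, 3], 0], [0.5, 0.5])  # A, T
        assert pwm.bits[:, 0].sum() == pytest.approx(1.0)

    def test_short_word_contributes_only_covered_columns(self):
        pwm = mo.build_pwm(["ATGCAAAT"] * 4 + ["ATGCAA"], pseudocount=0.0)
        # prefix-aligned 6-mer covers columns 0..5; last two columns stay pure
        np.testing.assert_allclose(pwm.probs[[0, 3], 7], [0.0, 1.0])

    def test_fewer_than_two_words_rejected(self):
        with pytest.raises(ValueError):
            mo.build_pwm(["ATGCAAAT"])

    def test_probability_columns_sum_to_one(self, rng):
        nb = list(mo.levenshtein_neighborhood("ATGCAAAT", 2))
        pick = [nb[i] for i in rng.integers(0, len(nb), 40)]
        pwm = mo.build_pwm(pick)
        np.testing.assert_allclose(pwm.probs.sum(axis=0), 1.0, atol=1e-12)
        assert ((pwm.bits.sum(axis=0) >= -1e-12) & (pwm.bits.sum(axis=0) <= 2 + 1e-12)).all()


class TestScanPwm:
    def test_consensus_scores_sixteen_bits_under_own_pwm(self):
        pwm = mo.build_pwm(["ATGCAAAT"] * 10, pseudocount=0.0)
        hit = mo.best_hit("GG" + "ATGCAAAT" + "GG", pwm)
        assert hit.score == pytest.approx(16.0)
        assert (hit.offset, hit.strand) == (2, "+")

    def test_strand_symmetry(self, rng):
        pwm = mo.build_pwm(["ATGCAAAT"] * 8 + ["ATGCATAT"] * 2)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        assert mo.best_hit(seq, pwm).score == pytest.approx(
            mo.best_hit(reverse_complement(seq), pwm).score
        )

    def test_matches_all_window_oracle(self, rng):
        pwm = mo.build_pwm(["ATGCAAAT"] * 7 + ["ATTCAAAT"] * 3)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        S = pwm.score_matrix
        idx = {b: i for i, b in enumerate("ACGT")}

        def window_score(w):
            return sum(S[idx[b], i] for i, b in enumerate(w))

        expected = max(
            max(window_score(seq[o : o + 8]) for o in range(len(seq) - 7)),
            max(
                window_score(reverse_complement(seq[o : o + 8]))
                for o in range(len(seq) - 7)
            ),
        )
        assert mo.best_hit(seq, pwm).score == pytest.approx(expected)

    def test_minus_strand_hit_reported_at_forward_coordinates(self):
        pwm = mo.build_pwm(["ATGCAAAT"] * 10, pseudocount=0.0)
        seq = "GGGG" + reverse_complement("ATGCAAAT") + "GGGG"
        hit = mo.best_hit(seq, pwm)
        assert (hit.offset, hit.strand, hit.score) == (4, "-", pytest.approx(16.0))


class TestCalibration:
    def test_all_consensus_regions_calibrate_to_max_score(self):
        pwm = mo.build_pwm(["ATGCAAAT"] * 10, pseudocount=0.0)
        regions = [(1.0, "GG" + "ATGCAAAT" + "CC")] * 3
        thr = mo.calibrate_threshold(regions, pwm)
        assert thr.value == pytest.approx(pwm.max_score)
        assert thr.n_regions == 3

    def test_low_peak_score_regions_excluded(self):
        pwm = mo.build_pwm(["ATGCAAAT"] * 10)
        regions = [(0.1, "ATGCAAAT" * 3), (0.8, "GG" + "ATGCAAAT" + "GG")]
        thr = mo.calibrate_threshold(regions, pwm, peak_score_min=0.5)
        assert thr.n_regions == 1

    def test_no_qualifying_region_raises(self):
        pwm = mo.build_pwm(["ATGCAAAT"] * 10)
        with pytest.raises(ValueError, match="calibrate"):
            mo.calibrate_threshold([(0.1, "ATGCAAATGG")], pwm, peak_score_min=0.5)

    def test_median_of_planted_best_scores_recovered(self):
        # GC-only background cannot score; planted words set region bests
        pwm = mo.build_pwm(["ATGCAAAT"] * 8 + ["ATGCATAT", "ATGAAAAT"])
        planted = ["ATGCAAAT", "ATGCATAT", "ATGAAAAT", "TTGCAAAT", "ATGCAAAA"]
        regions = []
        direct = []
        for w in planted:
            regions.append((1.0, "G" * 40 + w + "C" * 40))
            direct.append(mo.best_hit(w, pwm).score)
        thr = mo.calibrate_threshold(regions, pwm)
        assert thr.value == pytest.approx(float(np.median(direct)))


class TestFixedMotifs:
    def test_pore_literal_matched_once(self):
        seq = "G" * 20 + MOTIF_WORDS["PORE"] + "G" * 20
        hits = mo.match_fixed_motif(seq, "PORE")
        assert len(hits) == 1 and hits[0].offset == 20

    def test_more_is_palindromic_and_deduplicated(self):
        seq = "G" * 10 + MOTIF_WORDS["MORE"] + "G" * 10
        hits = mo.match_fixed_motif(seq, "MORE")
        assert len(hits) == 1  # one physical site, not one per strand

    def test_pore_on_minus_strand_found(self):
        seq = "G" * 10 + reverse_complement(MOTIF_WORDS["PORE"]) + "G" * 10
        hits = mo.match_fixed_motif(seq, "PORE")
        assert len(hits) == 1 and hits[0].strand == "-"

    def test_pore_region_also_yields_octamer_neighborhood_hit(self):
        # the PORE's 3' 8-mer is the OCT4 octamer itself
        assert MOTIF_WORDS["PORE"].endswith(MOTIF_WORDS["OCT4"])
        seq = "G" * 20 + MOTIF_WORDS["PORE"] + "G" * 20
        hits = mo.harvest_neighborhood({"r": seq})
        assert any(h.distance == 0 and h.strand == "+" for h in hits)

    def test_mismatch_tolerance_option(self):
        seq = "G" * 10 + "ATGCATATGCAA" + "G" * 10  # MORE with 1 mismatch
        assert mo.match_fixed_motif(seq, "MORE") == []
        assert len(mo.match_fixed_motif(seq, "MORE", max_mismatches=1)) >= 1


class TestPwmDistanceAndComplexity:
    def test_identical_pwms_distance_zero_and_one_survivor(self):
        a = mo.build_pwm(["ATGCAAAT"] * 10)
        b = mo.build_pwm(["ATGCAAAT"] * 10)
        assert mo.pwm_align_distance(a, b) == pytest.approx(0.0)
        assert len(mo.dedup_motifs([a, b], cutoff=0.2)) == 1

    def test_single_column_swap_distance_hand_computed(self):
        a = mo.build_pwm(["ATGCAAAT"] * 10, pseudocount=0.0)
        b = mo.build_pwm(["TTGCAAAT"] * 10, pseudocount=0.0)
        # at offset 0: one column differs by the A<->T swap, Euclidean sqrt(2)
        d0 = np.sqrt(2.0) / 8.0
        assert mo.pwm_align_distance(a, b, min_overlap=8) == pytest.approx(d0)

    def test_dissimilar_pwms_both_retained(self):
        a = mo.build_pwm(["ATGCAAAT"] * 10, pseudocount=0.0)
        b = mo.build_pwm(["CACGTGCA"] * 10)
        assert mo.pwm_align_distance(a, b, min_overlap=8) >= 0.2
        kept = mo.dedup_motifs([a, b], cutoff=0.2, min_overlap=8)
        assert len(kept) == 2

    def test_dedup_keeps_highest_information_member(self):
        sharp = mo.build_pwm(["ATGCAAAT"] * 10, pseudocount=0.0)
        fuzzy = mo.build_pwm(["ATGCAAAT"] * 6 + ["ATGCAATT"] * 4, pseudocount=0.0)
        kept = mo.dedup_motifs([fuzzy, sharp], cutoff=0.2)
        assert kept == [sharp]

    @pytest.mark.parametrize(
        "word,expected",
        [("AAAAAAAA", 0.0), ("ATATATAT", 1.0), ("ACGTACGT", 2.0)],
    )
    def test_dimer_entropy_known_values(self, word, expected):
        assert mo.dimer_entropy(word) == pytest.approx(expected)

    def test_complexity_filter_drops_low_entropy(self):
        kept = mo.filter_complexity(["AAAAAAAA", "ATATATAT", "ACGTACGT"], min_entropy=1.0)
        assert kept == ["ATATATAT", "ACGTACGT"]

    def test_single_symbol_rejected(self):
        with pytest.raises(ValueError):
            mo.dimer_entropy("A")
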