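import itertools
import math

import numpy as np
import pandas as pd
import pytest

from polycage.motifs import (
    Pfm,
    enrichment_fisher,
    occurrence_matrix,
    occurrence_pca,
    pfm_to_pwm,
    promoter_windows,
    read_jaspar_pfm,
    scan_window,
)
from polycage.seq import revcomp
from polycage.simulate import simulate_motif_windows

JASPAR_TEXT = """>MA0001.1 TEST
A  [ 10   2   0   8   0   1   3   2 ]
C  [  0   1  12   0   0   9   4   3 ]
G  [  1   8   0   2  12   1   3   4 ]
T  [  1   1   0   2   0   1   2   3 ]
"""

JASPAR_REORDERED = """>MA0002.1 SWAP
A  [ 10  0  3  1 ]
T  [  0  0  3  1 ]
G  [  0 12  3  1 ]
C  [  2  0  3  9 ]
"""


class TestJasparParsing:
    def test_standard_record(self, tmp_path):
        p = tmp_path / "m.jaspar"
        p.write_text(JASPAR_TEXT)
        (pfm,) = read_jaspar_pfm(p)
        assert pfm.motif_id == "MA0001.1"
        assert pfm.length == 8
        assert pfm.counts[0, 0] == 10  # A row first

    def test_row_labels_honored_regardless_of_order(self, tmp_path):
        p = tmp_path / "m.jaspar"
        p.write_text(JASPAR_REORDERED)
        (pfm,) = read_jaspar_pfm(p)
        # rows must come back as A, C, G, T
        np.testing.assert_allclose(pfm.counts[:, 0], [10, 2, 0, 0])
        np.testing.assert_allclose(pfm.counts[:, 1], [0, 0, 12, 0])
        np.testing.assert_allclose(pfm.counts[:, 3], [1, 9, 1, 1])

    def test_unequal_row_lengths_rejected(self, tmp_path):
        p = tmp_path / "m.jaspar"
        p.write_text(">MA0003.1 BAD\nA [ 1 2 3 ]\nC [ 1 2 ]\nG [ 1 2 3 ]\nT [ 1 2 3 ]\n")
        with pytest.raises(ValueError):
            read_jaspar_pfm(p)


class TestPwm:
    def test_uniform_columns_give_zero_log_odds(self):
        pfm = Pfm("u", "u", np.full((4, 4), 5.0))
        pwm = pfm_to_pwm(pfm)
        np.testing.assert_allclose(pwm, 0.0, atol=1e-12)

    def test_one_hot_column_signs(self):
        counts = np.zeros((4, 4))
        counts[0, :] = 100.0  # all A
        pwm = pfm_to_pwm(Pfm("a", "a", counts))
        assert (pwm[0] > 0).all()
        assert (pwm[1:] < 0).all()

    def test_hand_computed_two_column_example(self):
        counts = np.array([[3.0, 0.0], [1.0, 0.0], [0.0, 4.0], [0.0, 0.0]])
        pwm = pfm_to_pwm(Pfm("h", "h", counts), pseudocount=0.8)
        expected_a0 = math.log2(((3 + 0.8 * 0.25) / (4 + 0.8)) / 0.25)
        expected_g1 = math.log2(((4 + 0.8 * 0.25) / (4 + 0.8)) / 0.25)
        assert pwm[0, 0] == pytest.approx(expected_a0)
        assert pwm[2, 1] == pytest.approx(expected_g1)

    def test_zero_background_rejected(self):
        pfm = Pfm("u", "u", np.full((4, 4), 5.0))
        with pytest.raises(ValueError):
            pfm_to_pwm(pfm, background={"A": 0.0, "C": 0.5, "G": 0.25, "T": 0.25})


def consensus_pfm(consensus, strong=18.0, weak=2.0):
    counts = np.full((4, len(consensus)), weak)
    for j, base in enumerate(consensus):
        counts["ACGT".index(base), j] = strong
    return Pfm("CONS", "cons", counts)


class TestScanning:
    def test_consensus_window_scores_one(self, rng):
        motif = "TGACGTCA"
        pwm = pfm_to_pwm(consensus_pfm(motif))
        seq = "".join(rng.choice(list("ACGT"), size=30)) + motif
        occ = scan_window(seq, pwm)
        assert occ.best_relative_score == pytest.approx(1.0)
        assert occ.present

    def test_reverse_complement_scores_identically(self, rng):
        pwm = pfm_to_pwm(consensus_pfm("TGACGTCAGG"))
        seq = "".join(rng.choice(list("ACGT"), size=60))
        a = scan_window(seq, pwm)
        b = scan_window(revcomp(seq), pwm)
        assert a.best_relative_score == pytest.approx(b.best_relative_score)

    def test_random_sequence_rarely_matches_long_strict_motif(self, rng):
        pwm = pfm_to_pwm(consensus_pfm("TGACGTCAGGAT", strong=100.0, weak=0.0))
        hits = 0
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=300))
            if scan_window(seq, pwm, rel_threshold=0.85).present:
                hits += 1
        assert hits == 0

    def test_window_shorter_than_motif_flagged_absent(self):
        pwm = pfm_to_pwm(consensus_pfm("TGACGTCA"))
        occ = scan_window("ACG", pwm)
        assert not occ.present
        assert occ.flagged


def fisher_oracle(a, b, c, d):
    """One-sided (greater) hypergeometric tail by direct enumeration."""
    n_fg, n_with = a + b, a + c
    total = a + b + c + d
    denom = math.comb(total, n_with)
    p = 0.0
    for k in range(a, min(n_fg, n_with) + 1):
        if n_with - k > c + d:
            continue
        p += math.comb(n_fg, k) * math.comb(c + d, n_with - k) / denom
    return p


class TestFisherEnrichment:
    def _presence(self, n, k, prefix):
        idx = [f"{prefix}{i}" for i in range(n)]
        return pd.DataFrame({"M": [i < k for i in range(n)]}, index=idx)

    def test_equal_proportions_are_null(self):
        fg = self._presence(20, 8, "f")
        bg = self._presence(100, 40, "b")
        row = enrichment_fisher(fg, bg).iloc[0]
        assert row["p_value"] >= 0.5
        assert row["odds_ratio"] == pytest.approx(1.0, rel=0.2)

    def test_matches_hypergeometric_enumeration_oracle(self):
        fg = self._presence(20, 8, "f")
        bg = self._presence(100, 10, "b")
        row = enrichment_fisher(fg, bg).iloc[0]
        assert row["p_value"] == pytest.approx(fisher_oracle(8, 12, 10, 90), rel=1e-9)

    def test_oracle_agreement_over_small_table_grid(self):
        # every 2x2 table with margins up to 30
        for n_fg, n_bg in ((5, 10), (12, 18), (15, 15)):
            for a, c in itertools.product(range(n_fg + 1), range(0, n_bg + 1, 3)):
                fg = self._presence(n_fg, a, "f")
                bg = self._presence(n_bg, c, "b")
                row = enrichment_fisher(fg, bg).iloc[0]
                expected = fisher_oracle(a, n_fg - a, c, n_bg - c)
                assert row["p_value"] == pytest.approx(expected, rel=1e-9, abs=1e-12)

    def test_extreme_table_attains_minimal_p(self):
        fg = self._presence(10, 10, "f")
        bg = self._presence(50, 0, "b")
        row = enrichment_fisher(fg, bg).iloc[0]
        assert row["p_value"] == pytest.approx(
            1.0 / math.comb(60, 10), rel=1e-9
        )
        assert row["odds_ratio"] > 100  # Haldane-corrected, zero cells

    def test_empty_foreground_rejected(self):
        bg = self._presence(10, 3, "b")
        with pytest.raises(ValueError, match="foreground"):
            enrichment_fisher(bg.iloc[:0], bg)

    def test_overlapping_sets_rejected(self):
        fg = self._presence(10, 3, "x")
        with pytest.raises(ValueError, match="exclude"):
            enrichment_fisher(fg, fg)

    def test_fdr_dominates_p(self):
        rng = np.random.default_rng(0)
        fg = pd.DataFrame(rng.random((30, 6)) < 0.3,
                          columns=list("ABCDEF"),
                          index=[f"f{i}" for i in range(30)])
        bg = pd.DataFrame(rng.random((100, 6)) < 0.25,
                          columns=list("ABCDEF"),
                          index=[f"b{i}" for i in range(100)])
        out = enrichment_fisher(fg, bg)
        assert (out["fdr"] >= out["p_value"] - 1e-12).all()


class TestPlantedMotifRecovery:
    def test_planted_motif_ranks_first_by_p_value(self):
        motif = "TGACGTCATC"
        fg, bg, fg_planted, _ = simulate_motif_windows(
            200, 1000, motif, fg_rate=0.4, bg_rate=0.05, seed=17
        )
        pfms = [consensus_pfm(motif)]
        rng = np.random.default_rng(18)
        for i in range(3):
            decoy = "".join(rng.choice(list("ACGT"), size=10))
            p = consensus_pfm(decoy)
            p.motif_id = f"DECOY{i}"
            pfms.append(p)
        fg_mat = occurrence_matrix(fg, pfms)
        bg_mat = occurrence_matrix(bg, pfms)
        out = enrichment_fisher(fg_mat, bg_mat)
        assert out.iloc[0]["motif_id"] == "CONS"
        assert out.iloc[0]["enriched"]
        # the scanner must actually find the planted instances
        assert fg_mat["CONS"].sum() >= 0.9 * len(fg_planted)


class TestOccurrencePca:
    def test_distinct_group_separates_on_pc1(self):
        mat = pd.DataFrame(
            {
                "m1": [10.0, 10.0, 80.0],
                "m2": [20.0, 20.0, 90.0],
                "m3": [5.0, 5.0, 60.0],
            },
            index=["g1", "g2", "g3"],
        )
        coords, var = occurrence_pca(mat)
        # the two identical groups sit together, opposite the distinct one
        assert coords.loc["g1", "PC1"] == pytest.approx(coords.loc["g2", "PC1"])
        assert np.sign(coords.loc["g3", "PC1"]) != np.sign(coords.loc["g1", "PC1"])
        assert abs(coords.loc["g3", "PC1"]) > abs(coords.loc["g1", "PC1"])

    def test_needs_three_groups(self):
        mat = pd.DataFrame({"m1": [1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(ValueError):
            occurrence_pca(mat)


class TestPromoterWindows:
    def test_minus_strand_window_is_reverse_complemented(self):
        from polycage.clustering import TagCluster

        genome = {"chr1": "ACGTACGTACGTACGTACGT"}
        cl = TagCluster("TC0", "chr1", "-", 10, 11, 10, 1.0, 10, 10, 1, "sharp")
        win = promoter_windows([cl], genome, upstream=3, downstream=2)
        # minus-strand: upstream is genomically rightward
        assert win["TC0"] == revcomp(genome["chr1"][8:14])
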