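import math

import numpy as np
import pytest

from affinityscan import (
    PWM,
    Background,
    CutoffGrid,
    SequenceRecord,
    occupancy,
    s_max,
    score_matrix,
    sum_of_scores,
    tba,
    window_score,
)
from affinityscan.affinity import NoScorableWindowError, UnscorableWindowError

from .conftest import random_pwm, random_sequence
from .oracle import (
    brute_occupancy,
    brute_s_max,
    brute_sum_of_scores,
    brute_tba,
    brute_window_scores,
)


class TestWindowScore:
    def test_uniform_pwm_uniform_background_scores_zero(self, uniform_pwm, bg_uniform):
        assert window_score(uniform_pwm, "ACG", bg_uniform) == pytest.approx(0.0)

    def test_both_orientations_hand_computed_for_l1(self, strong_a_pwm, bg_uniform):
        # forward: P(A)=0.997 vs bg 0.25 -> log(3.988)
        assert window_score(strong_a_pwm, "A", bg_uniform) == pytest.approx(math.log(0.997 / 0.25))
        # "T" is scored via the reverse orientation as the complement of A
        assert window_score(strong_a_pwm, "T", bg_uniform) == pytest.approx(math.log(0.997 / 0.25))
        # "C" matches neither orientation well: complement is G
        assert window_score(strong_a_pwm, "C", bg_uniform) == pytest.approx(math.log(0.001 / 0.25))

    def test_palindromic_consensus_orientations_agree(self, bg_uniform):
        m = np.array(
            [[0.7, 0.1, 0.1, 0.1], [0.1, 0.1, 0.1, 0.7], [0.1, 0.7, 0.1, 0.1], [0.1, 0.1, 0.7, 0.1]]
        ).T
        pwm = PWM(name="pal", matrix=m)  # consensus ATGC... build palindrome ACGT
        # palindromic window on any PWM: fwd and rev scores computed explicitly
        scores = brute_window_scores(pwm, SequenceRecord(id="w", bases="ACGT"), bg_uniform)
        assert window_score(pwm, "ACGT", bg_uniform) == pytest.approx(scores[0])

    def test_window_with_n_is_unscorable(self, uniform_pwm, bg_uniform):
        with pytest.raises(UnscorableWindowError):
            window_score(uniform_pwm, "ANG", bg_uniform)

    def test_wrong_window_length_rejected(self, uniform_pwm, bg_uniform):
        with pytest.raises(ValueError, match="length"):
            window_score(uniform_pwm, "ACGT", bg_uniform)


class TestSMax:
    def test_uniform_pwm_uniform_background_zero(self, uniform_pwm, bg_uniform):
        assert s_max(uniform_pwm, bg_uniform) == pytest.approx(0.0)

    @pytest.mark.parametrize("bg_name", ["bg_uniform", "bg_skewed"])
    def test_matches_exhaustive_dinucleotide_maximum(self, rng, bg_name, request):
        bg = request.getfixturevalue(bg_name)
        pwm = random_pwm(rng, 2)
        exhaustive = max(
            window_score(pwm, a + b, bg) for a in "ACGT" for b in "ACGT"
        )
        assert s_max(pwm, bg) == pytest.approx(exhaustive, abs=1e-12)

    def test_upper_bounds_sampled_window_scores(self, rng, bg_skewed):
        pwm = random_pwm(rng, 6)
        smax = s_max(pwm, bg_skewed)
        for _ in range(1000):
            w = "".join(rng.choice(list("ACGT"), size=6))
            assert window_score(pwm, w, bg_skewed) <= smax + 1e-12

    def test_agrees_with_brute_force(self, rng, bg_skewed):
        for l in (1, 3, 8):
            pwm = random_pwm(rng, l)
            assert s_max(pwm, bg_skewed) == pytest.approx(brute_s_max(pwm, bg_skewed), abs=1e-12)


class TestTba:
    def test_uniform_everything_counts_windows(self, uniform_pwm, bg_uniform):
        seq = SequenceRecord(id="s", bases="ACGTACGTAC")  # L=10, l=3 -> 8 windows
        result = tba(uniform_pwm, seq, bg_uniform)
        assert result.value == pytest.approx(math.log(8))
        assert result.n_windows_used == 8

    def test_reverse_complement_invariance(self, rng, bg_uniform):
        for _ in range(20):
            pwm = random_pwm(rng, int(rng.integers(1, 13)))
            seq = random_sequence(rng, int(rng.integers(pwm.length, 200)))
            assert tba(pwm, seq, bg_uniform).value == pytest.approx(
                tba(pwm, seq.reverse_complement(), bg_uniform).value, abs=1e-9
            )

    def test_no_scorable_window_is_an_error(self, uniform_pwm, bg_uniform):
        with pytest.raises(NoScorableWindowError):
            tba(uniform_pwm, SequenceRecord(id="s", bases="AN"), bg_uniform)
        with pytest.raises(NoScorableWindowError):
            tba(uniform_pwm, SequenceRecord(id="s", bases="ACNGT"), bg_uniform)

    def test_masked_junction_splits_concatenation_exactly(self, rng, bg_skewed):
        """TBA over two masked-joined fragments = log of summed per-fragment sums."""
        pwm = random_pwm(rng, 4)
        s1 = random_sequence(rng, 50, "s1")
        s2 = random_sequence(rng, 60, "s2")
        joined = SequenceRecord(id="j", bases=s1.bases + "N" + s2.bases)
        combined = tba(pwm, joined, bg_skewed).value
        expected = np.logaddexp(tba(pwm, s1, bg_skewed).value, tba(pwm, s2, bg_skewed).value)
        assert combined == pytest.approx(expected, abs=1e-9)


class TestOccupancy:
    def test_cutoff_one_keeps_only_top_sites(self, bg_uniform):
        """Two planted consensus sites: at C=1 exactly they contribute, nothing else."""
        m = np.array([[0.85, 0.05, 0.05, 0.05], [0.05, 0.85, 0.05, 0.05], [0.05, 0.05, 0.85, 0.05]]).T
        pwm = PWM(name="acg", matrix=m)
        # "ACGA" plants the ACG consensus without also creating its reverse
        # complement CGT in an adjacent window (as "ACGT" would)
        seq = SequenceRecord(id="s", bases="TTTTACGATTTTACGATTT")
        result = occupancy(pwm, seq, bg_uniform, cutoff=1.0)
        assert result.n_sites_passing == 2
        assert result.value == pytest.approx(math.log(2) + s_max(pwm, bg_uniform), abs=1e-9)

    def test_consensus_site_passes_at_cutoff_one_when_consensus_is_max(self, bg_uniform):
        m = np.array([[0.9, 0.05, 0.03, 0.02], [0.9, 0.05, 0.03, 0.02]]).T
        pwm = PWM(name="aa", matrix=m)
        seq = SequenceRecord(id="s", bases="CCGGAACCGG")
        result = occupancy(pwm, seq, bg_uniform, cutoff=1.0)
        assert result.n_sites_passing == 1
        assert result.value == pytest.approx(s_max(pwm, bg_uniform), abs=1e-9)

    def test_monotone_non_increasing_in_cutoff(self, rng, bg_skewed):
        pwm = random_pwm(rng, 6)
        seq = random_sequence(rng, 300)
        grid = CutoffGrid()
        values = [occupancy(pwm, seq, bg_skewed, c).value for c in grid]
        total = tba(pwm, seq, bg_skewed).value
        for a, b in zip(values, values[1:]):
            assert np.exp(a) >= np.exp(b) - 1e-12
        assert all(np.exp(v) <= np.exp(total) + 1e-12 for v in values)

    def test_low_cutoff_recovers_tba_exactly(self, rng, bg_uniform):
        """Every window scores > 0 here, so some C in (0,1] admits them all."""
        m = np.array([[0.4, 0.2, 0.2, 0.2]]).T  # l=1; A and T both score log(1.6) or more... only A/T
        pwm = PWM(name="at", matrix=m)
        bases = "".join(rng.choice(list("AT"), size=100))  # A fwd, T via reverse orientation
        seq = SequenceRecord(id="s", bases=bases)
        smax = s_max(pwm, bg_uniform)
        scores = [window_score(pwm, b, bg_uniform) for b in bases]
        assert min(scores) > 0
        c = min(scores) / smax / 2
        result = occupancy(pwm, seq, bg_uniform, cutoff=c)
        assert result.value == pytest.approx(tba(pwm, seq, bg_uniform).value, abs=1e-9)
        assert result.n_sites_passing == result.n_windows_used == 100

    def test_empty_occupancy_is_minus_inf_sentinel(self, bg_uniform):
        m = np.array([[0.97, 0.01, 0.01, 0.01]] * 3).T
        pwm = PWM(name="aaa", matrix=m)
        seq = SequenceRecord(id="s", bases="CCCCGGGGCC")
        result = occupancy(pwm, seq, bg_uniform, cutoff=1.0)
        assert result.value == float("-inf")
        assert result.n_sites_passing == 0

    def test_invalid_cutoff_rejected(self, uniform_pwm, bg_uniform):
        seq = SequenceRecord(id="s", bases="ACGTACGT")
        for bad in (0.0, -0.5, 1.5):
            with pytest.raises(ValueError):
                occupancy(uniform_pwm, seq, bg_uniform, cutoff=bad)


class TestSumOfScores:
    def test_no_passing_window_sums_to_zero(self, bg_uniform):
        m = np.array([[0.97, 0.01, 0.01, 0.01]] * 3).T
        pwm = PWM(name="aaa", matrix=m)
        assert sum_of_scores(pwm, SequenceRecord(id="s", bases="CCCCGGGG"), bg_uniform, 1.0) == 0.0

    def test_single_passing_window_returns_its_score(self, bg_uniform):
        m = np.array([[0.97, 0.01, 0.01, 0.01]] * 3).T
        pwm = PWM(name="aaa", matrix=m)
        seq = SequenceRecord(id="s", bases="CCCAAACCC")
        expected = window_score(pwm, "AAA", bg_uniform)
        assert sum_of_scores(pwm, seq, bg_uniform, 1.0) == pytest.approx(expected)

    def test_three_planted_sites_hand_summed(self, bg_uniform):
        m = np.array([[0.9, 0.04, 0.03, 0.03], [0.04, 0.9, 0.03, 0.03]]).T
        pwm = PWM(name="ac", matrix=m)
        seq = SequenceRecord(id="s", bases="ACGGACGGAC")
        site = window_score(pwm, "AC", bg_uniform)
        assert sum_of_scores(pwm, seq, bg_uniform, 1.0) == pytest.approx(3 * site, abs=1e-9)

    def test_agrees_with_brute_force(self, rng, bg_skewed):
        pwm = random_pwm(rng, 5)
        seq = random_sequence(rng, 200)
        for c in (0.1, 0.5, 0.9):
            assert sum_of_scores(pwm, seq, bg_skewed, c) == pytest.approx(
                brute_sum_of_scores(pwm, seq, bg_skewed, c), abs=1e-9
            )


class TestOracleEquivalence:
    """The vectorized implementation against the explicit-loop reference."""

    def test_tba_and_occupancy_match_oracle_on_random_fixtures(self, rng, bg_skewed):
        cutoffs = CutoffGrid(values=(0.1, 0.5, 0.9))
        for trial in range(100):
            l = int(rng.integers(1, 13))
            L = int(rng.integers(l, 501))
            pwm = random_pwm(rng, l)
            seq = random_sequence(rng, L, f"fixture_{trial}")
            bg = bg_skewed if trial % 2 else Background()
            assert tba(pwm, seq, bg).value == pytest.approx(brute_tba(pwm, seq, bg), abs=1e-9)
            c = cutoffs.values[trial % 3]
            got = occupancy(pwm, seq, bg, c)
            want_value, want_n = brute_occupancy(pwm, seq, bg, c)
            assert got.n_sites_passing == want_n
            if math.isinf(want_value):
                assert got.value == float("-inf")
            else:
                assert got.value == pytest.approx(want_value, abs=1e-9)

    def test_masked_positions_match_oracle(self, rng, bg_uniform):
        pwm = random_pwm(rng, 4)
        bases = "".join(rng.choice(list("ACGT"), size=80))
        mask = frozenset(int(i) for i in rng.choice(80, size=6, replace=False))
        seq = SequenceRecord(id="m", bases=bases, mask=mask)
        assert tba(pwm, seq, bg_uniform).value == pytest.approx(
            brute_tba(pwm, seq, bg_uniform), abs=1e-9
        )


class TestScoreMatrix:
    def test_composition_matches_scalar_ops(self, rng, bg_uniform):
        pwms = [random_pwm(rng, 3), random_pwm(rng, 5), random_pwm(rng, 7)]
        seqs = [random_sequence(rng, 60, "a"), random_sequence(rng, 80, "b")]
        sm = score_matrix(pwms, seqs, bg_uniform, mode="tba")
        assert sm.values.shape == (2, 3)
        for seq in seqs:
            for pwm in pwms:
                assert sm.values.loc[seq.id, pwm.name] == pytest.approx(
                    tba(pwm, seq, bg_uniform).value
                )

    def test_empty_inputs_rejected(self, rng, bg_uniform):
        with pytest.raises(ValueError):
            score_matrix([], [random_sequence(rng, 50)], bg_uniform)
        with pytest.raises(ValueError):
            score_matrix([random_pwm(rng, 3)], [], bg_uniform)

    def test_deterministic_and_roundtrips_through_tsv(self, rng, bg_uniform, tmp_path):
        pwms = [random_pwm(rng, 4)]
        seqs = [random_sequence(rng, 50, "x"), random_sequence(rng, 50, "y")]
        sm1 = score_matrix(pwms, seqs, bg_uniform, mode="occupancy", cutoff=0.5)
        sm2 = score_matrix(pwms, seqs, bg_uniform, mode="occupancy", cutoff=0.5)
        assert sm1.values.equals(sm2.values)
        path = tmp_path / "scores.tsv"
        sm1.to_tsv(path)
        back = type(sm1).read_tsv(path, mode="occupancy", cutoff=0.5)
        np.testing.assert_allclose(back.values.to_numpy(), sm1.values.to_numpy(), atol=1e-9)

    def test_unscorable_cell_recorded_as_missing_with_reason(self, rng, bg_uniform):
        pwms = [random_pwm(rng, 6)]
        seqs = [random_sequence(rng, 50, "ok"), SequenceRecord(id="short", bases="ACG")]
        sm = score_matrix(pwms, seqs, bg_uniform, mode="tba")
        assert np.isnan(sm.values.loc["short", pwms[0].name])
        assert ("short", pwms[0].name) in sm.missing
        assert "short" in sm.missing[("short", pwms[0].name)]

    def test_minus_inf_serialized_distinctly_from_missing(self, tmp_path, bg_uniform):
        m = np.array([[0.97, 0.01, 0.01, 0.01]] * 4).T
        pwm = PWM(name="aaaa", matrix=m)
        seqs = [SequenceRecord(id="noA", bases="CCGGCCGGCC")]
        sm = score_matrix([pwm], seqs, bg_uniform, mode="occupancy", cutoff=1.0)
        assert sm.values.loc["noA", "aaaa"] == float("-inf")
        assert not sm.missing
        path = tmp_path / "occ.tsv"
        sm.to_tsv(path)
        assert "-inf" in path.read_text()
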