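import itertools
import math

import numpy as np
import pytest

from seqregister.alphabet import AA1, AA_INDEX
from seqregister.profile_align import (AlignmentParams, NullDistribution,
                                       alignment_pvalue, alignment_score,
                                       best_gapless_alignment,
                                       certified_pvalue_bound, floor_rows,
                                       logodds_matrix, null_score_distribution,
                                       window_scores_matrix)
from seqregister.structure_io import TargetSequence
from seqregister.synthetic import GroundTruth, gen_profile, gen_sequence

from conftest import random_sequence, random_window


def degenerate_window(seq_fragment):
    w = np.full((len(seq_fragment), 20), 1e-6)
    for i, a in enumerate(seq_fragment):
        w[i, AA_INDEX[a]] = 1.0
    return w / w.sum(axis=1, keepdims=True)


class TestScore:
    def test_uniform_rows_score_zero(self, params):
        window = np.full((7, 20), 0.05)
        seq = TargetSequence("s", "ACDEFGH")
        assert alignment_score(window, seq, 0, params) == pytest.approx(0.0, abs=1e-12)

    def test_single_position_closed_form(self, params):
        window = np.full((1, 20), 0.5 / 19)
        window[0, AA_INDEX["A"]] = 0.5
        seq = TargetSequence("s", "A")
        assert alignment_score(window, seq, 0, params) == pytest.approx(math.log(10), abs=1e-12)

    def test_x_contributes_zero(self, params):
        rng = np.random.default_rng(0)
        w = random_window(rng, 3)
        s1 = TargetSequence("s", "AXA")
        s2 = TargetSequence("t", "AAA")
        lo = logodds_matrix(w, params)
        got = alignment_score(w, s1, 0, params)
        expect = lo[0, AA_INDEX["A"]] + lo[2, AA_INDEX["A"]]
        assert got == pytest.approx(expect, abs=1e-12)

    def test_against_term_by_term_oracle(self, params):
        rng = np.random.default_rng(42)
        w = random_window(rng, 3)
        seq = random_sequence(rng, 10)
        for offset in range(8):
            floored = floor_rows(w, params.probability_floor)
            expect = sum(
                math.log(floored[i, AA_INDEX[seq.residues[offset + i]]] / 0.05)
                for i in range(3)
            )
            assert alignment_score(w, seq, offset, params) == pytest.approx(expect, abs=1e-12)

    def test_offset_out_of_range(self, params):
        with pytest.raises(ValueError):
            alignment_score(np.full((3, 20), 0.05), TargetSequence("s", "ACDE"), 2, params)


class TestBestAlignment:
    def test_degenerate_window_finds_source_offset(self, params):
        rng = np.random.default_rng(1)
        seq = random_sequence(rng, 40)
        window = degenerate_window(seq.residues[7:15])
        best = best_gapless_alignment(window, [seq], params)
        assert (best.seq_id, best.offset) == ("s", 7)
        assert best.n_offsets == 40 - 8 + 1

    def test_tie_break_lowest_offset(self, params):
        seq = TargetSequence("s", "AAAA")
        window = degenerate_window("AA")
        assert best_gapless_alignment(window, [seq], params).offset == 0

    def test_against_exhaustive_oracle(self, params):
        """100 seeded random windows vs full enumeration."""
        rng = np.random.default_rng(7)
        seqs = [random_sequence(rng, 25, "a"), random_sequence(rng, 18, "b")]
        for _ in range(100):
            w = random_window(rng, 4)
            best = best_gapless_alignment(w, seqs, params)
            scored = [
                (alignment_score(w, s, o, params), s.id, o)
                for s in seqs
                for o in range(len(s) - 4 + 1)
            ]
            top = max(s for s, _, _ in scored)
            # first sequence, lowest offset among ties
            expect = next(t for t in scored if t[0] >= top - 1e-12)
            assert (best.seq_id, best.offset) == (expect[1], expect[2])
            assert best.score == pytest.approx(expect[0], abs=1e-12)

    def test_window_scores_matrix_matches_direct(self, params):
        rng = np.random.default_rng(3)
        probs = random_window(rng, 12)
        seq = random_sequence(rng, 30)
        lo = logodds_matrix(probs, params)
        C = window_scores_matrix(lo, np.array([AA_INDEX[a] for a in seq.residues]), 5)
        for w in range(12 - 5 + 1):
            for o in range(30 - 5 + 1):
                direct = alignment_score(probs[w : w + 5], seq, o, params)
                assert C[w, o] == pytest.approx(direct, abs=1e-10)

    def test_no_valid_offsets(self, params):
        with pytest.raises(ValueError):
            best_gapless_alignment(np.full((5, 20), 0.05),
                                   [TargetSequence("s", "ACD")], params)


class TestNullDistribution:
    def test_single_position_example(self, params):
        window = np.full((1, 20), 0.5 / 19)
        window[0, AA_INDEX["A"]] = 0.5
        null = null_score_distribution(window, params)
        values = (null.min_bin + np.arange(len(null.mass))) * null.step
        top = values[null.mass > 0][-1]
        assert top == pytest.approx(math.log(10), abs=params.grid_step)
        assert null.mass[-1] == pytest.approx(0.05, abs=1e-12)
        assert null.total_mass == pytest.approx(1.0, abs=1e-9)

    def test_l2_matches_exhaustive_enumeration(self, params):
        """Convolution equals the 400-pair enumeration, binned identically."""
        rng = np.random.default_rng(11)
        w = random_window(rng, 2)
        null = null_score_distribution(w, params)
        lo = logodds_matrix(w, params)[:, :20]
        bins = np.floor(lo / params.grid_step + 1e-9).astype(int)
        mass = {}
        for a, b in itertools.product(range(20), range(20)):
            key = bins[0, a] + bins[1, b]
            mass[key] = mass.get(key, 0.0) + 0.05 * 0.05
        for key, m in mass.items():
            idx = key - null.min_bin
            assert 0 <= idx < len(null.mass)
            assert null.mass[idx] == pytest.approx(m, abs=1e-12)
        assert null.total_mass == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("length", [1, 3, 8, 20])
    def test_total_mass_one(self, params, length):
        rng = np.random.default_rng(length)
        null = null_score_distribution(random_window(rng, length), params)
        assert null.total_mass == pytest.approx(1.0, abs=1e-9)

    def test_tail_brackets_exact_enumeration(self, params):
        """Discretized tails bracket the exact tails within L lattice steps."""
        rng = np.random.default_rng(13)
        w = random_window(rng, 2)
        null = null_score_distribution(w, params)
        lo = logodds_matrix(w, params)[:, :20]
        sums = (lo[0][:, None] + lo[1][None, :]).ravel()
        step = params.grid_step
        for s in np.quantile(sums, [0.05, 0.25, 0.5, 0.75, 0.9, 0.99]):
            exact_hi = float(np.mean(sums >= s + 2 * step))
            exact_lo = float(np.mean(sums >= s - 3 * step))
            binned = float(null.tail(s))
            assert exact_hi - 1e-12 <= binned <= exact_lo + 1e-12

    def test_cache_keyed_by_row_multiset(self, params):
        rng = np.random.default_rng(5)
        w = random_window(rng, 4)
        cache = {}
        n1 = null_score_distribution(w, params, cache=cache)
        n2 = null_score_distribution(w[::-1].copy(), params, cache=cache)
        # row order does not change the convolved distribution
        assert n1.min_bin == n2.min_bin
        assert np.array_equal(n1.mass, n2.mass)
        assert len(cache) == 1


class TestPvalue:
    def test_closed_forms(self):
        null = NullDistribution(min_bin=0, mass=np.array([0.95, 0.05]), step=1.0, length=1)
        assert alignment_pvalue(1.5, null, 1) == pytest.approx(0.05, abs=1e-12)
        null2 = NullDistribution(min_bin=0, mass=np.array([0.99, 0.01]), step=1.0, length=1)
        assert alignment_pvalue(1.5, null2, 100) == pytest.approx(1 - 0.99**100, abs=1e-9)

    def test_monotone_in_score_and_offsets(self, params):
        rng = np.random.default_rng(21)
        null = null_score_distribution(random_window(rng, 6), params)
        scores = np.linspace(-10, 10, 50)
        ps = [alignment_pvalue(s, null, 10) for s in scores]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))
        for s in (-3.0, 0.0, 2.0):
            p1 = alignment_pvalue(s, null, 1)
            p5 = alignment_pvalue(s, null, 5)
            p50 = alignment_pvalue(s, null, 50)
            assert p1 <= p5 + 1e-15 <= p50 + 2e-15

    def test_certified_bound_dominates_exact(self, params):
        rng = np.random.default_rng(22)
        w = random_window(rng, 8)
        null = null_score_distribution(w, params)
        for s in (2.0, 5.0, 9.0):
            bound = certified_pvalue_bound(s, 8, 40, params.grid_step)
            exact = alignment_pvalue(s, null, 40)
            assert bound >= exact - 1e-12

    def test_pvalue_in_unit_interval(self, params):
        rng = np.random.default_rng(23)
        null = null_score_distribution(random_window(rng, 5), params)
        for s in (-50.0, 0.0, 50.0):
            assert 0 < alignment_pvalue(s, null, 7) <= 1.0


class TestSeparation:
    def test_true_source_beats_unrelated(self, params):
        """Windows from a known source align to it with lower p-values
        than to unrelated sequences in almost all paired trials."""
        rng = np.random.default_rng(31)
        n_trials = 2000
        wins = 0
        cache = {}
        for _ in range(n_trials):
            source = gen_sequence(300, seed=rng)
            start = int(rng.integers(0, 281))
            truth = GroundTruth("A", source.id, [(i + 1, "") for i in range(20)],
                                source.residues[start : start + 20],
                                list(range(start + 1, start + 21)))
            window = gen_profile(truth, 0.9, seed=rng).probs
            unrelated = gen_sequence(300, seed=rng, seq_id="u")
            null = null_score_distribution(window, params, cache=cache)
            best_t = best_gapless_alignment(window, [source], params)
            best_u = best_gapless_alignment(window, [unrelated], params)
            p_t = alignment_pvalue(best_t.score, null, best_t.n_offsets)
            p_u = alignment_pvalue(best_u.score, null, best_u.n_offsets)
            wins += p_t < p_u
        assert wins / n_trials >= 0.99
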