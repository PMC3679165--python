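"""Profile training: alignment, frequencies, weights, loop fits, tetrad
statistics and the logo-stability similarity coefficient."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from propellerscan.profile_builder import (
    AA_INDEX,
    AnnotatedRepeat,
    POSITION_INDEX,
    align_annotated_repeats,
    background_array,
    build_profile,
    estimate_frequencies,
    estimate_tetrad_model,
    fit_loop_scores,
    initial_regulator,
    modified_regulator,
    position_weight,
    similarity_coefficient,
    split_half_stability,
)
from propellerscan.repeat_model import SCORED_POSITIONS, PositionID
from propellerscan.synthetic_eval import generate_wd40

from conftest import make_repeat


def _uniform_repeat(seq_char="V", loops=(2, 2, 2), source="toy"):
    """A 30-residue repeat with loops (2,2,2), single residue type."""
    lda, lab, lbc = loops
    seq = seq_char * (24 + lda + lab + lbc)
    return make_repeat(seq, 0, 6 + lda, 12 + lda + lab, 18 + lda + lab + lbc, source)


class TestAlignment:
    def test_identical_repeats_single_residue_columns(self):
        cols = align_annotated_repeats([_uniform_repeat(), _uniform_repeat()])
        for pos in SCORED_POSITIONS:
            col = cols[pos]
            if col:  # loop slots beyond length 2 are absent
                assert set(col) == {"V"}

    def test_overlong_loop_excluded_from_loop_columns_only(self):
        # Lab of 16 residues: its Lab columns are dropped, strands still count
        lda, lab, lbc = 2, 16, 2
        seq = "A" * (24 + lda + lab + lbc)
        long_rep = make_repeat(seq, 0, 6 + lda, 12 + lda + lab, 18 + lda + lab + lbc)
        cols = align_annotated_repeats([long_rep, _uniform_repeat()])
        assert cols[PositionID("Lab", 1)] == ["V"]  # only the short repeat
        assert sorted(cols[PositionID("Sa", 1)]) == ["A", "V"]

    def test_hand_alignment_of_three_short_repeats(self):
        # loops (2,2,2): scored loop slots are Lda2, Lab1, Lab2 (Lda3, Lab3,
        # Lab4, Lbc3 fall beyond the loop length)
        reps = [_uniform_repeat(c) for c in "VIL"]
        cols = align_annotated_repeats(reps)
        assert cols[PositionID("Sd", 1)] == list("VIL")
        assert cols[PositionID("Lda", 2)] == list("VIL")
        assert cols[PositionID("Lda", 3)] == []
        assert cols[PositionID("Lbc", 3)] == []

    def test_malformed_annotation_rejected(self):
        bad = AnnotatedRepeat(sequence="A" * 30,
                              strand_starts={"Sd": 0, "Sa": 4, "Sb": 12, "Sc": 20},
                              source_id="bad")
        with pytest.raises(ValueError, match="bad"):
            align_annotated_repeats([bad, _uniform_repeat()])

    def test_needs_two_repeats(self):
        with pytest.raises(ValueError):
            align_annotated_repeats([_uniform_repeat()])


class TestFrequencies:
    def test_pseudo_count_arithmetic(self):
        cols = {pos: [] for pos in SCORED_POSITIONS}
        cols[PositionID("Sa", 1)] = ["V"] * 10
        freq = estimate_frequencies(cols, pseudo_count=1e-4)
        k = POSITION_INDEX[PositionID("Sa", 1)]
        assert freq.P[k, AA_INDEX["V"]] == pytest.approx((10 + 1e-4) / (10 + 20e-4))
        assert freq.P[k, AA_INDEX["A"]] == pytest.approx(1e-4 / (10 + 20e-4))

    def test_rows_sum_to_one_and_positive(self, trained_profile):
        P = trained_profile.frequencies.P
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-9)
        assert (P > 0).all()

    def test_empty_column_falls_back_to_background(self):
        cols = {pos: [] for pos in SCORED_POSITIONS}
        cols[PositionID("Sa", 1)] = ["V"] * 3
        freq = estimate_frequencies(cols)
        k = POSITION_INDEX[PositionID("Lbc", 3)]
        assert np.allclose(freq.P[k], background_array())

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError):
            estimate_frequencies({pos: [] for pos in SCORED_POSITIONS})


class TestPositionWeight:
    def test_uniform_gives_zero_information(self):
        assert position_weight(np.full(20, 0.05)) == pytest.approx(0.0, abs=1e-12)

    def test_single_residue_gives_max_information(self):
        p = np.zeros(20)
        p[0] = 1.0
        assert position_weight(p) == pytest.approx(math.log2(20))

    def test_two_residue_split(self):
        p = np.zeros(20)
        p[AA_INDEX["V"]] = p[AA_INDEX["I"]] = 0.5
        assert position_weight(p) == pytest.approx(math.log2(20) - 1.0)

    def test_entropy_mode_is_complementary(self):
        p = np.zeros(20)
        p[AA_INDEX["V"]] = p[AA_INDEX["I"]] = 0.5
        assert position_weight(p, "entropy") == pytest.approx(1.0)
        with pytest.raises(ValueError):
            position_weight(p, "nonsense")


class TestLoopScores:
    def test_mode_maximizes_fitted_score(self):
        table = fit_loop_scores({4: 50}, 1, 15, penalty_slope=1, smoothing_window=1)
        assert table.modal_length == 4

    def test_strictly_decreasing_beyond_l0(self, profile):
        for table in profile.loop_scores.values():
            ls = sorted(l for l in table.scores if l > table.l0)
            vals = [table.scores[l] for l in ls]
            assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_penalty_slope_in_extrapolation(self, profile):
        table = profile.loop_scores["Lab"]
        l_far = max(table.scores) + 5
        assert table.score(l_far + 5) == pytest.approx(
            table.score(l_far) - 5 * table.t
        )

    def test_toy_fit_matches_independent_oracle(self):
        counts, pc, lmin, lmax, slope, win = {2: 5, 3: 10, 4: 5}, 0.01, 1, 15, 1.0, 1.0
        table = fit_loop_scores(counts, lmin, lmax, pseudo_count=pc,
                                penalty_slope=slope, smoothing_window=win)
        # independent re-derivation of the documented procedure
        ls = np.arange(lmin, lmax + 1)
        total, K = sum(counts.values()), len(ls)
        f = np.array([counts.get(int(l), 0) + pc for l in ls]) / (total + pc * K)
        raw = np.log(f / (pc / (total + pc * K)))
        pad = np.concatenate([raw[:1], raw, raw[-1:]])
        sm = 0.25 * pad[:-2] + 0.5 * pad[1:-1] + 0.25 * pad[2:]
        fpad = np.concatenate([f[:1], f, f[-1:]])
        fs = 0.25 * fpad[:-2] + 0.5 * fpad[1:-1] + 0.25 * fpad[2:]
        fit = np.polyval(np.polyfit(ls, sm, 2, w=np.sqrt(fs)), ls)
        peak = int(ls[np.argmax(fit)])
        l0 = next((int(l) for l, v in zip(ls, fit) if l > peak and v < 1.0), int(ls[-1]))
        expected = {}
        for l, v in zip(ls, fit):
            if l <= l0:
                expected[int(l)] = float(v)
            else:
                lam = min(1.0, (l - l0) / max(win, 1.0))
                expected[int(l)] = float((1 - lam) * v + lam * (1.0 - slope * (l - l0)))
        for l in range(l0 + 1, lmax + 1):
            expected[l] = min(expected[l], expected[l - 1] - 1e-9)
        assert table.l0 == l0
        for l in expected:
            assert table.scores[l] == pytest.approx(expected[l], abs=1e-9)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            fit_loop_scores({}, 1, 15)


class TestTetradModel:
    def _pentad_repeat(self, i, pentad=True):
        # two repeats per source so the second has Lcd context
        lda, lab, lbc = 3, 2, 2
        unit = list("A" * (24 + lda + lab + lbc))
        seq = []
        for r in range(2):
            start = len(seq)
            u = list(unit)
            if pentad:
                u[6 + 2] = "H"       # Lda3
                u[12 + lda + lab + 3] = "S"  # Sb4
                u[18 + lda + lab + lbc] = "S"    # Sc1
                u[18 + lda + lab + lbc + 4] = "W"  # Sc5
            seq.extend(u)
            if r == 0:
                seq.extend(list("XDXX"))  # Lcd with Asp at position 2
        seq = "".join(seq)
        reps = []
        for start in (0, len(unit) + 4):
            reps.append(make_repeat(seq, start, start + 6 + lda,
                                    start + 12 + lda + lab,
                                    start + 18 + lda + lab + lbc, f"src{i}"))
        return reps

    def test_all_pentads_probability_near_one(self):
        reps = [r for i in range(5) for r in self._pentad_repeat(i)]
        model = estimate_tetrad_model(reps)
        assert model.p_pentad > 0.9
        assert model.p_triad >= model.p_tetrad >= model.p_pentad

    def test_no_his_means_floor_probabilities(self):
        reps = [r for i in range(5) for r in self._pentad_repeat(i, pentad=False)]
        model = estimate_tetrad_model(reps)
        assert model.p_pentad < 0.05
        assert model.p_triad < 0.05

    def test_mixed_counts(self):
        reps = []
        for i in range(10):
            reps.extend(self._pentad_repeat(i, pentad=i < 4))
        model = estimate_tetrad_model(reps)
        # only second repeats have context: 10 with context, 4 pentads
        assert model.p_pentad == pytest.approx((4 + 0.01) / (10 + 0.02), abs=1e-9)


class TestSimilarityCoefficient:
    def test_identity_is_exactly_one(self, profile):
        assert similarity_coefficient(profile.frequencies, profile.frequencies) == 1.0

    def test_disjoint_supports_give_zero(self):
        x, y = np.zeros((2, 4)), np.zeros((2, 4))
        x[:, 0] = 1.0
        y[:, 1] = 1.0
        assert similarity_coefficient(x, y) == 0.0

    def test_cosine_of_45_degrees(self):
        assert similarity_coefficient(
            np.array([1.0, 0.0]), np.array([1.0, 1.0]) / math.sqrt(2)
        ) == pytest.approx(1 / math.sqrt(2))

    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_symmetric_and_scale_invariant(self, seed, scale):
        rng = np.random.default_rng(seed)
        x, y = rng.random((2, 15)) + 1e-6, rng.random((2, 15)) + 1e-6
        s_xy = similarity_coefficient(x, y)
        assert similarity_coefficient(y, x) == pytest.approx(s_xy)
        assert similarity_coefficient(x * scale, y) == pytest.approx(s_xy)
        assert 0.0 <= s_xy <= 1.0 + 1e-12

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError):
            similarity_coefficient(np.zeros(5), np.ones(5))


class TestSplitHalf:
    def test_identical_repeats_give_unit_similarity(self):
        reps = [_uniform_repeat() for _ in range(20)]
        values, mean = split_half_stability(reps, n_trials=5, seed=1)
        assert mean == pytest.approx(1.0)

    def test_reproducible_under_seed(self, profile):
        reps = []
        for s in range(6):
            reps.extend(generate_wd40(profile, 7, seed=300 + s,
                                      sequence_id=f"s{s}").annotated_repeats())
        v1, m1 = split_half_stability(reps, n_trials=4, seed=7)
        v2, m2 = split_half_stability(reps, n_trials=4, seed=7)
        assert v1 == v2 and m1 == m2
        assert m1 > 0.8  # halves of a 42-repeat pool agree closely

    def test_too_few_repeats(self):
        with pytest.raises(ValueError):
            split_half_stability([_uniform_repeat()] * 3)


class TestParameterRecovery:
    def test_similarity_grows_with_sample_size(self, profile):
        sims = []
        for n_seq, base in ((8, 40), (30, 80)):  # ~56 and ~210 repeats
            reps = []
            for s in range(n_seq):
                reps.extend(generate_wd40(profile, 7, seed=base + s,
                                          sequence_id=f"r{s}").annotated_repeats())
            trained = build_profile(reps)
            sims.append(similarity_coefficient(trained.frequencies,
                                               profile.frequencies))
        assert sims[1] > sims[0] - 0.01
        assert sims[1] > 0.95


class TestRegulator:
    def test_sevenfold_maxima(self, profile):
        for table in (initial_regulator(), modified_regulator(), profile.regulator):
            assert table.value(7) > table.value(5)
            assert table.value(7) > table.value(9)
            assert table.value(14) > table.value(13) or table.value(14) > table.value(15)

    def test_initial_table_is_symmetric_across_centres(self):
        table = initial_regulator()
        assert table.value(7) == pytest.approx(table.value(14), abs=1e-6)

    def test_modified_discourages_incomplete_domains(self):
        table = modified_regulator()
        assert table.value(3) < table.value(6) < table.value(7)
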