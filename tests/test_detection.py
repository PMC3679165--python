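"""Pipeline stages: trimming, enumeration, filters, DP/GA assembly,
classification and secondary-structure emission."""

import itertools

import numpy as np
import pytest

from propellerscan.detection import (
    CandidatePool,
    DetectionConfig,
    candidate_at,
    classify,
    count_domains,
    detect,
    dp_optimal,
    early_exit,
    emit_secondary_structure,
    enumerate_candidates,
    ga_combine,
    overlap_filter,
    pool_threshold,
    apply_threshold,
    slice_domains,
    trim_termini,
)
from propellerscan.io_formats import report_to_json
from propellerscan.scoring import SSPrediction, lcd_score, regulator
from propellerscan.synthetic_eval import (
    generate_candidate_pool,
    generate_decoy,
    generate_wd40,
)


def hand_pool(entries, length=400):
    """CandidatePool from (start, lda, lab, lbc, score) tuples."""
    starts, a, b, c, scores = (np.array(v) for v in zip(*entries))
    s = scores.astype(float)
    return CandidatePool(
        sequence_id="hand", sequence="A" * length, start=starts.astype(int),
        lda=a.astype(int), lab=b.astype(int), lbc=c.astype(int),
        s_aa=s, s_loop=np.zeros(len(s)), s_corr=np.zeros(len(s)),
        s_ss=np.zeros(len(s)), score=s,
    )


class TestTrimTermini:
    def test_no_prediction_is_identity(self):
        assert trim_termini("A" * 300) == (0, 300)

    def test_all_sheet_is_identity(self):
        ss = SSPrediction(states="E" * 300, conf=[9] * 300)
        assert trim_termini("A" * 300, ss) == (0, 300)

    def test_helical_nterminus_is_stripped(self):
        ss = SSPrediction(states="H" * 100 + "E" * 300, conf=[9] * 400)
        lo, hi = trim_termini("A" * 400, ss)
        assert 80 <= lo <= 101
        assert hi == 400

    def test_interior_helix_is_kept(self):
        states = "E" * 100 + "H" * 60 + "E" * 100
        ss = SSPrediction(states=states, conf=[9] * len(states))
        assert trim_termini("A" * len(states), ss) == (0, len(states))


class TestEnumeration:
    def test_short_sequence_gives_empty_pool(self, profile):
        pool = enumerate_candidates("A" * 23, profile)
        assert pool.N == 0

    def test_generation_floor_holds(self, profile):
        truth = generate_wd40(profile, 3, seed=11)
        pool = enumerate_candidates(truth.sequence, profile, min_score=10.0)
        assert pool.N > 0
        assert (pool.score > 10.0).all()

    def test_planted_repeats_are_hit_within_one_residue(self, profile):
        truth = generate_wd40(profile, 7, seed=12)
        pool = enumerate_candidates(truth.sequence, profile)
        sa = pool.start + 6 + pool.lda
        sb = sa + 6 + pool.lab
        sc = sb + 6 + pool.lbc
        for rep in truth.planted_repeats:
            t = rep.strand_starts
            hit = (
                (np.abs(pool.start - t["Sd"]) <= 1)
                & (np.abs(sa - t["Sa"]) <= 1)
                & (np.abs(sb - t["Sb"]) <= 1)
                & (np.abs(sc - t["Sc"]) <= 1)
            )
            assert hit.any()

    def test_decoy_pool_much_smaller_than_planted(self, profile):
        truth = generate_wd40(profile, 7, seed=13)
        decoy = generate_decoy(len(truth.sequence), profile, seed=13)
        n_true = enumerate_candidates(truth.sequence, profile).N
        n_decoy = enumerate_candidates(decoy.sequence, profile).N
        assert n_decoy < n_true / 3

    def test_pool_matches_direct_scoring(self, profile):
        """Vectorized enumeration agrees with scoring one candidate directly."""
        from propellerscan.scoring import score_repeat

        truth = generate_wd40(profile, 2, seed=14)
        pool = enumerate_candidates(truth.sequence, profile)
        for i in (0, pool.N // 2, pool.N - 1):
            cand = pool.materialize(i)
            bd = score_repeat(
                candidate_at(truth.sequence, cand.start, cand.loop_lengths),
                profile,
            )
            assert bd.S_aa == pytest.approx(cand.score_terms["S_aa"], abs=1e-9)
            assert bd.S_loop_len == pytest.approx(cand.score_terms["S_loop_len"], abs=1e-9)


class TestOverlapFilter:
    def test_strong_dominator_removes_weaker_twin(self):
        pool = hand_pool([(0, 2, 2, 2, 50.0), (0, 2, 2, 2, 40.0)])
        kept = overlap_filter(pool)
        assert kept.N == 1 and kept.score[0] == 50.0

    def test_weak_overlaps_survive_below_dominance_level(self):
        pool = hand_pool([(0, 2, 2, 2, 30.0), (0, 2, 2, 2, 25.0)])
        assert overlap_filter(pool).N == 2

    def test_non_overlapping_all_survive(self):
        pool = hand_pool([(0, 2, 2, 2, 80.0), (100, 2, 2, 2, 12.0)])
        assert overlap_filter(pool).N == 2

    def test_dominator_must_strictly_exceed(self):
        pool = hand_pool([(0, 2, 2, 2, 50.0), (0, 2, 2, 2, 50.0)])
        assert overlap_filter(pool).N == 2  # ties are kept


class TestEarlyExitAndThreshold:
    def test_strict_comparison_at_45(self):
        assert early_exit(hand_pool([(0, 2, 2, 2, 44.9)]))
        assert not early_exit(hand_pool([(0, 2, 2, 2, 45.0)]))
        assert early_exit(hand_pool([(0, 2, 2, 2, 20.0)]).subset(np.array([], int)))

    def test_median_policy(self):
        pool = hand_pool([(0, 2, 2, 2, 20.0), (50, 2, 2, 2, 30.0),
                          (100, 2, 2, 2, 40.0), (150, 2, 2, 2, 50.0)])
        T = pool_threshold(pool)
        assert T == 35.0
        assert apply_threshold(pool, T).N == 2

    def test_floor_of_ten(self):
        assert pool_threshold(hand_pool([(0, 2, 2, 2, 12.0)] )) == 12.0
        # the floor binds when the median would undercut the generation floor
        assert pool_threshold(hand_pool([(0, 2, 2, 2, 9.0), (60, 2, 2, 2, 9.5)])) == 10.0


def brute_force_best(pool, profile):
    """Exhaustive oracle over ordered non-overlapping subsets."""
    idx = list(range(pool.N))
    ends, starts = pool.end, pool.start
    best = 0.0 if pool.N == 0 else float("-inf")
    for r in range(1, pool.N + 1):
        for combo in itertools.combinations(idx, r):
            order = sorted(combo, key=lambda i: starts[i])
            if any(starts[b] < ends[a] for a, b in zip(order, order[1:])):
                continue
            total = float(pool.score[list(order)].sum())
            total += sum(
                lcd_score(int(starts[b] - ends[a]), profile)
                for a, b in zip(order, order[1:])
            )
            total += regulator(r, profile.regulator)
            best = max(best, total)
    return best


def chain_value(pool, chain, profile):
    chain = sorted(chain, key=lambda i: pool.start[i])
    total = float(pool.score[list(chain)].sum()) if chain else 0.0
    total += sum(
        lcd_score(int(pool.start[b] - pool.end[a]), profile)
        for a, b in zip(chain, chain[1:])
    )
    if chain:
        total += regulator(len(chain), profile.regulator)
    return total


class TestExactDP:
    def test_empty_pool(self, profile):
        pool = hand_pool([(0, 2, 2, 2, 50.0)]).subset(np.array([], int))
        assert dp_optimal(pool, profile) == []

    def test_two_overlapping_candidates(self, profile):
        pool = hand_pool([(0, 2, 2, 2, 50.0), (10, 2, 2, 2, 70.0)])
        chain = dp_optimal(pool, profile)
        assert [float(pool.score[i]) for i in chain] == [70.0]

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_enumeration(self, profile, seed):
        rng = np.random.default_rng(seed)
        pool = generate_candidate_pool(int(rng.integers(3, 9)), seed=seed + 100)
        chain = dp_optimal(pool, profile)
        assert chain_value(pool, chain, profile) == pytest.approx(
            brute_force_best(pool, profile)
        )

    def test_monotone_under_candidate_addition(self, profile):
        pool = generate_candidate_pool(8, seed=42)
        base = chain_value(pool, dp_optimal(pool, profile), profile)
        # append a far-away strong candidate that overlaps nothing
        entries = list(zip(pool.start, pool.lda, pool.lab, pool.lbc, pool.score))
        longer = hand_pool(entries + [(2000, 2, 2, 2, 60.0)], length=2100)
        extended = chain_value(longer, dp_optimal(longer, profile), profile)
        assert extended >= base - 1e-9


class TestGeneticAlgorithm:
    def test_unique_compatible_set_is_found(self, profile):
        entries = [(i * 40, 1, 1, 1, 50.0 + i) for i in range(7)]
        pool = hand_pool(entries)
        chain = ga_combine(pool, profile, seed=0)
        assert sorted(chain) == list(range(7))

    def test_deterministic_under_seed(self, profile):
        pool = generate_candidate_pool(12, seed=77)
        assert ga_combine(pool, profile, seed=5) == ga_combine(pool, profile, seed=5)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exact_dp_on_small_pools(self, profile, seed):
        rng = np.random.default_rng(seed)
        pool = generate_candidate_pool(int(rng.integers(3, 13)), seed=seed + 3000)
        ga = chain_value(pool, ga_combine(pool, profile, seed=seed), profile)
        dp = chain_value(pool, dp_optimal(pool, profile), profile)
        assert ga == pytest.approx(dp)


class TestClassification:
    def test_domain_counting_rule(self):
        assert count_domains(7) == 1
        assert count_domains(8) == 1
        assert count_domains(9) == 2
        assert count_domains(16) == 2
        assert count_domains(17) == 3
        assert count_domains(33) == 5

    def test_slice_domains_merges_short_tail(self):
        chain = list(range(9))  # stand-ins
        slices = slice_domains(chain)
        assert [len(s) for s in slices] == [9]
        assert [len(s) for s in slice_domains(list(range(14)))] == [7, 7]
        assert [len(s) for s in slice_domains(list(range(13)))] == [7, 6]

    def test_verdict_boundary_at_asr_threshold(self, profile):
        truth = generate_wd40(profile, 7, seed=21)
        rep = detect(truth.sequence, profile, seed=21)
        assert rep.verdict == "WD40" and not rep.tetrad_found
        asr = rep.asr[0]
        at = detect(truth.sequence, profile, seed=21,
                    config=DetectionConfig(asr_threshold=asr))
        above = detect(truth.sequence, profile, seed=21,
                       config=DetectionConfig(asr_threshold=asr + 1e-6))
        assert at.verdict == "WD40"       # threshold is inclusive
        assert above.verdict == "not-WD40"

    def test_verdict_boundary_at_six_repeats(self, profile):
        truth = generate_wd40(profile, 6, seed=22)
        rep6 = detect(truth.sequence, profile, seed=22)
        assert rep6.verdict == "WD40"
        rep7min = detect(truth.sequence, profile, seed=22,
                         config=DetectionConfig(min_repeats=7))
        assert rep7min.verdict == "not-WD40"

    def test_tetrad_rescues_low_asr(self, profile):
        truth = generate_wd40(profile, 7, seed=23, force_pentad=True)
        rep = detect(truth.sequence, profile, seed=23)
        assert rep.tetrad_found
        strict = detect(truth.sequence, profile, seed=23,
                        config=DetectionConfig(asr_threshold=1e6))
        assert strict.verdict == "WD40"  # tetrad evidence alone suffices

    def test_nine_repeats_count_as_two_domains(self, profile):
        truth = generate_wd40(profile, 9, seed=24)
        rep = detect(truth.sequence, profile, seed=24)
        assert rep.verdict == "WD40"
        assert sum(d.N_rep for d in rep.domains) >= 9
        assert rep.n_domains == 2


class TestSecondaryStructureOutput:
    def test_no_domains_is_all_coil(self):
        ss, segments = emit_secondary_structure([], 50)
        assert ss == "C" * 50 and segments == []

    def test_seven_repeat_synthetic_has_28_strand_segments(self, profile):
        truth = generate_wd40(profile, 7, seed=25)
        rep = detect(truth.sequence, profile, seed=25)
        ss, segments = emit_secondary_structure(rep.domains, len(truth.sequence))
        assert len(ss) == len(truth.sequence)
        assert len(segments) == 28
        assert all(s1 - s0 == 6 for _, s0, s1 in segments)
        assert ss.count("E") <= 28 * 6

    def test_single_repeat_pattern(self, profile):
        cand = candidate_at("A" * 40, 0, {"Lda": 1, "Lab": 1, "Lbc": 1})
        cand.S_repeat, cand.score_terms = 50.0, {"S_corr": 0.0}
        from propellerscan.repeat_model import domain_from_repeats

        ss, segments = emit_secondary_structure([domain_from_repeats([cand])], 40)
        assert ss[:6] == "EEEEEE" and ss[6] == "C"
        assert [seg[0] for seg in segments] == ["d1", "a1", "b1", "c1"]


class TestPipeline:
    def test_byte_identical_reports_under_fixed_seed(self, profile):
        truth = generate_wd40(profile, 7, seed=30)
        r1 = detect(truth.sequence, profile, seed=30)
        r2 = detect(truth.sequence, profile, seed=30)
        assert report_to_json(r1) == report_to_json(r2)

    def test_decoy_exits_early(self, profile):
        decoy = generate_decoy(300, profile, seed=31)
        rep = detect(decoy.sequence, profile, seed=31)
        assert rep.verdict == "not-WD40"

    def test_helix_rich_decoy_is_trimmed_and_rejected(self, profile):
        decoy = generate_decoy(300, profile, seed=32, mode="helix-rich")
        lo, hi = trim_termini(decoy.sequence, decoy.ss)
        assert lo >= 30  # at least one terminal window stripped
        rep = detect(decoy.sequence, profile, ss=decoy.ss, seed=32)
        assert rep.verdict == "not-WD40"

    def test_report_invariant_on_wd40_verdict(self, profile):
        truth = generate_wd40(profile, 7, seed=33)
        rep = detect(truth.sequence, profile, seed=33)
        if rep.verdict == "WD40":
            for dom, asr in zip(rep.domains, rep.asr):
                assert dom.N_rep >= 6
                assert asr >= 48.0 or rep.tetrad_found
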