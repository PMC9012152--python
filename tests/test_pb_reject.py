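"""Rejection cascade: K-Medoids clustering, rechecks, and verdicts."""

import itertools
import math

import numpy as np
import pytest

from pafscreen import PipelineConfig, RhythmSpec, VerdictClass, cluster_rr, gen_rr
from pafscreen.pb_reject import (
    _fine_tune,
    _within_group_std,
    classify_candidate,
    exact_kmedoids,
    geminy_pattern_present,
    geminy_recheck,
    kmedoids,
    pam_kmedoids,
    recheck_rc,
    segment_rr_slice,
    select_median_group,
    single_pb_recheck,
)
from pafscreen.pipeline import detect_paf
from pafscreen.screening import CandidateSegment, candidate_segments, rc_series
from tests.conftest import CAL_THRESHOLD


def exhaustive_kmedoids_cost(X, k=3):
    """Independent oracle: minimum cost over all medoid subsets."""
    n = len(X)
    best = math.inf
    for combo in itertools.combinations(range(n), k):
        cost = sum(min(math.dist(X[i], X[m]) for m in combo) for i in range(n))
        best = min(best, cost)
    return best


class TestKMedoids:
    def test_matches_independent_oracle_on_small_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            n = int(rng.integers(6, 13))
            X = rng.normal(size=(n, 2))
            _, _, cost = kmedoids(X, k=3)
            assert cost == pytest.approx(exhaustive_kmedoids_cost(X), abs=1e-9)

    def test_exact_assignment_uses_nearest_medoid(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(12, 2))
        medoids, assignment, cost = exact_kmedoids(X, 3)
        dist = np.linalg.norm(X[:, None, :] - X[medoids][None, :, :], axis=2)
        assert np.array_equal(assignment, np.argmin(dist, axis=1))
        assert cost == pytest.approx(dist.min(axis=1).sum())

    def test_pam_near_optimal_and_deterministic(self):
        # PAM is a local search used for long segments only; it must be
        # deterministic and close to the optimum on small instances.
        rng = np.random.default_rng(8)
        worst = 1.0
        for _ in range(50):
            X = rng.normal(size=(12, 2))
            m1, a1, c1 = pam_kmedoids(X, 3)
            m2, a2, c2 = pam_kmedoids(X, 3)
            assert np.array_equal(m1, m2) and np.array_equal(a1, a2) and c1 == c2
            worst = max(worst, c1 / exhaustive_kmedoids_cost(X))
        assert worst < 1.25

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            kmedoids(np.zeros((2, 2)), k=3)


class TestClusterRR:
    def test_bigeminy_long_group_is_the_pauses(self, bigeminy_31):
        rr = bigeminy_31.rr
        res = cluster_rr(rr)
        long_members = rr[res.assignment == res.n_groups - 1]
        assert np.all(long_members > 0.9)
        assert len(long_members) == np.count_nonzero(rr > 0.9)

    def test_trigeminy_groups_match_three_lengths(self, trigeminy_31):
        rr = trigeminy_31.rr
        res = cluster_rr(rr)
        assert res.group_means == pytest.approx([0.48, 0.80, 1.12], abs=0.08)
        # every short interval in group 0, every pause in group 2
        assert np.all(res.assignment[rr < 0.6] == 0)
        assert np.all(res.assignment[rr > 1.0] == 2)

    def test_af_groups_have_no_clear_rr_separation(self):
        means_spread = []
        for seed in range(20):
            rr = gen_rr(RhythmSpec("AF", 31, seed=seed)).rr
            res = cluster_rr(rr)
            means_spread.append(np.ptp(res.group_means) / np.mean(rr))
        # group mean RRs stay nearly equal relative to the AF variability
        assert np.median(means_spread) < 0.5

    def test_group_means_sorted_and_partition_complete(self, af_31):
        res = cluster_rr(af_31.rr)
        assert np.all(np.diff(res.group_means) >= 0)
        assert set(np.unique(res.assignment)) <= {0, 1, 2}
        assert len(res.assignment) == af_31.n_rr

    def test_degenerate_constant_input(self):
        res = cluster_rr(np.full(10, 0.8))
        assert res.degenerate
        assert res.n_groups == 1

    def test_fine_tune_never_increases_summed_std(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            rr = rng.uniform(0.4, 1.4, size=24)
            a0 = rng.integers(0, 3, size=24)
            while len(np.unique(a0)) < 3:
                a0 = rng.integers(0, 3, size=24)
            a1 = _fine_tune(rr, a0, 3)
            assert _within_group_std(rr, a1, 3) <= _within_group_std(rr, a0, 3) + 1e-12

    def test_fine_tune_fixes_straggler_in_separated_bands(self):
        # three clean bands with one long interval misassigned to the shorts
        rr = np.array([0.5] * 8 + [0.8] * 8 + [1.2] * 8)
        rr = rr + np.linspace(0, 0.01, 24)  # break exact ties
        a0 = np.array([0] * 8 + [1] * 8 + [2] * 8)
        a0[23] = 0
        a1 = _fine_tune(rr, a0, 3)
        assert a1[23] == 2
        assert _within_group_std(rr, a1, 3) < _within_group_std(rr, a0, 3)

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            cluster_rr([0.8] * 5)


class TestCascadeRules:
    def test_single_pb_run_length_boundary(self):
        seg = lambda run: CandidateSegment(0, run, run)
        assert single_pb_recheck(seg(7)) is True
        assert single_pb_recheck(seg(10)) is True  # "exceeds" means > 10
        assert single_pb_recheck(seg(11)) is False

    def test_select_median_group_arithmetic(self):
        from pafscreen.pb_reject import ClusterResult

        rr = np.array([0.5] * 5 + [0.8] * 16 + [1.1] * 5)
        res = ClusterResult(
            assignment=np.array([0] * 5 + [1] * 16 + [2] * 5),
            medoids=np.zeros((3, 2)),
            group_means=np.array([0.5, 0.8, 1.1]),
            degenerate=False,
        )
        assert select_median_group(res, rr) == 1

    def test_select_median_group_on_multi_pb_segment(self, config):
        rr_seq = gen_rr(RhythmSpec("MULTI_PB", 31, seed=21))
        res = cluster_rr(rr_seq.rr)
        g = select_median_group(res, rr_seq.rr)
        assert res.group_means[g] == pytest.approx(0.8, rel=0.1)

    def test_recheck_constant_subsequence_rejects(self):
        assert recheck_rc(np.full(20, 0.8), 0.065) is True

    def test_recheck_small_sample_rule(self):
        assert recheck_rc(np.array([0.4, 1.3, 0.5, 1.2, 0.45]), 0.065) is True

    def test_recheck_af_median_group_stays_loud(self):
        kept = 0
        for seed in range(100):
            rr = gen_rr(RhythmSpec("AF", 31, seed=seed)).rr
            res = cluster_rr(rr)
            g = select_median_group(res, rr)
            if not recheck_rc(rr[res.assignment == g], CAL_THRESHOLD):
                kept += 1
        assert kept >= 95

    def test_geminy_pattern_on_trigeminy_clusters(self, trigeminy_31):
        res = cluster_rr(trigeminy_31.rr)
        assert geminy_pattern_present(res) is True

    def test_geminy_pattern_on_alternating_assignment(self):
        from pafscreen.pb_reject import ClusterResult

        # canonical bigeminy grouping: every window holds 3 shorts, 3 longs
        a = np.tile([0, 2], 15)
        res = ClusterResult(
            assignment=a,
            medoids=np.zeros((3, 2)),
            group_means=np.array([0.48, 0.8, 1.12]),
            degenerate=False,
        )
        assert geminy_pattern_present(res) is True

    def test_geminy_pattern_rejects_unbalanced_window(self):
        from pafscreen.pb_reject import ClusterResult

        rr = np.concatenate([np.full(10, 0.5), np.full(2, 1.2)])
        res = ClusterResult(
            assignment=np.array([0] * 10 + [2] * 2),
            medoids=np.zeros((3, 2)),
            group_means=np.array([0.5, 0.5, 1.2]),
            degenerate=False,
        )
        assert geminy_pattern_present(res) is False

    def test_geminy_recheck_rejects_synthetic_geminy(self, bigeminy_31, trigeminy_31):
        for seq in (bigeminy_31, trigeminy_31):
            res = cluster_rr(seq.rr)
            assert geminy_recheck(seq.rr, res, CAL_THRESHOLD) is True


class TestClassifyCandidate:
    def _candidate(self, rr_seq, config):
        series = rc_series(rr_seq, config.threshold, config.std_mode)
        segs = candidate_segments(series, config.merge_gap_beats)
        assert segs, "expected at least one candidate"
        return segs

    def test_single_pb_segment_rejected_as_single(self, config):
        rr_seq = gen_rr(RhythmSpec("SINGLE_PB", 31, seed=2))
        for seg in self._candidate(rr_seq, config):
            v = classify_candidate(seg, rr_seq, config.threshold)
            assert v.klass is VerdictClass.SINGLE_PB

    def test_bigeminy_segment_rejected(self, config, bigeminy_31):
        for seg in self._candidate(bigeminy_31, config):
            v = classify_candidate(seg, bigeminy_31, config.threshold)
            assert v.klass is not VerdictClass.AF

    def test_af_segment_kept(self, config, af_31):
        segs = self._candidate(af_31, config)
        assert any(
            classify_candidate(s, af_31, config.threshold).klass is VerdictClass.AF
            for s in segs
        )

    def test_af_only_when_every_rejection_fails(self, config):
        # over a mixed corpus, an AF verdict implies run length > 10 and
        # both rechecks stayed above threshold
        rng = np.random.default_rng(77)
        for s in rng.integers(0, 2**31 - 1, size=40):
            rr_seq = gen_rr(RhythmSpec("AF", 31, seed=int(s)))
            for seg, v in detect_paf(rr_seq, config).verdicts:
                if v.klass is VerdictClass.AF:
                    assert seg.rc_run_length > config.single_pb_max_run

    def test_determinism(self, config, af_31):
        (seg, *_) = self._candidate(af_31, config)
        v1 = classify_candidate(seg, af_31, config.threshold, seed=0)
        v2 = classify_candidate(seg, af_31, config.threshold, seed=0)
        assert v1.klass == v2.klass and v1.evidence == v2.evidence

    def test_segment_rr_slice_covers_flagged_windows(self, af_31, config):
        (seg, *_) = self._candidate(af_31, config)
        sl = segment_rr_slice(seg, af_31)
        assert len(sl) == min(seg.end_beat + 5, af_31.n_rr) - seg.start_beat
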