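"""Synthetic rhythm generator: per-class RR structure, labels, determinism."""

import numpy as np
import pytest

from pafscreen import RhythmClass, RhythmSpec, gen_recording, gen_rr, render_ecg
from pafscreen.synth import RR_MAX, RR_MIN, read_rr_csv, write_rr_csv


class TestGenRR:
    def test_nsr_low_variability_no_pb(self):
        seq = gen_rr(RhythmSpec("NSR", 31, seed=1))
        assert seq.n_rr == 30
        cv = np.std(seq.rr) / np.mean(seq.rr)
        assert cv < 0.05
        assert not np.any(seq.beat_labels == "PB")

    def test_bigeminy_alternates_short_long(self):
        seq = gen_rr(RhythmSpec("BIGEMINY", 31, base_rr=0.8, seed=3))
        short, long_ = seq.rr[0::2], seq.rr[1::2]
        assert np.allclose(short, 0.48, atol=0.08)
        assert np.allclose(long_, 1.12, atol=0.15)
        assert np.all(short < long_.min())
        # premature beat labels on every other beat
        assert np.all(seq.beat_labels[1::2] == "PB")

    def test_trigeminy_repeats_normal_short_long(self):
        seq = gen_rr(RhythmSpec("TRIGEMINY", 31, base_rr=0.8, seed=3))
        assert np.allclose(seq.rr[0::3], 0.80, atol=0.1)
        assert np.allclose(seq.rr[1::3], 0.48, atol=0.08)
        assert np.allclose(seq.rr[2::3], 1.12, atol=0.15)
        assert np.all(seq.beat_labels[2::3] == "PB")

    def test_single_pb_coupling_then_pause(self):
        spec = RhythmSpec("SINGLE_PB", 31, seed=5)
        seq = gen_rr(spec)
        pb = np.flatnonzero(seq.beat_labels == "PB")
        assert pb.shape == (1,)
        p = pb[0]
        assert 3 <= p <= 27  # not within 3 beats of either end
        assert seq.rr[p - 1] == pytest.approx(0.6 * 0.8, rel=0.1)
        assert seq.rr[p] == pytest.approx(1.4 * 0.8, rel=0.1)
        assert seq.rr[p - 1] < 0.8 < seq.rr[p]

    def test_multi_pb_count_and_spacing(self):
        seq = gen_rr(RhythmSpec("MULTI_PB", 31, n_pb=4, seed=9))
        pb = np.flatnonzero(seq.beat_labels == "PB")
        assert pb.shape == (4,)
        assert np.all(np.diff(pb) >= 3)

    @pytest.mark.parametrize("cls", list(RhythmClass))
    def test_bounds_determinism_and_label_count(self, cls):
        spec = RhythmSpec(cls, 60, seed=11)
        a, b = gen_rr(spec), gen_rr(spec)
        assert np.array_equal(a.rr, b.rr)
        assert np.array_equal(a.beat_labels, b.beat_labels)
        assert np.all((a.rr >= RR_MIN) & (a.rr <= RR_MAX))
        n_pb = int(np.count_nonzero(a.beat_labels == "PB"))
        expected = {
            RhythmClass.NSR: 0,
            RhythmClass.AF: 0,
            RhythmClass.SINGLE_PB: 1,
            RhythmClass.MULTI_PB: 4,
            RhythmClass.BIGEMINY: 30,  # beats 1,3,...,59
            RhythmClass.TRIGEMINY: 20,  # beats 2,5,...,59
        }[cls]
        assert n_pb == expected

    def test_af_cv_matches_spec_at_large_n(self):
        spec = RhythmSpec("AF", 1000, seed=2)
        seq = gen_rr(spec)
        cv = np.std(seq.rr) / np.mean(seq.rr)
        assert abs(cv - spec.af_cv) / spec.af_cv < 0.30

    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_beats", 3),
            ("base_rr", -1.0),
            ("nsr_cv", 1.5),
            ("coupling_fraction", 1.2),
            ("compensatory_fraction", 0.9),
            ("n_pb", 0),
        ],
    )
    def test_invalid_spec_rejected_naming_field(self, field, value):
        kwargs = {"rhythm_class": "NSR", "n_beats": 31, field: value}
        with pytest.raises(ValueError, match=field):
            RhythmSpec(**kwargs)


class TestGenRecording:
    def test_episode_boundaries_recoverable(self):
        eps = [
            (RhythmSpec("NSR", 100), "N"),
            (RhythmSpec("AF", 80), "AFIB"),
            (RhythmSpec("NSR", 100), "N"),
        ]
        rec = gen_recording(eps, seed=1)
        assert rec.rhythm_annotation == [(0, "N"), (100, "AFIB"), (180, "N")]
        assert rec.rr.n_beats == 280
        assert len(rec.beat_labels) == 280

    def test_single_episode_annotation(self):
        rec = gen_recording([(RhythmSpec("NSR", 50), "N")], seed=0)
        assert rec.rhythm_annotation == [(0, "N")]

    def test_alternating_episodes(self):
        eps = []
        for _ in range(5):
            eps.append((RhythmSpec("NSR", 40), "N"))
            eps.append((RhythmSpec("AF", 40), "AFIB"))
        rec = gen_recording(eps, seed=3)
        starts = [s for s, lab in rec.rhythm_annotation if lab == "AFIB"]
        assert starts == [40, 120, 200, 280, 360]

    def test_empty_episode_list_rejected(self):
        with pytest.raises(ValueError):
            gen_recording([], seed=0)


class TestRenderECG:
    def test_noiseless_peaks_at_true_indices(self):
        rec = gen_recording([(RhythmSpec("NSR", 31), "N")], seed=4)
        sig, truth = render_ecg(rec, fs=250)
        for s in truth:
            lo, hi = max(0, s - 15), min(len(sig), s + 16)
            assert lo + np.argmax(np.abs(sig[lo:hi])) == s

    def test_signal_length_is_duration_plus_pad(self):
        rec = gen_recording([(RhythmSpec("NSR", 31), "N")], seed=4)
        sig, _ = render_ecg(rec, fs=250)
        half = int(round(0.040 * 250))
        assert len(sig) == int(round(np.sum(rec.rr.rr) * 250)) + 2 * half + 1

    def test_low_fs_rejected(self):
        rec = gen_recording([(RhythmSpec("NSR", 31), "N")], seed=4)
        with pytest.raises(ValueError, match="fs"):
            render_ecg(rec, fs=50)


class TestRRCsvRoundTrip:
    def test_round_trip_preserves_structure(self, tmp_path, nsr_af_nsr_recording):
        path = tmp_path / "rec.csv"
        write_rr_csv(path, nsr_af_nsr_recording)
        back = read_rr_csv(path)
        assert back.rhythm_annotation == nsr_af_nsr_recording.rhythm_annotation
        assert np.array_equal(back.beat_labels, nsr_af_nsr_recording.beat_labels)
        np.testing.assert_allclose(
            back.rr.rr, nsr_af_nsr_recording.rr.rr, atol=2e-6
        )
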