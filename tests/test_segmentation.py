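"""Detection rules: thresholding, component location, pruning, labelling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from phonoseg import (CandidateSegment, RPeakSeries, RRStats, SimConfig,
                      Recording, classify_sounds, generate_recording,
                      locate_components, prune_false_positives,
                      segment_recording, threshold_segments)


def threshold_oracle(env, mean_rr_ms, fs=1000.0, thr_frac=0.05,
                     join_frac=0.10):
    """Two-pass brute-force run finding + gap merging."""
    env = np.asarray(env, dtype=float)
    if env.max(initial=0.0) <= 0:
        return []
    thr = thr_frac * env.max()
    runs = []
    in_run = False
    for i, v in enumerate(env):
        if v > thr and not in_run:
            runs.append([i, i + 1])
            in_run = True
        elif v > thr:
            runs[-1][1] = i + 1
        else:
            in_run = False
    merged = []
    gap = join_frac * mean_rr_ms * fs / 1000.0
    for s, e in runs:
        if merged and s - merged[-1][1] < gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [tuple(r) for r in merged]


class TestThresholdSegments:
    def test_two_separate_segments(self):
        env = np.array([0, 0, 1, 1, 0, 0, 1, 1, 0], dtype=float)
        assert threshold_segments(env, mean_rr=10.0) == [(2, 4), (6, 8)]

    def test_gap_joining(self):
        env = np.array([0, 0, 1, 1, 0, 0, 1, 1, 0], dtype=float)
        assert threshold_segments(env, mean_rr=1000.0) == [(2, 8)]

    def test_all_zero_envelope(self):
        assert threshold_segments(np.zeros(100), mean_rr=1000.0) == []

    @given(hnp.arrays(np.float64, st.integers(10, 200),
                      elements=st.floats(0, 10, allow_nan=False)),
           st.floats(50, 2000))
    def test_matches_bruteforce(self, env, mean_rr):
        assert threshold_segments(env, mean_rr) == threshold_oracle(env,
                                                                    mean_rr)


def two_lobe_env(p, q, sigma=6.0, n=200, a=1.0, b=0.9):
    i = np.arange(n, dtype=float)
    return (a * np.exp(-0.5 * ((i - p) / sigma) ** 2)
            + b * np.exp(-0.5 * ((i - q) / sigma) ** 2))


def deepest_min_oracle(seg):
    """Brute-force scan: deepest interior local minimum (None if absent)."""
    cands = [i for i in range(1, len(seg) - 1)
             if seg[i] < seg[i - 1] and seg[i] < seg[i + 1]]
    if not cands:
        return None
    return min(cands, key=lambda i: (seg[i], i))


class TestLocateComponents:
    def test_two_lobes(self):
        env = two_lobe_env(60, 120)
        got = locate_components(env, 10, 190)
        oracle_split = 10 + deepest_min_oracle(env[10:190])
        assert not got.degenerate
        assert got.split == oracle_split
        assert got.c1 == 60 and got.c2 == 120

    def test_single_lobe_degenerate(self):
        i = np.arange(200, dtype=float)
        env = np.exp(-0.5 * ((i - 100) / 8.0) ** 2)
        got = locate_components(env, 50, 150)
        assert got.degenerate
        assert got.c1 == got.c2 == got.split == 100

    def test_deeper_of_two_minima_wins(self):
        # Two interior minima of unequal depth inside the inter-lobe
        # valley: the deeper one is the split.
        env = two_lobe_env(50, 150, sigma=12.0)
        env[95] -= 0.02   # shallow dip
        env[105] -= 0.05  # deeper dip
        got = locate_components(env, 10, 190)
        assert got.split == 10 + deepest_min_oracle(env[10:190])
        assert got.split == 105

    def test_min_peak_separation_guards_ripples(self):
        # A ripple twin-peak 5 samples from the main lobe must not be
        # mistaken for a second component when the separation floor is the
        # envelope window length.
        i = np.arange(200, dtype=float)
        env = np.exp(-0.5 * ((i - 100) / 9.0) ** 2)
        env[105] += 0.1  # ripple forms a local peak 5 samples out
        got = locate_components(env, 50, 150, min_peak_sep=20)
        assert got.degenerate

    def test_min_prominence_flags_flat_merges(self):
        env = two_lobe_env(90, 110, sigma=12.0)  # heavily merged pair
        got = locate_components(env, 40, 160, min_prominence=0.2)
        assert got.degenerate

    def test_too_short_segment_rejected(self):
        with pytest.raises(ValueError):
            locate_components(np.zeros(10), 4, 6)


def seg(c1, env_val, start=None, end=None):
    start = c1 - 10 if start is None else start
    end = c1 + 30 if end is None else end
    return CandidateSegment(start=start, end=end, split=c1 + 10, c1=c1,
                            c2=c1 + 20), env_val


class TestPruneFalsePositives:
    def make(self, spec):
        cands = []
        env = np.zeros(20000)
        for c1, v in spec:
            s, val = seg(c1, v)
            env[c1] = val
            cands.append(s)
        return cands, env

    def test_close_pair_drops_weaker(self):
        cands, env = self.make([(1000, 1.0), (1100, 0.4)])
        out = prune_false_positives(cands, env, mean_rr=1000.0)
        assert [c.c1 for c in out] == [1000]

    def test_distant_pair_untouched(self):
        cands, env = self.make([(1000, 1.0), (1300, 0.4)])
        out = prune_false_positives(cands, env, mean_rr=1000.0)
        assert [c.c1 for c in out] == [1000, 1300]

    def test_triple_rule(self):
        # Gaps 350/350 ms, both under 40% of a 1000-ms RR: the weakest
        # first component of the triple goes.
        cands, env = self.make([(1000, 1.0), (1350, 0.2), (1700, 0.8)])
        out = prune_false_positives(cands, env, mean_rr=1000.0)
        assert [c.c1 for c in out] == [1000, 1700]

    def test_single_candidate_passthrough(self):
        cands, env = self.make([(1000, 1.0)])
        assert prune_false_positives(cands, env, 1000.0) == cands

    def test_empty_passthrough(self):
        assert prune_false_positives([], np.zeros(10), 1000.0) == []

    def test_iterates_to_stability(self):
        # A chain of close candidates collapses to the single strongest.
        cands, env = self.make([(1000, 0.3), (1100, 0.5), (1200, 1.0)])
        out = prune_false_positives(cands, env, mean_rr=1000.0)
        assert [c.c1 for c in out] == [1200]


class TestClassifySounds:
    def setup_method(self):
        self.peaks = RPeakSeries(np.arange(1000, 11000, 1000), 1000.0)
        self.rr = RRStats(mean_rr=1000.0, per_beat_rr=np.full(9, 1000.0))

    def classify(self, c1s):
        env = np.zeros(20000)
        cands = []
        for c1 in c1s:
            env[c1] = 1.0
            cands.append(CandidateSegment(start=c1 - 10, end=c1 + 30,
                                          split=c1 + 10, c1=c1, c2=c1 + 20))
        return classify_sounds(cands, self.peaks, self.rr, env=env)

    def test_s1_window(self):
        out = self.classify([2040])  # ref 2000, 40 ms < 18% of 1000
        assert len(out) == 1
        assert out[0].label == "S1"
        assert out[0].ref_rpeak == 2000
        assert out[0].component_labels == ("mitral", "tricuspid")

    def test_s2_window(self):
        out = self.classify([2350])  # 350 ms >= 180 ms
        assert len(out) == 1
        assert out[0].label == "S2"
        assert out[0].component_labels == ("aortic", "pulmonary")

    def test_pre_rpeak_window(self):
        out = self.classify([1960])  # 40 ms before the 2000 R-peak
        assert len(out) == 1
        assert out[0].label == "S1" and out[0].ref_rpeak == 2000

    def test_outside_both_windows_discarded(self):
        assert self.classify([1940]) == []  # 60 ms before R: no window

    def test_one_sound_per_label_per_cycle(self):
        env = np.zeros(20000)
        cands = []
        for c1, amp in [(2040, 0.8), (2100, 1.0)]:  # both in S1 window? no:
            # 2100 is 100 ms after ref, still <180 -> competing S1s
            env[c1] = amp
            cands.append(CandidateSegment(start=c1 - 10, end=c1 + 30,
                                          split=c1 + 10, c1=c1, c2=c1 + 20))
        out = classify_sounds(cands, self.peaks, self.rr, env=env)
        assert len(out) == 1
        assert out[0].segment.c1 == 2100  # higher envelope wins


class TestSegmentRecording:
    def test_clean_record_full_recovery(self, clean_record, segmented_clean):
        # One S1 and one S2 per beat; components within +-3 ms of planted
        # times for at least 95% of sounds (sounds at the record's
        # amplitude ceiling are flattened by the Shannon transform and may
        # stray up to ~10 ms; see the acceptance suite).
        _, truth = clean_record
        res = segmented_clean
        n_beats = len(res.rpeaks)
        s1 = [s for s in res.sounds if s.label == "S1"]
        s2 = [s for s in res.sounds if s.label == "S2"]
        assert len(s1) == n_beats and len(s2) == n_beats
        comp = truth.component_times_ms()
        errs = []
        for snd in res.sounds:
            first, second = comp[snd.label]
            j = np.argmin(np.abs(first - snd.segment.c1))
            errs.append(max(abs(snd.segment.c1 - first[j]),
                            abs(snd.segment.c2 - second[j])))
        errs = np.asarray(errs)
        assert np.mean(errs <= 3.0) >= 0.95
        assert errs.max() <= 10.0

    def test_pure_noise_yields_no_sounds(self, rng):
        rec = Recording(ecg=rng.standard_normal(30000),
                        pcg=rng.standard_normal(30000))
        res = segment_recording(rec)
        assert res.sounds == []

    def test_pvc_cycle_contributes_no_sounds(self):
        rec, truth = generate_recording(SimConfig(duration=60.0, pvc_count=2,
                                                  seed=4))
        res = segment_recording(rec)
        pvc_r = truth.true_rpeaks[truth.pvc_beats]
        for snd in res.sounds:
            assert all(abs(snd.ref_rpeak - p) > 100 for p in pvc_r)

    def test_window_invariants_hold(self, segmented_default):
        res = segmented_default
        idx = res.rpeaks.indices
        for snd in res.sounds:
            k = int(np.searchsorted(idx, snd.ref_rpeak))
            rr = (idx[k + 1] - idx[k] if k + 1 < len(idx)
                  else res.rr.mean_rr)
            delta = snd.segment.c1 - snd.ref_rpeak
            if snd.label == "S1":
                assert -50 <= delta <= 0.18 * rr
            else:
                assert delta >= 0.18 * rr

    def test_at_most_one_sound_per_label_per_cycle(self, segmented_default):
        seen = set()
        for snd in segmented_default.sounds:
            key = (snd.ref_rpeak, snd.label)
            assert key not in seen
            seen.add(key)

    def test_bitwise_determinism(self, default_record):
        rec, _ = default_record
        a = segment_recording(rec)
        b = segment_recording(rec)
        np.testing.assert_array_equal(a.rpeaks.indices, b.rpeaks.indices)
        np.testing.assert_array_equal(a.envelope.values, b.envelope.values)
        assert [(s.label, s.segment) for s in a.sounds] == \
            [(s.label, s.segment) for s in b.sounds]

    def test_stage_errors_carry_stage_identity(self):
        rec = Recording(ecg=np.zeros(400), pcg=np.zeros(400))
        with pytest.raises(ValueError, match=r"\[bandpass_ecg\]"):
            segment_recording(rec)
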